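"""Ground-truthed synthetic fixtures: toy atlas, sphere scenes, rendered stacks.

Every pipeline stage can be exercised without downloading reference data:
a nested, axis-aligned toy atlas stands in for the real annotation volume
and ontology; scenes place 20-um beads at known atlas coordinates; the
renderer produces serial block-face images with the physical behaviour
that drives the method — beads shine through up to ~400 um of tissue with
depth-attenuated intensity, so each bead is visible in its own image and
up to three preceding ones, brightest when it finally surfaces.

Atlas axes are ordered (anterior-posterior, dorsal-ventral, medial-lateral),
so axis 0 is the cutting axis, image rows follow axis 1 and image columns
follow axis 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .detection import DEFAULT_THRESHOLD_LOW
from .imaging_io import BlockfaceStack
from .atlas_registration import AnchorSpec, SectionMapping
from .ontology_assignment import AtlasOntology, AnnotationVolume

AP, DV, ML = 0, 1, 2

_LEVEL2_NAMES = ("gray matter", "fiber tracts", "ventricular systems")


def generate_toy_atlas(
    depth: int = 5,
    branching: int = 2,
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_um: float = 50.0,
    seed: int = 0,
    margin: int = 2,
    early_stop_prob: float = 0.25,
) -> tuple[AtlasOntology, AnnotationVolume]:
    """Nested axis-aligned toy atlas with known region volumes.

    The brain is a box inset by ``margin`` voxels of label 0.  Each
    internal node is partitioned exactly among ``branching`` children
    (slabs along its longest axis), so sibling volumes tile their parent.
    From level 3 on, a seeded fraction of branches terminates early —
    exactly the situation that makes a structure "not exist" at deep
    ontology levels.  The first child of every node always recurses so the
    full ``depth`` is reached somewhere.  Same seed, same bytes.
    """
    if depth < 3:
        raise ValueError("depth must be >= 3")
    if branching < 2:
        raise ValueError("branching must be >= 2")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)
    brain = tuple(slice(margin, s - margin) for s in shape)
    brain_size = [s - 2 * margin for s in shape]
    if min(brain_size) < branching ** ((depth - 1 + 2) // 3):
        # each axis is split roughly every third level going down the tree
        raise ValueError("volume too small to nest the requested depth")

    nodes: list[dict] = []
    counter = {"next": 1}

    def new_node(name: str, parent: int | None) -> int:
        nid = counter["next"]
        counter["next"] += 1
        nodes.append({"id": nid, "name": name, "parent_structure_id": parent})
        return nid

    root = new_node("root", None)

    def build(nid: int, box: tuple[slice, slice, slice], level: int, forced: bool) -> None:
        """Partition ``box`` among children of ``nid``; recurse or stop."""
        sizes = [b.stop - b.start for b in box]
        axis = int(np.argmax(sizes))
        if sizes[axis] < branching or level >= depth:
            labels[box] = nid  # leaf: its voxels carry its own id
            return
        edges = np.linspace(box[axis].start, box[axis].stop, branching + 1).astype(int)
        any_child_recursed = False
        for c in range(branching):
            cbox = list(box)
            cbox[axis] = slice(edges[c], edges[c + 1])
            cbox = tuple(cbox)
            if level + 1 == 2 and c < len(_LEVEL2_NAMES):
                name = _LEVEL2_NAMES[c]
            else:
                name = f"region {counter['next']}"
            cid = new_node(name, nid)
            child_sizes = [b.stop - b.start for b in cbox]
            can_recurse = level + 1 < depth and max(child_sizes) >= branching
            force_child = c == 0 and forced
            # the last child of the forced spine at level 3 always stops:
            # guarantees at least one branch that "does not exist" at deep
            # levels, independent of the seed
            stop_early = level + 1 >= 3 and not force_child and (
                (forced and level + 1 == 3 and c == branching - 1)
                or rng.random() < early_stop_prob
            )
            if can_recurse and not stop_early:
                build(cid, cbox, level + 1, force_child)
                any_child_recursed = True
            else:
                labels[cbox] = cid
        if not any_child_recursed:
            pass  # all children are leaves; their slabs already tile the box

    build(root, brain, 1, True)
    ontology = AtlasOntology(nodes)
    annotation = AnnotationVolume(labels=labels, voxel_size_um=voxel_size_um)
    return ontology, annotation


@dataclass
class SceneSpec:
    """Ground-truth bead placement in atlas voxel coordinates."""

    positions: np.ndarray            # (n, 3) continuous voxel coords (ap, dv, ml)
    region_ids: np.ndarray           # (n,) annotation label under each bead
    sphere_diameter_um: float
    seed: int
    min_separation_um: float

    @property
    def n_spheres(self) -> int:
        return len(self.positions)


def generate_scene(
    ontology: AtlasOntology,
    annotation: AnnotationVolume,
    n_spheres: int,
    placement: str = "uniform",
    weights: dict[int, float] | None = None,
    seed: int = 0,
    sphere_diameter_um: float = 20.0,
    min_separation_um: float = 50.0,
    separation_window_um: float = 500.0,
) -> SceneSpec:
    """Place beads inside labelled voxels, optionally weighted per region.

    ``uniform`` placement is uniform over brain voxels; ``weighted``
    draws regions with probability proportional to weight x region volume
    (weights name ontology nodes; descendants inherit).  Beads whose
    anterior-posterior separation is within ``separation_window_um`` keep
    an in-plane distance of at least ``min_separation_um`` (rejection
    sampling), emulating beads lodging in distinct arterioles and keeping
    co-visible beads resolvable.  Same seed, same scene.
    """
    if n_spheres < 0:
        raise ValueError("n_spheres must be >= 0")
    rng = np.random.default_rng(seed)
    vox = annotation.voxel_size_um
    labelled = np.argwhere(annotation.labels > 0)
    if n_spheres and len(labelled) == 0:
        raise ValueError("annotation volume has no labelled voxels")

    if placement == "uniform":
        voxel_weights = np.ones(len(labelled))
    elif placement == "weighted":
        if not weights:
            raise ValueError("weighted placement needs a weights mapping")
        unknown = [r for r in weights if r not in ontology]
        if unknown:
            raise KeyError(f"weights name unknown regions: {unknown}")
        per_label: dict[int, float] = {}
        for nid, w in weights.items():
            for d in ontology.descendants(nid):
                per_label[d] = per_label.get(d, 0.0) + float(w)
        flat = annotation.labels[tuple(labelled.T)]
        voxel_weights = np.array([per_label.get(int(l), 0.0) for l in flat])
        if voxel_weights.sum() == 0:
            raise ValueError("weights select no labelled voxels")
    else:
        raise ValueError(f"unknown placement {placement!r}")
    p = voxel_weights / voxel_weights.sum() if len(labelled) else None

    positions = np.empty((n_spheres, 3))
    accepted = 0
    max_tries = 200 * max(n_spheres, 1)
    tries = 0
    while accepted < n_spheres:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place spheres at the requested separation; "
                "reduce n_spheres or min_separation_um"
            )
        # clearance of 0.1 voxel from voxel boundaries: a bead centred within
        # a few um of a structure boundary has no unique assignment at bead
        # scale, so scenes keep assignments well-posed
        vidx = labelled[rng.choice(len(labelled), p=p)]
        pos = vidx + rng.uniform(-0.4, 0.4, size=3)
        if min_separation_um > 0 and accepted:
            prev = positions[:accepted]
            close_ap = np.abs(prev[:, AP] - pos[AP]) * vox <= separation_window_um
            if np.any(close_ap):
                inplane = (
                    np.hypot(
                        prev[close_ap, DV] - pos[DV], prev[close_ap, ML] - pos[ML]
                    )
                    * vox
                )
                if np.any(inplane < min_separation_um):
                    continue
        positions[accepted] = pos
        accepted += 1

    idx = np.rint(positions).astype(int) if n_spheres else np.empty((0, 3), dtype=int)
    region_ids = (
        annotation.labels[tuple(idx.T)] if n_spheres else np.empty(0, dtype=np.int32)
    )
    return SceneSpec(
        positions=positions,
        region_ids=np.asarray(region_ids, dtype=np.int64),
        sphere_diameter_um=sphere_diameter_um,
        seed=seed,
        min_separation_um=min_separation_um,
    )


@dataclass
class RenderSpec:
    """Physical and photometric parameters of the block-face renderer."""

    pixel_size_um: float = 6.5
    section_thickness_um: float = 100.0
    visibility_depth_um: float = 400.0
    attenuation: str = "linear"          # or "exponential"
    surface_intensity: int = 255
    threshold_level: int = DEFAULT_THRESHOLD_LOW
    background_green: int = 40           # brain tissue autofluorescence, below threshold
    noise_sigma: float = 0.0
    jitter_px: float = 0.0               # max |dx|,|dy| rigid jitter per section
    jitter_deg: float = 0.0
    blur_per_section_px: float = 0.3     # scattering blur per 100 um of overlying tissue
    seed: int = 0

    def __post_init__(self) -> None:
        if self.visibility_depth_um < self.section_thickness_um:
            raise ValueError("visibility depth must cover at least one section")

    def intensity_at_depth(self, depth_um: float) -> float:
        """Monotone non-increasing attenuation; >= threshold within visibility."""
        if depth_um > self.visibility_depth_um:
            return 0.0
        top, floor = self.surface_intensity, self.threshold_level
        frac = depth_um / self.visibility_depth_um
        if self.attenuation == "linear":
            return top - (top - floor) * frac
        if self.attenuation == "exponential":
            # decays from top to exactly the floor at the visibility depth
            return top * (floor / top) ** frac
        raise ValueError(f"unknown attenuation {self.attenuation!r}")


@dataclass
class RenderResult:
    """Rendered stack plus everything needed to check it against truth."""

    stack: BlockfaceStack
    truth: pd.DataFrame
    mapping: SectionMapping
    jitter: list
    spec: RenderSpec = field(repr=False, default=None)


def true_section_mapping(
    annotation: AnnotationVolume, spec: RenderSpec, n_sections: int, width: int, height: int
) -> SectionMapping:
    """The exact pixel->atlas charts the renderer uses (ideal anchors).

    Atlas coordinates use the voxel-centre convention: voxel ``v`` spans
    physical [v*vox, (v+1)*vox) um and has continuous coordinate ``v`` at
    its centre, so um -> coord is ``um/vox - 0.5``.  Each section's chart
    reads out at the section's mid-plane.
    """
    vox = annotation.voxel_size_um
    t = spec.section_thickness_um
    o = np.full((n_sections, 3), -0.5)
    o[:, AP] = (np.arange(n_sections) + 0.5) * t / vox - 0.5
    u = np.tile([0.0, 0.0, width * spec.pixel_size_um / vox], (n_sections, 1))
    v = np.tile([0.0, height * spec.pixel_size_um / vox, 0.0], (n_sections, 1))
    return SectionMapping(o=o, u=u, v=v)


def anchors_from_mapping(mapping: SectionMapping, sections) -> list[AnchorSpec]:
    """Extract anchor specs for selected sections from a full mapping."""
    return [
        AnchorSpec(section_index=int(s), o=mapping.o[s], u=mapping.u[s], v=mapping.v[s])
        for s in sections
    ]


def _draw_disk(channel: np.ndarray, x: float, y: float, radius_px: float, value: float) -> None:
    h, w = channel.shape
    x0, x1 = int(math.floor(x - radius_px - 2)), int(math.ceil(x + radius_px + 2))
    y0, y1 = int(math.floor(y - radius_px - 2)), int(math.ceil(y + radius_px + 2))
    x0, x1 = max(0, x0), min(w - 1, x1)
    y0, y1 = max(0, y0), min(h - 1, y1)
    if x1 < x0 or y1 < y0:
        return
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    disk = (xx - x) ** 2 + (yy - y) ** 2 <= radius_px**2
    patch = channel[y0 : y1 + 1, x0 : x1 + 1]
    patch[disk] = np.maximum(patch[disk], value)
    cy, cx = int(round(y)), int(round(x))
    if 0 <= cy < h and 0 <= cx < w:
        channel[cy, cx] = max(channel[cy, cx], value)


def render_blockface_stack(
    scene: SceneSpec,
    annotation: AnnotationVolume,
    spec: RenderSpec | None = None,
) -> RenderResult:
    """Render a scene into a serial block-face RGB stack with ground truth.

    A bead in section s surfaces in image s (the block face photographed
    just before section s is cut) and shines through the preceding images
    s-1, s-2, ... while its depth below the cut surface stays within the
    visibility depth, with attenuated intensity and a small depth-dependent
    scattering blur.  Rigid jitter and Gaussian noise, when requested, are
    applied after rendering; the ground-truth table records each bead's
    true section, pre-jitter pixel position, atlas coordinate and region.
    """
    if spec is None:
        spec = RenderSpec()
    rng = np.random.default_rng(spec.seed)
    vox = annotation.voxel_size_um
    t = spec.section_thickness_um
    n0, n1, n2 = annotation.labels.shape
    n_sections = int(math.ceil(n0 * vox / t))
    width = int(math.ceil(n2 * vox / spec.pixel_size_um))
    height = int(math.ceil(n1 * vox / spec.pixel_size_um))
    images = np.zeros((n_sections, height, width, 3), dtype=float)

    # brain foreground: the labelled slab at each section's mid-plane,
    # upsampled to pixel resolution (nearest neighbour keeps it crisp)
    rows = np.clip(((np.arange(height) + 0.5) * spec.pixel_size_um / vox).astype(int), 0, n1 - 1)
    cols = np.clip(((np.arange(width) + 0.5) * spec.pixel_size_um / vox).astype(int), 0, n2 - 1)
    for s in range(n_sections):
        plane = min(int((s + 0.5) * t / vox), n0 - 1)
        fg = (annotation.labels[plane] > 0)[np.ix_(rows, cols)]
        for c, level in enumerate((spec.background_green,) * 3):
            images[s, ..., c][fg] = level

    radius_px = (scene.sphere_diameter_um / spec.pixel_size_um) / 2.0
    truth_rows = []
    max_span = int(math.ceil(spec.visibility_depth_um / t))
    for i in range(scene.n_spheres):
        # voxel-centre convention: coordinate v sits at physical (v+0.5)*vox
        ap_um = (scene.positions[i, AP] + 0.5) * vox
        section = min(int(ap_um // t), n_sections - 1)
        x_px = (scene.positions[i, ML] + 0.5) * vox / spec.pixel_size_um
        y_px = (scene.positions[i, DV] + 0.5) * vox / spec.pixel_size_um
        for k in range(max_span):
            s = section - k
            if s < 0:
                break
            depth = ap_um - s * t
            if depth > spec.visibility_depth_um:
                break
            value = spec.intensity_at_depth(depth)
            if k == 0 or spec.blur_per_section_px <= 0:
                _draw_disk(images[s, ..., 1], x_px, y_px, radius_px, value)
            else:
                # blurred sub-surface appearance, renormalised so the core
                # keeps its attenuated intensity (stays detectable)
                patch = np.zeros_like(images[s, ..., 1])
                _draw_disk(patch, x_px, y_px, radius_px, value)
                patch = ndimage.gaussian_filter(patch, sigma=spec.blur_per_section_px * k)
                if patch.max() > 0:
                    patch *= value / patch.max()
                np.maximum(images[s, ..., 1], patch, out=images[s, ..., 1])
        truth_rows.append(
            {
                "sphere_id": i,
                "section_index": section,
                "x_px": x_px,
                "y_px": y_px,
                "atlas_ap": scene.positions[i, AP],
                "atlas_dv": scene.positions[i, DV],
                "atlas_ml": scene.positions[i, ML],
                "region_id": int(scene.region_ids[i]),
            }
        )

    jitter = []
    if spec.jitter_px > 0 or spec.jitter_deg > 0:
        from .imaging_io import RigidTransform2D, apply_rigid

        for s in range(n_sections):
            dx = float(rng.uniform(-spec.jitter_px, spec.jitter_px))
            dy = float(rng.uniform(-spec.jitter_px, spec.jitter_px))
            ang = float(rng.uniform(-spec.jitter_deg, spec.jitter_deg))
            tform = RigidTransform2D(rotation_deg=ang, translation=(dx, dy))
            jitter.append(tform)
            images[s] = apply_rigid(images[s].astype(np.uint8), tform, order=1).astype(float)
    else:
        from .imaging_io import RigidTransform2D

        jitter = [RigidTransform2D() for _ in range(n_sections)]

    if spec.noise_sigma > 0:
        images += rng.normal(0.0, spec.noise_sigma, size=images.shape)

    stack = BlockfaceStack(
        sections=np.clip(np.rint(images), 0, 255).astype(np.uint8),
        pixel_size_um=spec.pixel_size_um,
        section_thickness_um=spec.section_thickness_um,
        metadata={"synthetic": True, "seed": spec.seed},
    )
    mapping = true_section_mapping(annotation, spec, n_sections, width, height)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sphere_id", "section_index", "x_px", "y_px",
            "atlas_ap", "atlas_dv", "atlas_ml", "region_id",
        ],
    )
    return RenderResult(stack=stack, truth=truth, mapping=mapping, jitter=jitter, spec=spec)


def generate_mask_stack(
    n_sections: int = 20,
    n_spheres: int = 50,
    shape: tuple[int, int] = (128, 128),
    max_chain: int = 4,
    radius_px: float = 2.0,
    drift_px: float = 1.0,
    match_radius_px: float = 4.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Random binary mask stacks of drifting sphere chains, with truth.

    Each sphere occupies a chain of 1..``max_chain`` consecutive sections
    ending at its true section, drifting by at most ``drift_px`` per
    section (so consecutive disks stay pixel-overlapping).  Chains that
    could co-occur in a section keep an in-plane separation of at least
    ``2 * (2*radius_px + match_radius_px)``, so distinct chains can be
    merged neither by pixel connectivity nor by centroid matching.
    Returns the per-section masks and a truth table (sphere id, true
    section, final x/y).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = int(radius_px + drift_px * max_chain + 2)
    sep = 2.0 * (2.0 * radius_px + match_radius_px)
    masks = [np.zeros(shape, dtype=np.uint8) for _ in range(n_sections)]
    truth = []
    placed: list[tuple[float, float, int, int]] = []  # x, y, first, last
    attempts = 0
    i = 0
    while i < n_spheres and attempts < 200 * max(n_spheres, 1):
        attempts += 1
        last = int(rng.integers(0, n_sections))
        span = int(rng.integers(1, max_chain + 1))
        first = max(0, last - span + 1)
        x = float(rng.uniform(margin, w - margin))
        y = float(rng.uniform(margin, h - margin))
        clash = any(
            math.hypot(x - px, y - py) < sep
            and not (last < pf - 1 or first > pl + 1)
            for px, py, pf, pl in placed
        )
        if clash:
            continue
        cx, cy = x, y
        for s in range(last, first - 1, -1):
            _draw_disk(masks[s], cx, cy, radius_px, 1)
            cx += float(rng.uniform(-drift_px, drift_px))
            cy += float(rng.uniform(-drift_px, drift_px))
        placed.append((x, y, first, last))
        truth.append({"sphere_id": i, "section_index": last, "x_px": x, "y_px": y})
        i += 1
    return masks, pd.DataFrame(truth, columns=["sphere_id", "section_index", "x_px", "y_px"])


def label_chains_3d(masks) -> tuple[int, list[int]]:
    """Brute-force z-resolution oracle: 26-connectivity labelling in 3D.

    Stacks the per-section masks into a volume, labels it with full
    3D connectivity, and reports the number of connected sphere chains and
    each chain's deepest (maximum) section index — the assignment the
    serial-subtraction rule must reproduce.
    """
    vol = np.stack([np.asarray(m) > 0 for m in masks])
    lab, n = ndimage.label(vol, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return 0, []
    zz = np.nonzero(vol)[0]
    comp = lab[vol]
    max_z = np.full(n + 1, -1)
    np.maximum.at(max_z, comp, zz)
    return n, sorted(int(z) for z in max_z[1:])
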