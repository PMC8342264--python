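"""Microsphere segmentation and z-plane resolution by serial mask subtraction.

The fluorescent beads are bright enough to shine through several hundred
micrometres of tissue, so one bead is usually visible in several
consecutive block-face images.  The last image in which a bead is detected
is the section that actually contains it: once that section is cut away the
bead is gone from the block.  Subtracting each section's binary mask from
its successor's therefore assigns every bead to its true section, giving a
z-resolution equal to the section thickness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import label, regionprops
from skimage.segmentation import watershed

DEFAULT_THRESHOLD_LOW = 140
DEFAULT_SPHERE_DIAMETER_UM = 20.0
DEFAULT_VISIBILITY_DEPTH_UM = 400.0


class BitDepthError(TypeError):
    """Input image is not 8-bit; thresholds are defined on the 0-255 scale."""


@dataclass
class Detection:
    """One resolved microsphere."""

    section_index: int
    x: float
    y: float
    area_px2: float
    equivalent_diameter_um: float
    merged: bool = False
    source: str = "auto"


def nominal_diameter_px(pixel_size_um: float, diameter_um: float = DEFAULT_SPHERE_DIAMETER_UM) -> int:
    """Sphere diameter in whole pixels, rounded up, at least 1."""
    return max(1, math.ceil(diameter_um / pixel_size_um))


def default_area_bounds(pixel_size_um: float, diameter_um: float = DEFAULT_SPHERE_DIAMETER_UM) -> tuple[float, float]:
    """(min, max) component area in px^2: 0.25x-4x the nominal disk area."""
    d = diameter_um / pixel_size_um
    area = math.pi * (d / 2.0) ** 2
    return max(1.0, 0.25 * area), max(1.0, 4.0 * area)


def threshold_microspheres(
    image: np.ndarray,
    low: int = DEFAULT_THRESHOLD_LOW,
    high: int = 255,
    channel: int = 1,
) -> np.ndarray:
    """Binary sphere mask from the green channel of an 8-bit image.

    Pixels with intensity below ``low`` are background; from ``low`` up
    (inclusive) they are classified as microsphere signal.
    """
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise BitDepthError(
            f"expected an 8-bit image, got dtype {image.dtype}; refusing to rescale silently"
        )
    chan = image[..., channel] if image.ndim == 3 else image
    return ((chan >= low) & (chan <= high)).astype(np.uint8)


def points_to_mask(
    points,
    shape: tuple[int, int],
    pixel_size_um: float,
    diameter_um: float = DEFAULT_SPHERE_DIAMETER_UM,
) -> np.ndarray:
    """Dilate manually clicked points to sphere-sized disks.

    Each (x, y) point becomes a filled disk whose diameter matches the
    physical bead size at the given calibration (rounded up to >= 1 px), so
    manual annotations flow through the same subtraction path as automated
    masks.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=np.uint8)
    pts = list(points)
    bad = [
        i for i, (x, y) in enumerate(pts)
        if not (0 <= x < w and 0 <= y < h)
    ]
    if bad:
        raise ValueError(f"points out of bounds at indices {bad}")
    d_px = nominal_diameter_px(pixel_size_um, diameter_um)
    r = d_px / 2.0
    for x, y in pts:
        x0, x1 = int(math.floor(x - r)), int(math.ceil(x + r))
        y0, y1 = int(math.floor(y - r)), int(math.ceil(y + r))
        yy, xx = np.mgrid[max(0, y0):min(h, y1 + 1), max(0, x0):min(w, x1 + 1)]
        disk = (xx - x) ** 2 + (yy - y) ** 2 <= r**2
        mask[max(0, y0):min(h, y1 + 1), max(0, x0):min(w, x1 + 1)][disk] = 1
        mask[int(round(y)), int(round(x))] = 1  # area >= 1 even at coarse calibration
    return mask


def _component_centroids(mask: np.ndarray) -> tuple[np.ndarray, list]:
    lab = label(mask > 0, connectivity=2)
    props = regionprops(lab)
    return lab, props


def resolve_z_by_serial_subtraction(
    masks,
    match_radius_px: float,
    mode: str = "component",
    max_chain_sections: int | None = None,
) -> list[np.ndarray]:
    """Keep, per section, only the spheres not seen again in the next section.

    ``component`` mode (default) matches connected components between
    adjacent masks by centroid distance, tolerating residual alignment
    error up to ``match_radius_px``; a component of section *i* survives iff
    no component of section *i+1* lies within the radius.  ``pixel`` mode is
    literal mask subtraction (``mask_i & ~mask_{i+1}``).  The last section's
    mask passes through unchanged in both modes.

    ``max_chain_sections`` caps how many consecutive sections one sphere may
    span (visibility depth / section thickness); longer same-place chains
    are split with a warning, each segment contributing one output sphere.
    """
    masks = [np.asarray(m) for m in masks]
    if not masks:
        return []
    if mode == "pixel":
        out = [((m > 0) & ~(nxt > 0)).astype(np.uint8) for m, nxt in zip(masks[:-1], masks[1:])]
        out.append((masks[-1] > 0).astype(np.uint8))
        return out
    if mode != "component":
        raise ValueError(f"unknown subtraction mode {mode!r}")

    labelled = [_component_centroids(m) for m in masks]
    keep: list[np.ndarray] = []
    chain_len: list[dict[int, int]] = [dict() for _ in masks]  # label -> run length so far
    for i, (lab, props) in enumerate(labelled):
        kept = np.zeros_like(lab, dtype=np.uint8)
        if i + 1 < len(masks):
            _, nxt_props = labelled[i + 1]
            nxt_centroids = np.array([p.centroid for p in nxt_props]) if nxt_props else np.empty((0, 2))
        else:
            nxt_centroids = np.empty((0, 2))
        for p in props:
            run = chain_len[i].get(p.label, 1)
            matched = False
            if len(nxt_centroids):
                d = np.hypot(
                    nxt_centroids[:, 0] - p.centroid[0], nxt_centroids[:, 1] - p.centroid[1]
                )
                j = int(np.argmin(d))
                if d[j] <= match_radius_px:
                    matched = True
                    nxt_label = labelled[i + 1][1][j].label
                    if max_chain_sections is not None and run >= max_chain_sections:
                        warnings.warn(
                            f"sphere chain longer than {max_chain_sections} sections at "
                            f"section {i}; splitting"
                        )
                        matched = False  # split: emit here, restart the chain
                        chain_len[i + 1][nxt_label] = 1
                    else:
                        chain_len[i + 1][nxt_label] = run + 1
            if not matched:
                kept[lab == p.label] = 1
        keep.append(kept)
    return keep


def extract_centroids(
    final_masks,
    pixel_size_um: float,
    min_area_px: float | None = None,
    max_area_px: float | None = None,
    source: str = "auto",
) -> list[Detection]:
    """Connected-component detections from resolved masks, with size filter.

    Components smaller than ``min_area_px`` are discarded as noise; larger
    than ``max_area_px`` they are treated as merged spheres and split by a
    distance-transform watershed seeded at local maxima, yielding >= 2
    detections.  Defaults derive from the nominal bead disk area at the
    given calibration (pass 0 / inf to disable filtering).
    """
    lo, hi = default_area_bounds(pixel_size_um)
    if min_area_px is None:
        min_area_px = lo
    if max_area_px is None:
        max_area_px = hi
    d_px = nominal_diameter_px(pixel_size_um)
    detections: list[Detection] = []
    for z, mask in enumerate(final_masks):
        mask = np.asarray(mask) > 0
        lab = label(mask, connectivity=2)
        for p in regionprops(lab):
            if p.area < min_area_px:
                continue
            if p.area <= max_area_px:
                cy, cx = p.centroid
                detections.append(
                    Detection(
                        section_index=z,
                        x=float(cx),
                        y=float(cy),
                        area_px2=float(p.area),
                        equivalent_diameter_um=float(p.equivalent_diameter_area * pixel_size_um),
                        source=source,
                    )
                )
                continue
            # merged blob: split on the distance transform
            region = lab == p.label
            dist = ndimage.distance_transform_edt(region)
            peaks = peak_local_max(
                dist, min_distance=max(1, d_px // 2), labels=region, exclude_border=False
            )
            if len(peaks) < 2:
                peaks = peak_local_max(dist, min_distance=1, labels=region, exclude_border=False)
            markers = np.zeros_like(lab)
            for k, (py, px) in enumerate(peaks, start=1):
                markers[py, px] = k
            split = watershed(-dist, markers, mask=region)
            for q in regionprops(split):
                if q.area < min_area_px:
                    continue
                cy, cx = q.centroid
                detections.append(
                    Detection(
                        section_index=z,
                        x=float(cx),
                        y=float(cy),
                        area_px2=float(q.area),
                        equivalent_diameter_um=float(q.equivalent_diameter_area * pixel_size_um),
                        merged=True,
                        source=source,
                    )
                )
    return detections


def detections_to_frame(detections) -> pd.DataFrame:
    """Detections as the CSV-ready table (id, section, position, area, source)."""
    return pd.DataFrame(
        {
            "id": range(len(detections)),
            "section_index": [d.section_index for d in detections],
            "x_px": [d.x for d in detections],
            "y_px": [d.y for d in detections],
            "area_px2": [d.area_px2 for d in detections],
            "equivalent_diameter_um": [d.equivalent_diameter_um for d in detections],
            "source": [d.source for d in detections],
        }
    )


@dataclass
class CountComparison:
    """Paired per-section automated vs manual counts plus totals."""

    table: pd.DataFrame
    total_automated: int
    total_manual: int


def compare_counts(automated, manual) -> CountComparison:
    """Pair per-section automated and manual sphere counts for validation."""
    automated = list(automated)
    manual = list(manual)
    if len(automated) != len(manual):
        raise ValueError(
            f"count lists differ in length: {len(automated)} vs {len(manual)}"
        )
    table = pd.DataFrame(
        {
            "section_index": range(len(automated)),
            "automated": automated,
            "manual": manual,
        }
    )
    table["difference"] = table["automated"] - table["manual"]
    return CountComparison(
        table=table,
        total_automated=int(table["automated"].sum()),
        total_manual=int(table["manual"].sum()),
    )
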