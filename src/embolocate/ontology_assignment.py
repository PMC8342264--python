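"""Hierarchical region assignment, count aggregation, and report tables.

The reference ontology is a rooted tree (level 1 = root; level 2 splits
into gray matter, fiber tracts and ventricular systems; deepest leaves
around level 12).  Not every branch reaches the same depth, so a structure
can simply "not exist" at a deep level.  Detections are looked up in a 3D
annotation label volume, rolled up the tree, and reported over the set of
terminal branches chosen by the >= 5-spheres expansion criterion, with
per-region proportion and volume-normalised density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: Sentinel for detections outside any labelled structure (or the volume).
UNACCOUNTED = "unaccounted"
#: Sentinel for a structure whose branch ends above the queried level.
NOT_AT_LEVEL = "not_at_this_level"

MAX_LEVEL = 12


class AtlasOntology:
    """Rooted hierarchical structure tree with per-node levels.

    Nodes follow structure-graph conventions: ``id``, ``name`` and
    ``parent_structure_id`` (``None`` for the root).  Level numbering
    starts at 1 for the root; level(child) = level(parent) + 1.
    """

    def __init__(self, nodes: Iterable[Mapping]):
        self.nodes: dict[int, dict] = {}
        for n in nodes:
            nid = int(n["id"])
            if nid in self.nodes:
                raise ValueError(f"duplicate ontology id {nid}")
            parent = n.get("parent_structure_id")
            self.nodes[nid] = {
                "id": nid,
                "name": str(n["name"]),
                "parent_structure_id": None if parent is None else int(parent),
            }
        roots = [nid for nid, n in self.nodes.items() if n["parent_structure_id"] is None]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {len(roots)}")
        self.root_id: int = roots[0]
        self._children: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for nid, n in self.nodes.items():
            p = n["parent_structure_id"]
            if p is not None:
                if p not in self.nodes:
                    raise ValueError(f"node {nid} references unknown parent {p}")
                self._children[p].append(nid)
        # levels by BFS; also detects cycles / unreachable nodes
        self._level: dict[int, int] = {self.root_id: 1}
        frontier = [self.root_id]
        while frontier:
            nxt = []
            for nid in frontier:
                for c in self._children[nid]:
                    self._level[c] = self._level[nid] + 1
                    nxt.append(c)
            frontier = nxt
        if len(self._level) != len(self.nodes):
            raise ValueError("ontology graph is not a single connected tree")

    @classmethod
    def from_json(cls, path: str | Path) -> "AtlasOntology":
        payload = json.loads(Path(path).read_text())
        if isinstance(payload, dict) and "msg" in payload:  # structure-graph envelope
            payload = payload["msg"]
        return cls(payload)

    def to_json(self, path: str | Path) -> None:
        out = [
            {**n, "level": self._level[nid]}
            for nid, n in sorted(self.nodes.items())
        ]
        Path(path).write_text(json.dumps(out, indent=2))

    def __contains__(self, nid: int) -> bool:
        return nid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def name(self, nid: int) -> str:
        return self.nodes[nid]["name"]

    def level(self, nid: int) -> int:
        return self._level[nid]

    def parent(self, nid: int) -> int | None:
        return self.nodes[nid]["parent_structure_id"]

    def children(self, nid: int) -> list[int]:
        return list(self._children[nid])

    def is_leaf(self, nid: int) -> bool:
        return not self._children[nid]

    def path_to_root(self, nid: int) -> list[int]:
        """Node ids from the root down to (and including) ``nid``."""
        if nid not in self.nodes:
            raise KeyError(f"unknown ontology id {nid}")
        path = []
        cur: int | None = nid
        while cur is not None:
            path.append(cur)
            cur = self.parent(cur)
        return path[::-1]

    def ancestor_at_level(self, nid: int, k: int):
        """The unique ancestor (or self) at level ``k``.

        Returns :data:`NOT_AT_LEVEL` when the node's own branch ends above
        ``k`` (its level is smaller than ``k``).
        """
        if nid not in self.nodes:
            raise KeyError(f"unknown ontology id {nid}")
        if k < 1:
            raise ValueError("levels start at 1")
        if self.level(nid) < k:
            return NOT_AT_LEVEL
        return self.path_to_root(nid)[k - 1]

    def descendants(self, nid: int, include_self: bool = True) -> list[int]:
        out = [nid] if include_self else []
        stack = list(self._children[nid])
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(self._children[cur])
        return out

    def path_names(self, nid: int) -> str:
        return " > ".join(self.name(i) for i in self.path_to_root(nid))


def ancestor_at_level(ontology: AtlasOntology, nid: int, k: int):
    return ontology.ancestor_at_level(nid, k)


@dataclass
class AnnotationVolume:
    """3D integer label volume with isotropic voxel size (um); 0 = outside."""

    labels: np.ndarray
    voxel_size_um: float
    _volume_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or 0 in self.labels.shape:
            raise ValueError("labels must be a non-empty 3D array")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um / 1000.0) ** 3

    @classmethod
    def from_nifti(cls, path: str | Path) -> "AnnotationVolume":
        img = nib.load(str(path))
        voxel = float(img.header.get_zooms()[0]) * 1000.0  # NIfTI zooms stored in mm
        return cls(np.asarray(img.dataobj).astype(np.int32), voxel_size_um=voxel)

    def to_nifti(self, path: str | Path) -> None:
        mm = self.voxel_size_um / 1000.0
        affine = np.diag([mm, mm, mm, 1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int32), affine), str(path))

    def label_voxel_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def assign_region(coord, annotation: AnnotationVolume):
    """Nearest-voxel structure lookup for one continuous atlas coordinate.

    Coordinates outside the volume or falling on label 0 map to
    :data:`UNACCOUNTED`.
    """
    idx = np.rint(np.asarray(coord, dtype=float)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(annotation.labels.shape)):
        return UNACCOUNTED
    lab = int(annotation.labels[tuple(idx)])
    return UNACCOUNTED if lab == 0 else lab


def aggregate_counts(ontology: AtlasOntology, leaf_counts: Mapping[int, int]) -> dict[int, int]:
    """Cumulative per-node counts: own direct count plus all descendants."""
    for nid in leaf_counts:
        if nid not in ontology:
            raise KeyError(f"count keyed by unknown ontology id {nid}")
    cumulative = {nid: int(leaf_counts.get(nid, 0)) for nid in ontology.nodes}
    # accumulate bottom-up: deepest levels first
    for nid in sorted(ontology.nodes, key=ontology.level, reverse=True):
        p = ontology.parent(nid)
        if p is not None:
            cumulative[p] += cumulative[nid]
    return cumulative


def select_terminal_branches(
    ontology: AtlasOntology,
    cumulative_counts: Mapping[int, int],
    min_count: int = 5,
    max_level: int | None = None,
    criterion_on: str = "parent",
) -> list[int]:
    """Frontier of reporting regions under the >= ``min_count`` expansion rule.

    Walking down from the root, a node's children are visited only when the
    node holds at least ``min_count`` spheres (cumulatively), it has
    children, and its level is below ``max_level`` (when set); otherwise the
    node is terminal.  With ``criterion_on="child"`` the count test is
    applied to each child instead of the expanded parent.  Zero-count
    frontier nodes are dropped, so the returned regions are mutually
    exclusive and jointly exhaustive over all counted spheres.
    """
    if criterion_on not in ("parent", "child"):
        raise ValueError(f"unknown criterion_on {criterion_on!r}")
    terminals: list[int] = []

    def visit(nid: int) -> None:
        count = cumulative_counts.get(nid, 0)
        expandable = (
            not ontology.is_leaf(nid)
            and (max_level is None or ontology.level(nid) < max_level)
        )
        if criterion_on == "parent":
            expand = expandable and count >= min_count
        else:
            expand = expandable
        if not expand:
            if count > 0:
                terminals.append(nid)
            return
        for c in ontology.children(nid):
            if criterion_on == "child" and cumulative_counts.get(c, 0) < min_count:
                if cumulative_counts.get(c, 0) > 0:
                    terminals.append(c)
            else:
                visit(c)

    visit(ontology.root_id)
    return terminals


def region_volume_mm3(
    ontology: AtlasOntology, annotation: AnnotationVolume, nid: int
) -> float:
    """Structure volume including all descendant voxels, in mm^3."""
    cache = annotation._volume_cache
    if "cumulative_voxels" not in cache:
        direct = annotation.label_voxel_counts()
        cum = {n: direct.get(n, 0) for n in ontology.nodes}
        for n in sorted(ontology.nodes, key=ontology.level, reverse=True):
            p = ontology.parent(n)
            if p is not None:
                cum[p] += cum[n]
        cache["cumulative_voxels"] = cum
    return cache["cumulative_voxels"][nid] * annotation.voxel_volume_mm3


def region_density(count: int, volume_mm3: float) -> float:
    """Spheres per mm^3 of structure."""
    if volume_mm3 <= 0:
        if count:
            raise ValueError("nonzero count in a zero-volume region")
        return 0.0
    return count / volume_mm3


@dataclass
class RegionReport:
    """Terminal-region report plus the per-detection level table."""

    regions: pd.DataFrame       # one row per terminal region (+ unaccounted, totals)
    level_table: pd.DataFrame   # one row per detection, ancestor name at levels 1..12
    total_detections: int
    unaccounted: int


def compile_report(
    assignments: Sequence,
    ontology: AtlasOntology,
    annotation: AnnotationVolume | None = None,
    min_count: int = 5,
    max_level: int | None = None,
    other_bucket: bool = True,
) -> RegionReport:
    """Consolidate per-detection region assignments into report tables.

    ``assignments`` holds one region id (or :data:`UNACCOUNTED`) per
    detection.  The region table has one row per terminal branch with
    count, proportion of all detections (unaccounted included, matching the
    published convention), structure volume and density, plus an
    "Unaccounted microspheres" row and a totals row whose count/proportion
    are column sums and whose density is the mean over regions.  When an
    expanded node carries direct detections that none of its children
    inherit, they are reported in an "(other)" bucket row for that node so
    every sphere lands in exactly one row.

    The level table lists every detection's ancestor at each ontology level
    1..12 (:data:`NOT_AT_LEVEL` past the end of its branch).
    """
    assignments = list(assignments)
    total = len(assignments)
    unaccounted = sum(1 for a in assignments if a == UNACCOUNTED)
    direct: dict[int, int] = {}
    for a in assignments:
        if a != UNACCOUNTED:
            if a not in ontology:
                raise KeyError(f"assignment to unknown ontology id {a}")
            direct[a] = direct.get(a, 0) + 1
    cumulative = aggregate_counts(ontology, direct)
    terminals = select_terminal_branches(
        ontology, cumulative, min_count=min_count, max_level=max_level
    )
    terminal_set = set(terminals)

    # direct counts on expanded (non-terminal) ancestors go to "(other)" buckets
    rows = []
    other_counts: dict[int, int] = {}
    for nid, c in direct.items():
        path = ontology.path_to_root(nid)
        owner = next((p for p in path if p in terminal_set), None)
        if owner is None:
            other_counts[nid] = other_counts.get(nid, 0) + c

    def volume_of(nid: int) -> float:
        if annotation is None:
            return float("nan")
        return region_volume_mm3(ontology, annotation, nid)

    denom = max(total, 1)
    for nid in terminals:
        cnt = cumulative[nid]
        vol = volume_of(nid)
        rows.append(
            {
                "region_id": nid,
                "region": ontology.name(nid),
                "level": ontology.level(nid),
                "count": cnt,
                "proportion_pct": 100.0 * cnt / denom,
                "volume_mm3": vol,
                "density_per_mm3": region_density(cnt, vol) if np.isfinite(vol) else float("nan"),
                "hierarchy_path": ontology.path_names(nid),
            }
        )
    if other_bucket:
        for nid, cnt in sorted(other_counts.items()):
            vol = volume_of(nid)
            rows.append(
                {
                    "region_id": nid,
                    "region": f"{ontology.name(nid)} (other)",
                    "level": ontology.level(nid),
                    "count": cnt,
                    "proportion_pct": 100.0 * cnt / denom,
                    "volume_mm3": vol,
                    "density_per_mm3": region_density(cnt, vol) if np.isfinite(vol) else float("nan"),
                    "hierarchy_path": ontology.path_names(nid),
                }
            )
    elif other_counts:
        unaccounted += sum(other_counts.values())

    region_df = pd.DataFrame(
        rows,
        columns=[
            "region_id", "region", "level", "count", "proportion_pct",
            "volume_mm3", "density_per_mm3", "hierarchy_path",
        ],
    )
    densities = region_df["density_per_mm3"].to_numpy(dtype=float) if len(region_df) else np.array([])
    summary_rows = pd.DataFrame(
        [
            {
                "region_id": -1,
                "region": "Unaccounted microspheres",
                "level": np.nan,
                "count": unaccounted,
                "proportion_pct": 100.0 * unaccounted / denom,
                "volume_mm3": np.nan,
                "density_per_mm3": np.nan,
                "hierarchy_path": "",
            },
            {
                "region_id": -2,
                "region": "Total, all regions combined",
                "level": np.nan,
                "count": int(region_df["count"].sum()) + unaccounted,
                "proportion_pct": float(region_df["proportion_pct"].sum())
                + 100.0 * unaccounted / denom,
                "volume_mm3": np.nan,
                "density_per_mm3": float(np.nanmean(densities)) if len(densities) else np.nan,
                "hierarchy_path": "",
            },
        ]
    )
    region_df = pd.concat([region_df, summary_rows], ignore_index=True)

    level_rows = []
    for i, a in enumerate(assignments):
        row: dict = {"detection_id": i, "region_id": a}
        for k in range(1, MAX_LEVEL + 1):
            if a == UNACCOUNTED:
                row[f"level_{k}"] = UNACCOUNTED
            else:
                anc = ontology.ancestor_at_level(a, k)
                row[f"level_{k}"] = anc if anc == NOT_AT_LEVEL else ontology.name(anc)
        level_rows.append(row)
    level_df = pd.DataFrame(level_rows)

    return RegionReport(
        regions=region_df,
        level_table=level_df,
        total_detections=total,
        unaccounted=unaccounted,
    )
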