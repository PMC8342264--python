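"""Anchor-based linear mapping from section pixels to 3D atlas coordinates.

Each section's placement in atlas space is a linear (affine) chart: an
origin ``o`` giving the atlas position of the image's top-left corner and
two in-plane vectors ``u``/``v`` spanning the image width and height, all
in continuous, 0-based atlas voxel coordinates.  A few sections are
anchored by the user against visible anatomy; anterior-posterior position
and cutting angles are then propagated linearly across the unanchored
sections, mirroring how serial-section anchoring tools interpolate between
a small number of user-placed charts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass
class AnchorSpec:
    """User-placed atlas chart for one section."""

    section_index: int
    o: np.ndarray  # (ox, oy, oz) atlas voxel coords of the top-left pixel
    u: np.ndarray  # atlas displacement spanning the image width
    v: np.ndarray  # atlas displacement spanning the image height

    def __post_init__(self) -> None:
        self.o = np.asarray(self.o, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        for name, vec in (("o", self.o), ("u", self.u), ("v", self.v)):
            if vec.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
        if np.linalg.norm(np.cross(self.u, self.v)) == 0:
            raise ValueError("anchor vectors u and v are parallel")


@dataclass
class SectionMapping:
    """Per-section (o, u, v) charts for every section of a stack."""

    o: np.ndarray  # (n_sections, 3)
    u: np.ndarray
    v: np.ndarray

    @property
    def n_sections(self) -> int:
        return self.o.shape[0]

    def chart(self, section_index: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.o[section_index], self.u[section_index], self.v[section_index]


def _piecewise_linear(xs: np.ndarray, ys: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Linear interpolation with end-segment slope extrapolation."""
    out = np.interp(q, xs, ys)
    if len(xs) >= 2:
        lo = q < xs[0]
        hi = q > xs[-1]
        s0 = (ys[1] - ys[0]) / (xs[1] - xs[0])
        s1 = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        out[lo] = ys[0] + s0 * (q[lo] - xs[0])
        out[hi] = ys[-1] + s1 * (q[hi] - xs[-1])
    return out


def propagate_anchors(
    anchors: Sequence[AnchorSpec],
    n_sections: int,
    section_thickness_um: float | None = None,
    voxel_size_um: float | None = None,
    ap_axis: int = 0,
    propagate: str = "all",
) -> SectionMapping:
    """Interpolate anchor charts across the whole stack.

    Between consecutive anchors each of o, u, v is linearly interpolated
    component-wise by section index; outside the anchored range the nearest
    segment's linear trend is extrapolated.  With a single anchor, the
    origin advances by one section thickness (in atlas voxels) per section
    along ``ap_axis`` while u and v stay constant — that requires the
    physical calibration arguments.

    ``propagate="ap-only"`` interpolates the origin only and holds u and v
    at the nearest anchor's values.
    """
    anchors = sorted(anchors, key=lambda a: a.section_index)
    if not anchors:
        raise ValueError("at least one anchor is required")
    idx = [a.section_index for a in anchors]
    if len(set(idx)) != len(idx):
        raise ValueError(f"duplicate anchor section indices: {idx}")
    for a in anchors:
        if not 0 <= a.section_index < n_sections:
            raise IndexError(f"anchor section {a.section_index} outside the stack")

    sections = np.arange(n_sections, dtype=float)
    if len(anchors) == 1:
        a = anchors[0]
        if section_thickness_um is None or voxel_size_um is None:
            raise ValueError(
                "single-anchor propagation needs section_thickness_um and voxel_size_um"
            )
        step = section_thickness_um / voxel_size_um
        o = np.tile(a.o, (n_sections, 1))
        o[:, ap_axis] += (sections - a.section_index) * step
        return SectionMapping(o=o, u=np.tile(a.u, (n_sections, 1)), v=np.tile(a.v, (n_sections, 1)))

    xs = np.array(idx, dtype=float)
    def interp(vectors: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [_piecewise_linear(xs, vectors[:, c], sections) for c in range(3)]
        )

    o = interp(np.stack([a.o for a in anchors]))
    if propagate == "ap-only":
        nearest = np.array([idx[int(np.argmin(np.abs(xs - s)))] for s in sections])
        by_index = {a.section_index: a for a in anchors}
        u = np.stack([by_index[i].u for i in nearest])
        v = np.stack([by_index[i].v for i in nearest])
    elif propagate == "all":
        u = interp(np.stack([a.u for a in anchors]))
        v = interp(np.stack([a.v for a in anchors]))
    else:
        raise ValueError(f"unknown propagate mode {propagate!r}")
    return SectionMapping(o=o, u=u, v=v)


def pixel_to_atlas(
    chart: tuple[np.ndarray, np.ndarray, np.ndarray],
    x_px: float,
    y_px: float,
    width: int,
    height: int,
    convention: str = "corner",
) -> np.ndarray:
    """Map one pixel to continuous atlas voxel coordinates.

    ``p = o + (x/W) u + (y/H) v`` with the pixel-corner convention
    (x in [0, W)); ``convention="center"`` uses (x + 0.5)/W instead.
    """
    o, u, v = (np.asarray(c, dtype=float) for c in chart)
    if not (0 <= x_px < width and 0 <= y_px < height):
        raise ValueError(f"pixel ({x_px}, {y_px}) outside {width}x{height} image")
    if convention == "center":
        fx, fy = (x_px + 0.5) / width, (y_px + 0.5) / height
    elif convention == "corner":
        fx, fy = x_px / width, y_px / height
    else:
        raise ValueError(f"unknown pixel convention {convention!r}")
    return o + fx * u + fy * v


def assign_hemisphere(
    midlines: dict[int, np.ndarray],
    section_index: int,
    x_px: float,
    y_px: float,
) -> str:
    """Left/right from the signed offset to the delineated midline.

    ``midlines`` maps section index to an (N, 2) polyline of (x, y) points
    spanning the section top-to-bottom.  A section without its own polyline
    inherits the nearest delineated section's.  With no polyline anywhere
    the hemisphere is ``"unassigned"``.  A detection exactly on the line is
    assigned to the right (deterministic tie-break).
    """
    if not midlines:
        return "unassigned"
    if section_index in midlines:
        poly = midlines[section_index]
    else:
        nearest = min(midlines, key=lambda s: abs(s - section_index))
        poly = midlines[nearest]
    poly = np.asarray(poly, dtype=float)
    order = np.argsort(poly[:, 1])
    ys, xs = poly[order, 1], poly[order, 0]
    x_mid = float(np.interp(y_px, ys, xs))
    return "left" if x_px < x_mid else "right"


def write_anchors(anchors: Sequence[AnchorSpec], path: str | Path) -> None:
    payload = [
        {
            "section_index": a.section_index,
            "ox": a.o[0], "oy": a.o[1], "oz": a.o[2],
            "ux": a.u[0], "uy": a.u[1], "uz": a.u[2],
            "vx": a.v[0], "vy": a.v[1], "vz": a.v[2],
        }
        for a in anchors
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_anchors(path: str | Path) -> list[AnchorSpec]:
    payload = json.loads(Path(path).read_text())
    return [
        AnchorSpec(
            section_index=int(d["section_index"]),
            o=[d["ox"], d["oy"], d["oz"]],
            u=[d["ux"], d["uy"], d["uz"]],
            v=[d["vx"], d["vy"], d["vz"]],
        )
        for d in payload
    ]


def write_midlines(midlines: dict[int, np.ndarray], path: str | Path) -> None:
    payload = {str(k): np.asarray(v, dtype=float).tolist() for k, v in midlines.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_midlines(path: str | Path) -> dict[int, np.ndarray]:
    payload = json.loads(Path(path).read_text())
    return {int(k): np.asarray(v, dtype=float) for k, v in payload.items()}
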