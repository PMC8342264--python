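"""Serial block-face stack I/O, midline rotation, rigid alignment, brain volume.

A block-face stack is an ordered series of coronal images of the cut tissue
surface, photographed before each vibratome section is removed.  Physical
calibration (um/pixel in-plane, section thickness along the cutting axis)
travels with the images so downstream steps can convert between pixels,
micrometres and atlas voxels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage, optimize
from skimage import transform as sktransform
from skimage.registration import phase_cross_correlation


class DimensionMismatchError(ValueError):
    """Sections in one series do not share a single width/height."""


@dataclass
class RigidTransform2D:
    """Rotation about the image centre followed by a translation, in pixels.

    ``rotation_deg`` is counter-clockwise in standard (x right, y down)
    image coordinates; ``translation`` is ``(dx, dy)`` applied after the
    rotation.  Applying the transform maps a *moving* image onto its
    reference frame.
    """

    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def matrix(self, shape: tuple[int, int]) -> np.ndarray:
        """3x3 homogeneous matrix mapping (x, y, 1) source -> target."""
        h, w = shape[:2]
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        theta = np.deg2rad(self.rotation_deg)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        to_centre = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
        back = np.array(
            [
                [1, 0, cx + self.translation[0]],
                [0, 1, cy + self.translation[1]],
                [0, 0, 1.0],
            ]
        )
        return back @ rot @ to_centre

    @classmethod
    def from_matrix(cls, m: np.ndarray, shape: tuple[int, int]) -> "RigidTransform2D":
        angle = np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))
        h, w = shape[:2]
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        centre = np.array([cx, cy, 1.0])
        mapped = m @ centre
        return cls(rotation_deg=float(angle), translation=(float(mapped[0] - cx), float(mapped[1] - cy)))

    def compose(self, other: "RigidTransform2D", shape: tuple[int, int]) -> "RigidTransform2D":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform2D.from_matrix(self.matrix(shape) @ other.matrix(shape), shape)

    def inverse(self, shape: tuple[int, int]) -> "RigidTransform2D":
        return RigidTransform2D.from_matrix(np.linalg.inv(self.matrix(shape)), shape)

    def apply_points(self, points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        homo = np.column_stack([pts, np.ones(len(pts))])
        return (self.matrix(shape) @ homo.T).T[:, :2]


@dataclass
class BlockfaceStack:
    """Ordered serial 2D sections with physical calibration.

    ``sections`` is a (n, H, W) or (n, H, W, 3) uint8 array, anterior first.
    """

    sections: np.ndarray
    pixel_size_um: float
    section_thickness_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sections = np.asarray(self.sections)
        if self.sections.ndim not in (3, 4):
            raise ValueError("sections must be a (n, H, W[, C]) array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.section_thickness_um <= 0:
            raise ValueError("section_thickness_um must be > 0")

    @property
    def n_sections(self) -> int:
        return self.sections.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.sections.shape[1], self.sections.shape[2]

    @property
    def is_rgb(self) -> bool:
        return self.sections.ndim == 4

    def __len__(self) -> int:
        return self.n_sections

    def __getitem__(self, i: int) -> np.ndarray:
        return self.sections[i]

    def grayscale(self) -> np.ndarray:
        """Max over channels, float (n, H, W); identity for single-channel."""
        if self.is_rgb:
            return self.sections.max(axis=-1).astype(float)
        return self.sections.astype(float)

    def green(self) -> np.ndarray:
        """Green channel (n, H, W) uint8; the sphere fluorescence channel."""
        if self.is_rgb:
            return self.sections[..., 1]
        return self.sections

    def with_sections(self, sections: np.ndarray) -> "BlockfaceStack":
        return BlockfaceStack(
            sections=sections,
            pixel_size_um=self.pixel_size_um,
            section_thickness_um=self.section_thickness_um,
            metadata=dict(self.metadata),
        )


def read_image_series(
    paths: Sequence[str | Path],
    pixel_size_um: float,
    section_thickness_um: float,
) -> BlockfaceStack:
    """Read an ordered file series into a stack; section order = input order."""
    images = []
    for p in paths:
        p = Path(p)
        try:
            img = iio.imread(p)
        except Exception as exc:  # plugins raise a zoo of error types
            raise OSError(f"could not read image file {p}") from exc
        if img.ndim == 3 and img.shape[-1] == 4:  # drop alpha
            img = img[..., :3]
        images.append(img)
    if not images:
        raise ValueError("empty path list")
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise DimensionMismatchError(f"sections have mixed dimensions: {sorted(shapes)}")
    return BlockfaceStack(
        sections=np.stack(images),
        pixel_size_um=pixel_size_um,
        section_thickness_um=section_thickness_um,
        metadata={"paths": [str(p) for p in paths]},
    )


def write_stack(stack: BlockfaceStack, path: str | Path) -> None:
    """Write the stack as a multi-page TIFF."""
    tifffile.imwrite(str(path), stack.sections)


def read_stack(path: str | Path, pixel_size_um: float, section_thickness_um: float) -> BlockfaceStack:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    return BlockfaceStack(tifffile.imread(str(path)), pixel_size_um, section_thickness_um)


def write_transforms(transforms: Sequence[RigidTransform2D], path: str | Path) -> None:
    payload = [
        {"rotation_deg": t.rotation_deg, "dx": t.translation[0], "dy": t.translation[1]}
        for t in transforms
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_transforms(path: str | Path) -> list[RigidTransform2D]:
    payload = json.loads(Path(path).read_text())
    return [RigidTransform2D(d["rotation_deg"], (d["dx"], d["dy"])) for d in payload]


def midline_rotation_angle(midline: Sequence[Sequence[float]]) -> float:
    """Rotation (deg, CCW) that makes the drawn midline vertical."""
    (x1, y1), (x2, y2) = midline
    if x1 == x2 and y1 == y2:
        raise ValueError("invalid midline: the two points coincide")
    # angle of the line away from the vertical axis; rotating the image by
    # this angle (CCW, y-down coordinates) brings the line onto a vertical.
    return float(np.rad2deg(np.arctan2(x2 - x1, y2 - y1)))


def _warp(image: np.ndarray, t: RigidTransform2D, output_shape: tuple[int, int], order: int) -> np.ndarray:
    """Apply ``t`` (source -> target) to an image, preserving dtype."""
    inv = np.linalg.inv(t.matrix(image.shape[:2]))
    tform = sktransform.AffineTransform(matrix=inv)
    out = sktransform.warp(
        image.astype(float), tform, output_shape=output_shape, order=order,
        mode="constant", cval=0.0, preserve_range=True,
    )
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(image.dtype)


def apply_rigid(image: np.ndarray, t: RigidTransform2D, order: int = 1) -> np.ndarray:
    """Apply a rigid transform to one image (same canvas size).

    ``order=0`` (nearest neighbour) must be used for binary masks so they
    stay binary; ``order=1`` (bilinear) for intensity images.
    """
    if image.ndim == 3:
        return np.stack(
            [_warp(image[..., c], t, image.shape[:2], order) for c in range(image.shape[-1])],
            axis=-1,
        )
    return _warp(image, t, image.shape[:2], order)


def rotate_stack_by_midline(
    stack: BlockfaceStack,
    midline: Sequence[Sequence[float]],
    order: int = 1,
) -> tuple[BlockfaceStack, float]:
    """Rotate every section so a user-drawn midline becomes vertical.

    One rotation angle is computed from the two midline points (drawn on any
    single section) and applied identically to all sections.  The canvas is
    expanded (black fill) so no pixel of any section is clipped; anchors and
    atlas mappings must therefore be specified on the rotated images.

    Returns the rotated stack and the applied angle in degrees CCW.
    """
    angle = midline_rotation_angle(midline)
    h, w = stack.frame_shape
    t = RigidTransform2D(rotation_deg=angle)
    # bounding box of the rotated frame corners -> padded canvas
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
    mapped = t.apply_points(corners, (h, w))
    mins = mapped.min(axis=0)
    maxs = mapped.max(axis=0)
    out_w = int(np.ceil(maxs[0] - mins[0])) + 1
    out_h = int(np.ceil(maxs[1] - mins[1])) + 1
    # shift so the rotated content starts at (0, 0) of the new canvas
    shift = RigidTransform2D(translation=(-float(mins[0]), -float(mins[1])))
    full = shift.compose(t, (h, w))
    rotated = []
    for i in range(stack.n_sections):
        img = stack.sections[i]
        if img.ndim == 3:
            rotated.append(
                np.stack(
                    [_warp(img[..., c], full, (out_h, out_w), order) for c in range(img.shape[-1])],
                    axis=-1,
                )
            )
        else:
            rotated.append(_warp(img, full, (out_h, out_w), order))
    out = stack.with_sections(np.stack(rotated))
    out.metadata["midline_rotation_deg"] = angle
    return out, angle


def register_rigid(
    fixed: np.ndarray,
    moving: np.ndarray,
    max_rotation_deg: float = 10.0,
    upsample_factor: int = 20,
    angle_tol_deg: float = 0.02,
    smooth_sigma: float = 1.0,
) -> RigidTransform2D:
    """Recover the rigid transform mapping ``moving`` onto ``fixed``.

    Translation comes from sub-pixel phase correlation; rotation from a
    bounded scalar optimisation over the angle of the normalised RMS error
    left after the best shift, i.e. intensity-similarity maximisation under
    rotation+translation only (no scaling or shear).  Both images are
    mildly Gaussian-smoothed first: interpolation during the trial
    rotations low-passes the image, which on unsmoothed noisy data lowers
    the error metric for spurious small angles; smoothing removes that
    bias.  A nonzero rotation is only accepted when it beats angle 0.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if not np.any(moving) or not np.any(fixed):
        warnings.warn("all-black section encountered; returning identity transform")
        return RigidTransform2D()
    if smooth_sigma > 0:
        fs = ndimage.gaussian_filter(fixed, smooth_sigma)
        ms = ndimage.gaussian_filter(moving, smooth_sigma)
    else:
        fs, ms = fixed, moving
    norm = float(np.sqrt(np.mean(fs**2)))

    def shift_at(angle: float) -> tuple[np.ndarray, tuple[float, float]]:
        rot = ms if angle == 0.0 else _warp(ms, RigidTransform2D(rotation_deg=angle), ms.shape, order=1)
        shift, _, _ = phase_cross_correlation(
            fs, rot, upsample_factor=upsample_factor, normalization=None
        )
        return rot, (float(shift[1]), float(shift[0]))  # skimage returns (dy, dx)

    def residual(angle: float) -> float:
        rot, (dx, dy) = shift_at(angle)
        aligned = _warp(rot, RigidTransform2D(translation=(dx, dy)), rot.shape, order=1)
        return float(np.sqrt(np.mean((fs - aligned) ** 2)) / norm)

    angle = 0.0
    if max_rotation_deg > 0:
        res = optimize.minimize_scalar(
            residual,
            bounds=(-max_rotation_deg, max_rotation_deg),
            method="bounded",
            options={"xatol": angle_tol_deg},
        )
        if float(res.fun) < residual(0.0):  # don't invent a rotation for pure shifts
            angle = float(res.x)
    _, (dx, dy) = shift_at(angle)
    return RigidTransform2D(rotation_deg=angle, translation=(dx, dy))


def rigid_align_stack(
    stack: BlockfaceStack,
    reference: int | None = None,
    max_rotation_deg: float = 10.0,
    order: int = 1,
) -> tuple[BlockfaceStack, list[RigidTransform2D]]:
    """Register every section to its predecessor and chain to a reference.

    Each consecutive pair is registered (rotation + translation only) and
    the pairwise transforms are composed so every section is expressed in
    the reference section's frame.  The middle section is the default
    reference, halving drift accumulation relative to chaining from one end.

    Returns the aligned stack and the per-section transforms that reproduce
    the alignment when re-applied to the original sections.
    """
    n = stack.n_sections
    if n < 2:
        raise ValueError("need at least 2 sections to align")
    if reference is None:
        reference = n // 2
    if not 0 <= reference < n:
        raise IndexError("reference section out of range")
    gray = stack.grayscale()
    shape = stack.frame_shape
    transforms: list[RigidTransform2D] = [RigidTransform2D() for _ in range(n)]
    # forward from the reference
    for i in range(reference + 1, n):
        pair = register_rigid(gray[i - 1], gray[i], max_rotation_deg=max_rotation_deg)
        transforms[i] = transforms[i - 1].compose(pair, shape)
    # backward from the reference
    for i in range(reference - 1, -1, -1):
        pair = register_rigid(gray[i + 1], gray[i], max_rotation_deg=max_rotation_deg)
        transforms[i] = transforms[i + 1].compose(pair, shape)
    aligned = np.stack([apply_rigid(stack.sections[i], transforms[i], order=order) for i in range(n)])
    return stack.with_sections(aligned), transforms


def compute_brain_volume(stack: BlockfaceStack, foreground_threshold: int = 15) -> float:
    """Whole-brain volume (mm^3) from section areas x thickness.

    Foreground pixels are those brighter than ``foreground_threshold`` on
    the max-over-channels image; the preparation guarantees a black
    background (ink-darkened embedding), so a low global threshold isolates
    tissue.  Volume = sum over sections of foreground area x thickness.
    """
    gray = stack.grayscale()
    counts = (gray > foreground_threshold).sum(axis=(1, 2))
    vol_um3 = float(counts.sum()) * stack.pixel_size_um**2 * stack.section_thickness_um
    return vol_um3 / 1e9
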