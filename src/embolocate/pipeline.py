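"""End-to-end localization: stack -> detections -> atlas regions -> report.

Thin orchestration over the stage modules, in the order the workflow runs
at the bench: (optionally) rigidly align the serial images, threshold the
green channel, resolve each sphere's true section by serial subtraction,
extract centroids, map them through the per-section atlas charts, look up
structures, and compile the hierarchical region report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging_io import BlockfaceStack, rigid_align_stack
from .detection import (
    DEFAULT_SPHERE_DIAMETER_UM,
    DEFAULT_THRESHOLD_LOW,
    DEFAULT_VISIBILITY_DEPTH_UM,
    detections_to_frame,
    extract_centroids,
    resolve_z_by_serial_subtraction,
    threshold_microspheres,
)
from .atlas_registration import SectionMapping, assign_hemisphere, pixel_to_atlas
from .ontology_assignment import (
    AnnotationVolume,
    AtlasOntology,
    RegionReport,
    UNACCOUNTED,
    assign_region,
    compile_report,
)


@dataclass
class PipelineResult:
    detections: pd.DataFrame
    report: RegionReport | None
    transforms: list | None


def detect_microspheres(
    stack: BlockfaceStack,
    threshold_low: int = DEFAULT_THRESHOLD_LOW,
    match_radius_um: float = DEFAULT_SPHERE_DIAMETER_UM,
    subtract_mode: str = "component",
    align: bool = False,
    max_rotation_deg: float = 5.0,
) -> tuple[pd.DataFrame, list | None]:
    """Detections (id, section, x, y) from a raw or pre-aligned stack."""
    transforms = None
    if align and stack.n_sections >= 2:
        stack, transforms = rigid_align_stack(stack, max_rotation_deg=max_rotation_deg)
    masks = [threshold_microspheres(stack[i], low=threshold_low) for i in range(stack.n_sections)]
    match_radius_px = match_radius_um / stack.pixel_size_um
    max_chain = int(math.ceil(DEFAULT_VISIBILITY_DEPTH_UM / stack.section_thickness_um))
    final = resolve_z_by_serial_subtraction(
        masks, match_radius_px=match_radius_px, mode=subtract_mode,
        max_chain_sections=max_chain,
    )
    detections = extract_centroids(final, pixel_size_um=stack.pixel_size_um)
    return detections_to_frame(detections), transforms


def localize_microspheres(
    stack: BlockfaceStack,
    mapping: SectionMapping,
    ontology: AtlasOntology | None = None,
    annotation: AnnotationVolume | None = None,
    midlines: dict[int, np.ndarray] | None = None,
    threshold_low: int = DEFAULT_THRESHOLD_LOW,
    match_radius_um: float = DEFAULT_SPHERE_DIAMETER_UM,
    subtract_mode: str = "component",
    align: bool = False,
    max_rotation_deg: float = 5.0,
    min_count: int = 5,
    max_level: int | None = None,
) -> PipelineResult:
    """Run the full workflow and return detections plus the region report.

    The detections table gains atlas coordinates (``ax, ay, az``),
    ``hemisphere`` and, when an annotation volume and ontology are given,
    ``region_id`` and the compiled :class:`RegionReport`.
    """
    detections, transforms = detect_microspheres(
        stack,
        threshold_low=threshold_low,
        match_radius_um=match_radius_um,
        subtract_mode=subtract_mode,
        align=align,
        max_rotation_deg=max_rotation_deg,
    )
    h, w = stack.frame_shape
    coords = []
    hemis = []
    for _, row in detections.iterrows():
        s = int(row["section_index"])
        coords.append(
            pixel_to_atlas(mapping.chart(s), float(row["x_px"]), float(row["y_px"]), w, h)
        )
        hemis.append(
            assign_hemisphere(midlines or {}, s, float(row["x_px"]), float(row["y_px"]))
        )
    coords = np.array(coords).reshape(-1, 3)
    detections["ax"] = coords[:, 0] if len(coords) else []
    detections["ay"] = coords[:, 1] if len(coords) else []
    detections["az"] = coords[:, 2] if len(coords) else []
    detections["hemisphere"] = hemis

    report = None
    if annotation is not None:
        regions = [assign_region(c, annotation) for c in coords]
        detections["region_id"] = regions
        if ontology is not None:
            report = compile_report(
                regions, ontology, annotation, min_count=min_count, max_level=max_level
            )
    return PipelineResult(detections=detections, report=report, transforms=transforms)
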