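"""Whole-image measurement pipeline: segment, trace, project, orient.

``measure_image`` runs preprocessing, candidate detection, heuristic
classification, midline extraction, focus/centromere projection and
orientation for one three-channel image, and returns both the per-bivalent
measurements and the intermediate products needed for overlays and
straightened renderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._skeleton import DegenerateSkeletonError
from .foci import (
    BivalentMeasurement,
    FociParams,
    background_stats,
    detect_foci,
    locate_centromere,
    orient_and_normalize,
)
from .midline import DEFAULT_PX_PER_UM, Midline, MidlineParams, extract_midline, to_micrometers
from .segment import CandidateObject, SegmentationParams, classify_bivalent, detect_objects, preprocess

MEASUREMENT_COLUMNS = [
    "cell_id",
    "object_index",
    "sc_length_px",
    "sc_length_um",
    "centromere_pos_norm",
    "foci_pos_norm",
    "n_foci",
    "flags",
    # extras used for matching, curation and diagnostics
    "centromere_pos_px",
    "foci_pos_px",
    "foci_offset_px",
    "branch_points",
    "skeleton_length_px",
    "centroid_r",
    "centroid_c",
]


@dataclass
class MeasureResult:
    cell_id: str
    measurements: list[BivalentMeasurement]
    objects: list[CandidateObject]
    classifications: list[tuple[bool, str | None]]
    preprocessed: np.ndarray
    midlines: dict[int, Midline] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return measurements_frame(self.measurements)


def measure_image(
    image: np.ndarray,
    cell_id: str = "cell",
    *,
    segmentation: SegmentationParams | None = None,
    midline_params: MidlineParams | None = None,
    foci_params: FociParams | None = None,
    px_per_um: float = DEFAULT_PX_PER_UM,
) -> MeasureResult:
    """Measure all passing bivalents in a (3, H, W) red/green/blue image."""
    segmentation = segmentation or SegmentationParams()
    midline_params = midline_params or MidlineParams()
    foci_params = foci_params or FociParams()

    pre = preprocess(image)
    red, green, blue = pre
    objects = detect_objects(red, segmentation)
    classifications = [classify_bivalent(o, segmentation) for o in objects]

    shape = red.shape
    all_mask = np.zeros(shape, dtype=bool)
    for o in objects:
        all_mask |= o.full_mask(shape)
    bg_green = background_stats(green, all_mask)
    bg_blue = background_stats(blue, all_mask)

    measurements: list[BivalentMeasurement] = []
    midlines: dict[int, Midline] = {}
    for obj, (passed, _reason) in zip(objects, classifications):
        if not passed:
            continue
        mask = obj.full_mask(shape)
        try:
            ml = extract_midline(mask, midline_params)
        except DegenerateSkeletonError:
            continue
        midlines[obj.object_index] = ml
        detections = detect_foci(green, ml, foci_params, bg_green)
        cpos, cflags = locate_centromere(blue, ml, foci_params, bg_blue)
        raw = BivalentMeasurement(
            cell_id=cell_id,
            object_index=obj.object_index,
            sc_length_px=ml.total_length_px,
            sc_length_um=to_micrometers(ml.total_length_px, px_per_um),
            centromere_pos_px=cpos,
            foci_pos_px=tuple(d.arc_px for d in detections),
            foci_offset_px=tuple(d.offset_px for d in detections),
            flags=cflags,
            branch_points=obj.branch_points,
            skeleton_length_px=obj.skeleton_length_px,
            centroid=obj.centroid,
        )
        measurements.append(orient_and_normalize(raw))
    return MeasureResult(
        cell_id=cell_id,
        measurements=measurements,
        objects=objects,
        classifications=classifications,
        preprocessed=pre,
        midlines=midlines,
    )


def measurements_frame(measurements: list[BivalentMeasurement]) -> pd.DataFrame:
    """Per-bivalent measurement table (one row per passing bivalent)."""
    rows = []
    for m in measurements:
        rows.append({
            "cell_id": m.cell_id,
            "object_index": m.object_index,
            "sc_length_px": m.sc_length_px,
            "sc_length_um": m.sc_length_um,
            "centromere_pos_norm": m.centromere_pos_norm,
            "foci_pos_norm": ";".join(f"{p:.6f}" for p in m.foci_pos_norm),
            "n_foci": m.n_foci,
            "flags": ";".join(sorted(m.flags)),
            "centromere_pos_px": m.centromere_pos_px,
            "foci_pos_px": ";".join(f"{p:.3f}" for p in m.foci_pos_px),
            "foci_offset_px": ";".join(f"{p:.3f}" for p in m.foci_offset_px),
            "branch_points": m.branch_points,
            "skeleton_length_px": m.skeleton_length_px,
            "centroid_r": m.centroid[0],
            "centroid_c": m.centroid[1],
        })
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
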