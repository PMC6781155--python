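"""Candidate-bivalent segmentation on the synaptonemal-complex (red) channel.

Objects are connected components of the thresholded, morphologically cleaned
red channel. Each candidate carries the shape features used by the heuristic
bivalent classifier: pachytene bivalents are elongated, solid, unbranched
ribbons away from the image border. The whole-image overlay draws a box
around every candidate and an index only at objects that pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk, skeletonize

from ._skeleton import (
    DegenerateSkeletonError,
    branch_points,
    longest_geodesic_path,
    pixel_graph,
    prune_spurs,
)


@dataclass
class SegmentationParams:
    """Threshold and heuristic criteria for the bivalent classifier.

    The default shape criteria make the "elongated ribbon" notion explicit:
    area within [min_area, max_area] px^2, pruned-skeleton length within
    [min_skeleton_len, max_skeleton_len] px, eccentricity and solidity
    minima, no residual branch points after spur pruning, and a clear
    border margin. All are configurable.
    """

    threshold_method: str = "otsu"
    threshold_offset: float = 0.0
    robust_k: float = 6.0
    smooth_sigma: float = 1.0
    min_detect_area: int = 20
    min_area: int = 150
    max_area: int = 6000
    min_skeleton_len: float = 30.0
    max_skeleton_len: float = 400.0
    min_eccentricity: float = 0.85
    min_solidity: float = 0.25
    max_branch_points: int = 0
    border_margin: int = 3
    spur_px: float = 5.0

    def validate(self) -> None:
        if self.min_area >= self.max_area:
            raise ValueError("min_area must be < max_area")
        if self.min_skeleton_len >= self.max_skeleton_len:
            raise ValueError("min_skeleton_len must be < max_skeleton_len")


@dataclass
class CandidateObject:
    object_index: int
    pixel_mask: np.ndarray  # cropped to bounding box
    bounding_box: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    area_px: int
    skeleton_length_px: float
    eccentricity: float
    solidity: float
    branch_points: int
    touches_border: bool
    centroid: tuple[float, float] = (0.0, 0.0)

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bounding_box
        out[r0:r1, c0:c1] = self.pixel_mask
        return out


def preprocess(image: np.ndarray) -> np.ndarray:
    """Per-channel illumination correction and intensity rescaling.

    Fits and subtracts a least-squares plane (removing constant background
    and linear illumination gradients exactly), then min-max rescales to
    [0, 1]. The operation is idempotent: a second application reproduces its
    input to floating-point precision. Constant channels map to zero.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[0] != 3:
        raise ValueError("expected a (3, H, W) three-channel image")
    h, w = img.shape[1:]
    rr, cc = np.mgrid[0:h, 0:w]
    basis = np.column_stack([np.ones(h * w), rr.ravel() / max(h - 1, 1), cc.ravel() / max(w - 1, 1)])
    out = np.empty_like(img)
    for ch in range(3):
        y = img[ch].ravel()
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        resid = y - basis @ coef
        lo, hi = resid.min(), resid.max()
        # guard scales with the input so a constant channel maps to zero
        floor = 1e-9 * max(1.0, float(np.abs(y).max()))
        out[ch] = ((resid - lo) / (hi - lo)).reshape(h, w) if hi - lo > floor else 0.0
    return out


def _object_features(mask: np.ndarray, params: SegmentationParams) -> tuple[float, int]:
    """(pruned skeleton length, residual branch-point count) for one mask."""
    skel = skeletonize(mask)
    if skel.sum() < 2:
        return float(skel.sum()), 0
    g = prune_spurs(pixel_graph(skel), params.spur_px)
    if g.number_of_nodes() < 2:
        return float(g.number_of_nodes()), 0
    try:
        _path, length = longest_geodesic_path(g)
    except DegenerateSkeletonError:
        length = 0.0
    return length, len(branch_points(g))


def detect_objects(sc_channel: np.ndarray, params: SegmentationParams | None = None) -> list[CandidateObject]:
    """Connected components of the thresholded, cleaned SC channel.

    The threshold is the larger of Otsu's value and a robust background bound
    (median + robust_k * 1.4826 * MAD), plus a configurable offset, so that a
    signal-free image yields no objects. Components are enumerated row-major
    by bounding-box origin; indices are 1-based.
    """
    params = params or SegmentationParams()
    params.validate()
    sc = np.asarray(sc_channel, dtype=float)
    sm = gaussian(sc, sigma=params.smooth_sigma, preserve_range=True) if params.smooth_sigma > 0 else sc
    med = float(np.median(sm))
    mad = float(np.median(np.abs(sm - med)))
    robust = med + params.robust_k * 1.4826 * mad
    try:
        otsu = float(threshold_otsu(sm))
    except ValueError:  # constant image
        return []
    thr = max(otsu, robust) + params.threshold_offset
    mask = sm > thr
    if not mask.any():
        return []
    mask = ndi.binary_closing(mask, structure=disk(1))
    mask = ndi.binary_fill_holes(mask)
    lab = label(mask, connectivity=2)
    h, w = mask.shape
    objs = []
    for rp in regionprops(lab):
        if rp.area < params.min_detect_area:
            continue
        r0, c0, r1, c1 = rp.bbox
        skel_len, n_branch = _object_features(rp.image, params)
        m = params.border_margin
        objs.append(CandidateObject(
            object_index=0,
            pixel_mask=rp.image.copy(),
            bounding_box=(r0, c0, r1, c1),
            area_px=int(rp.area),
            skeleton_length_px=skel_len,
            eccentricity=float(rp.eccentricity),
            solidity=float(rp.solidity),
            branch_points=n_branch,
            touches_border=bool(r0 < m or c0 < m or r1 > h - m or c1 > w - m),
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
        ))
    objs.sort(key=lambda o: (o.bounding_box[0], o.bounding_box[1]))
    for i, o in enumerate(objs, start=1):
        o.object_index = i
    return objs


# criterion order is part of the contract: the first violated criterion is
# reported as the fail reason
_CRITERIA = (
    ("area_min", lambda o, p: o.area_px >= p.min_area),
    ("area_max", lambda o, p: o.area_px <= p.max_area),
    ("skeleton_min", lambda o, p: o.skeleton_length_px >= p.min_skeleton_len),
    ("skeleton_max", lambda o, p: o.skeleton_length_px <= p.max_skeleton_len),
    ("eccentricity", lambda o, p: o.eccentricity >= p.min_eccentricity),
    ("solidity", lambda o, p: o.solidity >= p.min_solidity),
    ("branch_points", lambda o, p: o.branch_points <= p.max_branch_points),
    ("border", lambda o, p: not o.touches_border),
)


def classify_bivalent(obj: CandidateObject, params: SegmentationParams | None = None) -> tuple[bool, str | None]:
    """Pass/fail against the heuristic criteria plus the first failing one."""
    params = params or SegmentationParams()
    for name, ok in _CRITERIA:
        if not ok(obj, params):
            return False, name
    return True, None


def annotate_overlay(
    image: np.ndarray,
    objects: list[CandidateObject],
    classifications: list[tuple[bool, str | None]],
) -> tuple[np.ndarray, list[dict]]:
    """Whole-image overlay: a box around every object, an index at passing ones.

    Returns (RGB uint8 overlay with the input's spatial dimensions, a list of
    annotation records {object_index, bbox, labelled}).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[0] != 3:
        raise ValueError("expected a (3, H, W) three-channel image")
    scale = max(float(img.max()), 1e-12)
    rgb = np.moveaxis(np.clip(img / scale, 0, 1) * 255, 0, -1).astype(np.uint8)
    pil = Image.fromarray(rgb)
    draw = ImageDraw.Draw(pil)
    annotations = []
    for obj, (passed, _reason) in zip(objects, classifications):
        r0, c0, r1, c1 = obj.bounding_box
        draw.rectangle([c0, r0, c1 - 1, r1 - 1], outline=(255, 80, 80))
        if passed:
            draw.text((c0 + 2, max(r0 - 12, 0)), str(obj.object_index), fill=(255, 255, 0))
        annotations.append({
            "object_index": obj.object_index,
            "bbox": obj.bounding_box,
            "labelled": bool(passed),
        })
    return np.asarray(pil), annotations
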