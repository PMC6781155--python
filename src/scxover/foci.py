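"""MLH1 focus and centromere detection on the midline arc coordinate.

True MLH1 foci are distinguished from background by intensity (local maxima
above the background mean plus ``k_sigma`` background SDs) and by placement
within the width of the SC (inside a ribbon of ``ribbon_half_width`` px
around the midline). Detected peaks are projected to the nearest arc
position; peaks closer than ``min_separation_px`` along the arc are merged
to their intensity-weighted centroid. After detection, each bivalent is
oriented so its centromere lies in the proximal half (arc coordinate 0 at
the centromere-proximal end) and positions are normalized by SC length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .midline import Midline


@dataclass
class FociParams:
    k_sigma: float = 4.0
    ribbon_half_width: float = 6.0
    min_separation_px: float = 5.0
    min_peak_distance: int = 3
    smooth_sigma: float = 1.0


@dataclass
class FocusDetection:
    arc_px: float
    offset_px: float  # perpendicular distance from the midline
    peak_value: float


@dataclass
class BivalentMeasurement:
    """One bivalent's SC length, centromere and ordered foci arc positions."""

    cell_id: str
    object_index: int
    sc_length_px: float
    sc_length_um: float
    centromere_pos_px: float | None
    foci_pos_px: tuple[float, ...]
    foci_offset_px: tuple[float, ...] = ()
    flags: frozenset[str] = frozenset()
    branch_points: int = 0
    skeleton_length_px: float = 0.0
    centroid: tuple[float, float] = (0.0, 0.0)
    oriented: bool = False

    @property
    def n_foci(self) -> int:
        return len(self.foci_pos_px)

    @property
    def centromere_pos_norm(self) -> float | None:
        if self.centromere_pos_px is None:
            return None
        return self.centromere_pos_px / self.sc_length_px

    @property
    def foci_pos_norm(self) -> tuple[float, ...]:
        return tuple(p / self.sc_length_px for p in self.foci_pos_px)


@dataclass
class CellRecord:
    """Per-spermatocyte record of counts and manual quality-control fields."""

    mouse_id: str
    cell_id: str
    mlh1_total: int
    n_zero_foci_bivalents: int
    n_asynapsis_bivalents: int = 0
    quality: int = 1  # 1 (high) .. 5 (low)
    xy_paired: bool = True
    par_focus: bool = True

    def __post_init__(self):
        if not 1 <= int(self.quality) <= 5:
            raise ValueError("quality must be an integer in 1..5")
        if min(self.mlh1_total, self.n_zero_foci_bivalents, self.n_asynapsis_bivalents) < 0:
            raise ValueError("counts must be non-negative")


def background_stats(channel: np.ndarray, object_mask: np.ndarray,
                     dilate_px: int = 5) -> tuple[float, float]:
    """Mean and SD of a channel outside all (dilated) object masks."""
    bg = ~binary_dilation(object_mask.astype(bool), structure=disk(dilate_px))
    vals = np.asarray(channel, dtype=float)[bg]
    if vals.size == 0:
        vals = np.asarray(channel, dtype=float).ravel()
    return float(vals.mean()), float(vals.std())


def _arc_and_offset(points: np.ndarray, midline: Midline) -> tuple[np.ndarray, np.ndarray]:
    tree = cKDTree(midline.points)
    d, idx = tree.query(np.atleast_2d(points))
    return midline.cum_arc_px[idx], d


def _ribbon_region(midline: Midline, shape: tuple[int, int], half_width: float) -> np.ndarray:
    pad = int(np.ceil(half_width)) + 1
    r0 = max(int(midline.points[:, 0].min()) - pad, 0)
    r1 = min(int(midline.points[:, 0].max()) + pad, shape[0] - 1)
    c0 = max(int(midline.points[:, 1].min()) - pad, 0)
    c1 = min(int(midline.points[:, 1].max()) + pad, shape[1] - 1)
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d, _ = cKDTree(midline.points).query(grid, workers=-1)
    mask = np.zeros(shape, dtype=bool)
    mask[rr.ravel()[d <= half_width], cc.ravel()[d <= half_width]] = True
    return mask


def detect_foci(
    green_channel: np.ndarray,
    midline: Midline,
    params: FociParams | None = None,
    background: tuple[float, float] | None = None,
) -> list[FocusDetection]:
    """Foci arc positions for one bivalent, sorted along the arc."""
    params = params or FociParams()
    green = np.asarray(green_channel, dtype=float)
    if background is None:
        background = (float(np.median(green)), float(green.std()))
    bg_mean, bg_sd = background
    thr = bg_mean + params.k_sigma * max(bg_sd, 1e-12)
    sm = gaussian(green, sigma=params.smooth_sigma, preserve_range=True)
    ribbon = _ribbon_region(midline, green.shape, params.ribbon_half_width)
    peaks = peak_local_max(
        sm, min_distance=params.min_peak_distance, threshold_abs=thr,
        labels=ribbon.astype(int), exclude_border=False,
    )
    if len(peaks) == 0:
        return []
    arcs, offsets = _arc_and_offset(peaks.astype(float), midline)
    values = sm[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(arcs, kind="stable")
    arcs, offsets, values = arcs[order], offsets[order], values[order]

    # merge peaks closer than min_separation_px along the arc
    merged: list[FocusDetection] = []
    i = 0
    while i < len(arcs):
        j = i + 1
        while j < len(arcs) and arcs[j] - arcs[j - 1] < params.min_separation_px:
            j += 1
        wsum = values[i:j].sum()
        merged.append(FocusDetection(
            arc_px=float(np.average(arcs[i:j], weights=values[i:j])),
            offset_px=float(np.average(offsets[i:j], weights=values[i:j])),
            peak_value=float(wsum / (j - i)),
        ))
        i = j
    return merged


def locate_centromere(
    blue_channel: np.ndarray,
    midline: Midline,
    params: FociParams | None = None,
    background: tuple[float, float] | None = None,
) -> tuple[float | None, frozenset[str]]:
    """Arc position of the brightest in-ribbon centromere signal.

    Absent signal yields (None, {"no_centromere"}). When two maxima tie in
    brightness, the one nearer a bivalent end is chosen and the measurement
    is flagged "ambiguous_centromere".
    """
    params = params or FociParams()
    detections = detect_foci(blue_channel, midline, params, background)
    if not detections:
        return None, frozenset({"no_centromere"})
    values = np.array([d.peak_value for d in detections])
    top = values.max()
    # equally bright spots differ by ~1-2% after pixel sampling and
    # smoothing, so "equal maxima" means within 2% of the brightest
    ties = [d for d in detections if d.peak_value >= top * 0.98]
    flags: set[str] = set()
    if len(detections) > 1:
        # a single bivalent carries one centromere; several strong in-ribbon
        # signals are the signature of incorrectly merged bivalents
        flags.add("multiple_centromeres")
    if len(ties) > 1:
        flags.add("ambiguous_centromere")
        length = midline.total_length_px
        ties.sort(key=lambda d: min(d.arc_px, length - d.arc_px))
    return float(ties[0].arc_px), frozenset(flags)


def orient_and_normalize(measurement: BivalentMeasurement) -> BivalentMeasurement:
    """Reflect the arc coordinate so the centromere lies in the first half.

    If the centromere position exceeds half the SC length, every position is
    mapped x -> L - x and foci are re-sorted ascending (ordered by proximity
    to the centromere end). Orientation is an involution: applying it twice
    equals applying it once. With a missing centromere the measurement is
    returned unchanged apart from the `oriented` marker.
    """
    L = measurement.sc_length_px
    if L <= 0:
        raise ValueError("sc_length_px must be positive")
    if measurement.centromere_pos_px is None:
        return replace(measurement, oriented=True)
    if measurement.centromere_pos_px <= L / 2.0:
        foci = tuple(sorted(measurement.foci_pos_px))
        return replace(measurement, foci_pos_px=foci, oriented=True)
    order = np.argsort([L - p for p in measurement.foci_pos_px], kind="stable")
    foci = tuple(L - measurement.foci_pos_px[i] for i in order)
    offs = tuple(measurement.foci_offset_px[i] for i in order) if measurement.foci_offset_px else ()
    return replace(
        measurement,
        centromere_pos_px=L - measurement.centromere_pos_px,
        foci_pos_px=foci,
        foci_offset_px=offs,
        oriented=True,
    )


def assemble_cell_record(
    measurements: list[BivalentMeasurement],
    mouse_id: str,
    *,
    quality: int = 1,
    n_asynapsis_bivalents: int = 0,
    xy_paired: bool = True,
    par_focus: bool = True,
) -> CellRecord:
    """Tally per-cell MLH1 totals and zero-foci bivalents from measurements."""
    if not measurements:
        raise ValueError("no measurements to assemble")
    cell_ids = {m.cell_id for m in measurements}
    if len(cell_ids) != 1:
        raise ValueError("measurements must share a single cell_id")
    return CellRecord(
        mouse_id=mouse_id,
        cell_id=cell_ids.pop(),
        mlh1_total=int(sum(m.n_foci for m in measurements)),
        n_zero_foci_bivalents=int(sum(1 for m in measurements if m.n_foci == 0)),
        n_asynapsis_bivalents=n_asynapsis_bivalents,
        quality=quality,
        xy_paired=xy_paired,
        par_focus=par_focus,
    )
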