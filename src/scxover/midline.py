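"""Sub-pixel midline extraction, SC length, and ribbon straightening.

SC length is quantified as the length of the straightened midline: the mask
is skeletonized, side branches shorter than the spur threshold are pruned,
the longest geodesic path between skeleton endpoints is taken as the axis,
a smoothing spline is fitted (stiffness relaxed until the curve deviates
from the skeleton by at most ``max_spline_dev`` px), the curve is extended
to the mask boundary at both ends (skeletons recede from ribbon tips by
about half the ribbon width), and the result is resampled at a fixed arc
step. The reported length is the integrated length of that curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import splev, splprep
from scipy.ndimage import map_coordinates
from skimage.morphology import skeletonize

from ._skeleton import DegenerateSkeletonError, longest_geodesic_path, pixel_graph, prune_spurs

DEFAULT_PX_PER_UM = 9.8152  # instrument-specific translation factor; overridable


@dataclass
class MidlineParams:
    spur_px: float = 5.0
    step_px: float = 0.5
    max_spline_dev: float = 1.0
    max_extension_px: float = 12.0


@dataclass
class Midline:
    """Ordered sub-pixel midline with cumulative arc length per point."""

    points: np.ndarray  # (N, 2) row/col
    cum_arc_px: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.cum_arc_px is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.cum_arc_px = np.concatenate([[0.0], np.cumsum(seg)])
        self.cum_arc_px = np.asarray(self.cum_arc_px, dtype=float)

    @property
    def total_length_px(self) -> float:
        return float(self.cum_arc_px[-1])

    def total_length_um(self, px_per_um: float = DEFAULT_PX_PER_UM) -> float:
        return to_micrometers(self.total_length_px, px_per_um)

    @property
    def step_px(self) -> float:
        return float(np.median(np.diff(self.cum_arc_px)))


def to_micrometers(length_px: float, px_per_um: float = DEFAULT_PX_PER_UM) -> float:
    """Convert a pixel length to micrometres by exact division."""
    if px_per_um <= 0:
        raise ValueError("px_per_um must be positive")
    return float(length_px) / float(px_per_um)


def _smooth_path(path: np.ndarray, max_dev: float) -> tuple[np.ndarray, object] | None:
    """Fit a smoothing spline, relaxing stiffness until deviation <= max_dev."""
    if len(path) < 5:
        return None
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    u /= u[-1]
    s = float(len(path))
    for _ in range(24):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                tck, _ = splprep([path[:, 0], path[:, 1]], u=u, s=s, k=3)
            except (ValueError, TypeError):
                return None
        rr, cc = splev(u, tck)
        dev = np.hypot(rr - path[:, 0], cc - path[:, 1]).max()
        if dev <= max_dev:
            return u, tck
        s /= 2.0
        if s < 1e-8:
            s = 0.0
    return u, tck


def _extend_into_mask(point: np.ndarray, direction: np.ndarray, mask: np.ndarray,
                      max_px: float, step: float = 0.25) -> np.ndarray | None:
    """March from an end point along ``direction`` while still inside the mask."""
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        return None
    d = direction / norm
    h, w = mask.shape
    last = None
    t = step
    while t <= max_px:
        p = point + t * d
        r, c = int(round(p[0])), int(round(p[1]))
        if r < 0 or c < 0 or r >= h or c >= w or not mask[r, c]:
            break
        last = p
        t += step
    return last


def extract_midline(mask: np.ndarray, params: MidlineParams | None = None) -> Midline:
    """Midline of a single bivalent mask; raises on degenerate skeletons."""
    params = params or MidlineParams()
    mask = np.asarray(mask, dtype=bool)
    skel = skeletonize(mask)
    g = prune_spurs(pixel_graph(skel), params.spur_px)
    path_nodes, _ = longest_geodesic_path(g)
    path = np.array(path_nodes, dtype=float)
    if len(path) < 2:
        raise DegenerateSkeletonError("degenerate skeleton")

    fit = _smooth_path(path, params.max_spline_dev)
    if fit is not None:
        u, tck = fit
        n_dense = max(int(len(path) * 4), 64)
        uu = np.linspace(0.0, 1.0, n_dense)
        rr, cc = splev(uu, tck)
        curve = np.column_stack([rr, cc])
    else:
        curve = path

    # extend both ends to the mask boundary along the end tangents
    k = min(5, len(curve) - 1)
    head = _extend_into_mask(curve[0], curve[0] - curve[k], mask, params.max_extension_px)
    tail = _extend_into_mask(curve[-1], curve[-1] - curve[-1 - k], mask, params.max_extension_px)
    parts = []
    if head is not None:
        parts.append(head[None, :])
    parts.append(curve)
    if tail is not None:
        parts.append(tail[None, :])
    curve = np.vstack(parts)

    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise DegenerateSkeletonError("degenerate skeleton: zero length")
    s_new = np.arange(0.0, total, params.step_px)
    s_new = np.append(s_new, total)
    pts = np.column_stack([
        np.interp(s_new, cum, curve[:, 0]),
        np.interp(s_new, cum, curve[:, 1]),
    ])
    return Midline(points=pts, cum_arc_px=s_new)


def straighten(image: np.ndarray, midline: Midline, half_width: int) -> np.ndarray:
    """Resample the image perpendicular to the midline ("straightened" ribbon).

    Returns an array of shape (C, 2*half_width + 1, N) for a (C, H, W) input
    (or (2*half_width + 1, N) for a single channel), sampled with bilinear
    interpolation; one column per midline sample. Coordinates outside the
    image are clamped with a warning.
    """
    img = np.asarray(image, dtype=float)
    single = img.ndim == 2
    if single:
        img = img[None]
    pts = midline.points
    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(-half_width, half_width + 1)
    rows = pts[None, :, 0] + offsets[:, None] * normal[None, :, 0].squeeze(0)
    cols = pts[None, :, 1] + offsets[:, None] * normal[None, :, 1].squeeze(0)
    h, w = img.shape[1:]
    if rows.min() < 0 or cols.min() < 0 or rows.max() > h - 1 or cols.max() > w - 1:
        warnings.warn("midline ribbon exits the image; coordinates clamped", stacklevel=2)
        rows = np.clip(rows, 0, h - 1)
        cols = np.clip(cols, 0, w - 1)
    out = np.stack([
        map_coordinates(ch, [rows, cols], order=1, mode="nearest") for ch in img
    ])
    return out[0] if single else out
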