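"""Seeded generator of synthetic three-channel spermatocyte spreads.

Each synthetic cell emulates a pachytene spread: curved ribbon-like bivalents
of known arc length (red channel), point-like MLH1 foci rendered as isotropic
Gaussians at known arc positions on the midline (green), a centromere spot
(blue), additive Gaussian noise, optional salt speckle, and a multiplicative
corner-to-corner illumination gradient. Every rendered bivalent is recorded
in a ground-truth manifest so downstream measurements can be scored exactly.

Channels are 16-bit grayscale, stacked (3, H, W) in the order
red/green/blue = SYCP3 / MLH1 / CREST. Coordinates are (row, col), 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.interpolate import splev, splprep
from scipy.spatial import cKDTree

MANIFEST_COLUMNS = [
    "cell_id",
    "bivalent_id",
    "arc_length_px",
    "centromere_pos_px",
    "foci_pos_px",
    "overlaps",
    # extras beyond the documented header: used to match detected objects
    # to ground-truth rows and to mark the XY body
    "centroid_r",
    "centroid_c",
    "is_xy",
]


class PlacementError(RuntimeError):
    """Raised when a bivalent cannot be placed after bounded retries."""


def spline_path(control_points: np.ndarray, step: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Resample a cubic spline through ``control_points`` at ``step`` px.

    Returns (points (N, 2), cumulative arc length (N,)). The integrated
    polyline length of the dense resampling is the realized arc length.
    """
    pts = np.asarray(control_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two 2-D control points")
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if chord.sum() < 1e-9:
        raise ValueError("degenerate control polygon (zero length)")
    k = min(3, len(pts) - 1)
    u = np.concatenate([[0.0], np.cumsum(chord)]) / chord.sum()
    tck, _ = splprep([pts[:, 0], pts[:, 1]], u=u, s=0.0, k=k)
    # dense evaluation, then arc-length reparameterization at ``step``
    n_dense = max(int(chord.sum() / step) * 4, 32)
    uu = np.linspace(0.0, 1.0, n_dense)
    rr, cc = splev(uu, tck)
    dense = np.column_stack([rr, cc])
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s_new = np.arange(0.0, total, step)
    s_new = np.append(s_new, total)
    out = np.column_stack([np.interp(s_new, cum, dense[:, 0]), np.interp(s_new, cum, dense[:, 1])])
    return out, s_new


def _point_at_arc(points: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    return np.array(
        [np.interp(s, cum, points[:, 0]), np.interp(s, cum, points[:, 1])]
    )


@dataclass
class BivalentSpec:
    """Geometry and signal specification of one synthetic bivalent.

    Arc positions (centromere, foci) are in pixels along the midline spline,
    measured from the first control point. Intensities are fractions of the
    channel dynamic range.
    """

    control_points: np.ndarray
    ribbon_width: float = 5.0
    sc_intensity: float = 0.75
    centromere_arc_pos: float = 0.0
    foci_arc_pos: tuple[float, ...] = ()
    foci_sigma: float = 2.0
    foci_intensity: float = 0.9
    is_xy: bool = False

    _path: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False, compare=False)

    def path(self) -> tuple[np.ndarray, np.ndarray]:
        if self._path is None:
            self._path = spline_path(self.control_points)
        return self._path

    @property
    def arc_length_px(self) -> float:
        return float(self.path()[1][-1])

    def validate(self) -> None:
        if self.ribbon_width < 2:
            raise ValueError("ribbon_width must be >= 2 px")
        length = self.arc_length_px
        if length <= 0:
            raise ValueError("arc length must be positive")
        pos = (self.centromere_arc_pos, *self.foci_arc_pos)
        if any(p < 0 or p > length for p in pos):
            raise ValueError("arc positions must lie in [0, arc_length_px]")
        foci = np.asarray(self.foci_arc_pos, dtype=float)
        if len(foci) > 1 and not np.all(np.diff(foci) > 0):
            raise ValueError("foci_arc_pos must be strictly increasing")


@dataclass
class BivalentTruth:
    """One ground-truth manifest row for a rendered bivalent."""

    cell_id: str
    bivalent_id: int
    arc_length_px: float
    centromere_pos_px: float
    foci_pos_px: tuple[float, ...]
    overlaps: bool
    centroid_r: float
    centroid_c: float
    is_xy: bool


@dataclass
class CellSpec:
    """Specification of one synthetic spermatocyte spread.

    Defaults emulate a full mouse karyotype at pachytene: 23 autosomal
    bivalents plus one XY body, non-overlapping, with mild noise and a 10%
    corner-to-corner illumination gradient.
    """

    n_bivalents: int = 24
    include_xy: bool = True
    overlap_fraction: float = 0.0
    noise_sd: float = 0.01
    salt_fraction: float = 0.0
    illumination_gradient: float = 0.10
    canvas_size: tuple[int, int] = (900, 900)
    seed: int = 0
    arc_length_range: tuple[float, float] = (80.0, 160.0)
    ribbon_width: float = 5.0
    sc_intensity: float = 0.75
    foci_sigma: float = 2.0
    foci_intensity: float = 0.9
    n_stray_foci: int = 0

    def validate(self) -> None:
        if self.n_bivalents < 0:
            raise ValueError("n_bivalents must be >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")


def render_bivalent(
    spec: BivalentSpec, canvas: np.ndarray, *, cell_id: str = "cell", bivalent_id: int = 0
) -> BivalentTruth:
    """Render one bivalent into a float (3, H, W) canvas in place.

    The red channel gains a smooth tube of the spec's width along the spline
    midline; green Gaussian spots are placed at the foci arc positions and a
    blue spot at the centromere arc position (Gaussians clipped at 3 sigma).
    Returns the realized ground-truth row; its arc length is the numerically
    integrated spline length.
    """
    spec.validate()
    if canvas.ndim != 3 or canvas.shape[0] != 3:
        raise ValueError("canvas must be a (3, H, W) array")
    h, w = canvas.shape[1:]
    margin = spec.ribbon_width
    cp = np.asarray(spec.control_points, dtype=float)
    if (cp[:, 0].min() < margin or cp[:, 1].min() < margin
            or cp[:, 0].max() > h - 1 - margin or cp[:, 1].max() > w - 1 - margin):
        raise ValueError("control points must lie inside the canvas with margin >= ribbon_width")

    pts, cum = spec.path()
    tube = tube_footprint(spec, canvas.shape[1:])
    rows, cols, prof = tube
    np.maximum.at(canvas[0], (rows, cols), prof * spec.sc_intensity)

    focus_scale = 0.4 if spec.is_xy else 1.0
    for s in spec.foci_arc_pos:
        _add_gaussian(canvas[1], _point_at_arc(pts, cum, s),
                      spec.foci_sigma, spec.foci_intensity * focus_scale)
    _add_gaussian(canvas[2], _point_at_arc(pts, cum, spec.centromere_arc_pos),
                  spec.foci_sigma * 1.25, spec.foci_intensity * focus_scale)

    centroid_r = float(rows.mean()) if len(rows) else float(pts[:, 0].mean())
    centroid_c = float(cols.mean()) if len(cols) else float(pts[:, 1].mean())
    return BivalentTruth(
        cell_id=cell_id,
        bivalent_id=bivalent_id,
        arc_length_px=float(cum[-1]),
        centromere_pos_px=float(spec.centromere_arc_pos),
        foci_pos_px=tuple(float(s) for s in spec.foci_arc_pos),
        overlaps=False,
        centroid_r=centroid_r,
        centroid_c=centroid_c,
        is_xy=spec.is_xy,
    )


def tube_footprint(spec: BivalentSpec, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixels within the ribbon tube and their soft-edge intensity profile.

    Returns (rows, cols, profile) with profile in (0, 1]; the tube has radius
    ribbon_width / 2 with a 1-px anti-aliased edge.
    """
    pts, _ = spec.path()
    radius = spec.ribbon_width / 2.0
    pad = radius + 1.5
    r0 = max(int(np.floor(pts[:, 0].min() - pad)), 0)
    r1 = min(int(np.ceil(pts[:, 0].max() + pad)), shape[0] - 1)
    c0 = max(int(np.floor(pts[:, 1].min() - pad)), 0)
    c1 = min(int(np.ceil(pts[:, 1].max() + pad)), shape[1] - 1)
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d, idx = cKDTree(pts).query(grid, workers=-1)
    prof = np.clip(radius + 0.5 - d, 0.0, 1.0)
    # flat end caps: the ribbon tip coincides with the nominal arc endpoints,
    # so the rendered arc length equals the integrated spline length
    for end, inward in ((0, pts[min(4, len(pts) - 1)] - pts[0]),
                        (len(pts) - 1, pts[max(len(pts) - 5, 0)] - pts[-1])):
        outward = -inward / max(np.linalg.norm(inward), 1e-12)
        at_end = idx == end
        overshoot = (grid[at_end] - pts[end]) @ outward
        prof[np.flatnonzero(at_end)[overshoot > 0.5]] = 0.0
    keep = prof > 0
    return rr.ravel()[keep], cc.ravel()[keep], prof[keep]


def _add_gaussian(channel: np.ndarray, center: np.ndarray, sigma: float, amplitude: float) -> None:
    h, w = channel.shape
    rad = 3.0 * sigma
    r0 = max(int(np.floor(center[0] - rad)), 0)
    r1 = min(int(np.ceil(center[0] + rad)), h - 1)
    c0 = max(int(np.floor(center[1] - rad)), 0)
    c1 = min(int(np.ceil(center[1] + rad)), w - 1)
    if r1 < r0 or c1 < c0:
        return
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    g = amplitude * np.exp(-d2 / (2.0 * sigma**2))
    g[d2 > rad**2] = 0.0  # clip at 3 sigma
    channel[r0:r1 + 1, c0:c1 + 1] += g


def _random_control_points(
    rng: np.random.Generator, spec: CellSpec, target_len: float,
    start: np.ndarray | None = None, heading: float | None = None,
) -> np.ndarray:
    """Correlated random walk giving a gently curved 5-point control polygon."""
    h, w = spec.canvas_size
    margin = spec.ribbon_width + 2
    if start is None:
        start = rng.uniform([margin, margin], [h - 1 - margin, w - 1 - margin])
    if heading is None:
        heading = rng.uniform(0.0, 2.0 * math.pi)
    n_seg = 4
    step = target_len / n_seg
    pts = [np.asarray(start, dtype=float)]
    ang = heading
    for _ in range(n_seg):
        ang += rng.normal(0.0, 0.35)
        pts.append(pts[-1] + step * np.array([math.sin(ang), math.cos(ang)]))
    return np.array(pts)


def _inside(points: np.ndarray, spec: CellSpec) -> bool:
    h, w = spec.canvas_size
    m = spec.ribbon_width + 1
    return bool(
        points[:, 0].min() >= m and points[:, 1].min() >= m
        and points[:, 0].max() <= h - 1 - m and points[:, 1].max() <= w - 1 - m
    )


def _sample_foci(rng: np.random.Generator, length: float, spec: CellSpec) -> tuple[float, ...]:
    # longer bivalents are more likely to carry two (interfering) crossovers
    mid = 0.5 * (spec.arc_length_range[0] + spec.arc_length_range[1])
    p2 = 1.0 / (1.0 + math.exp(-(length - mid) / 15.0))
    if rng.random() < p2:
        f1 = length * rng.uniform(0.08, 0.30)
        f2 = length * rng.uniform(0.70, 0.92)
        return (float(f1), float(f2))
    return (float(length * rng.uniform(0.35, 0.65)),)


def generate_cell(spec: CellSpec) -> tuple[np.ndarray, list[BivalentTruth]]:
    """Render one synthetic spread; returns (uint16 (3, H, W) image, truth rows).

    Placement is rejection-sampled so that at most
    ``ceil(overlap_fraction * n)`` bivalents intersect another; the
    overlap-designated bivalents are deliberately placed end-to-end against an
    already placed bivalent so that merging errors occur. Identical seeds give
    bit-identical images.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas_size
    canvas = np.zeros((3, h, w), dtype=float)
    occupied = np.zeros((h, w), dtype=bool)
    truths: list[BivalentTruth] = []
    n = spec.n_bivalents
    n_overlap = math.ceil(spec.overlap_fraction * n) if n else 0
    overlap_ids = set(range(n - n_overlap, n)) if n_overlap else set()
    endpoints: list[tuple[np.ndarray, float]] = []  # (endpoint, outgoing heading)

    for i in range(n):
        want_overlap = bool(i in overlap_ids and endpoints)
        placed = False
        for _attempt in range(400):
            target_len = rng.uniform(*spec.arc_length_range)
            if want_overlap:
                # continue smoothly from an existing bivalent's end so the two
                # ribbons merge into one elongated object (an end-to-end merge
                # that passes the shape heuristics and must be caught downstream)
                ep, heading = endpoints[rng.integers(len(endpoints))]
                start = ep + np.array([math.sin(heading), math.cos(heading)])
                cp = _random_control_points(rng, spec, target_len, start=start,
                                            heading=heading + rng.normal(0.0, 0.1))
            else:
                cp = _random_control_points(rng, spec, target_len)
            if not _inside(cp, spec):
                continue
            is_xy = spec.include_xy and i == n - 1
            length = spline_path(cp)[1][-1]
            foci = () if is_xy else _sample_foci(rng, length, spec)
            if is_xy:
                foci = (float(length * rng.uniform(0.8, 0.9)),)  # PAR focus
            cpos = float(length * rng.uniform(0.18, 0.32))
            bspec = BivalentSpec(
                control_points=cp,
                ribbon_width=spec.ribbon_width,
                sc_intensity=spec.sc_intensity,
                centromere_arc_pos=cpos,
                foci_arc_pos=foci,
                foci_sigma=spec.foci_sigma,
                foci_intensity=spec.foci_intensity,
                is_xy=is_xy,
            )
            rows, cols, _prof = tube_footprint(bspec, (h, w))
            hit = occupied[rows, cols].any()
            if want_overlap != hit and not (want_overlap and not hit and _attempt < 200):
                # non-overlap bivalents must not touch; overlap ones must
                continue
            truth = render_bivalent(bspec, canvas, cell_id=f"cell_{spec.seed}", bivalent_id=i)
            truth.overlaps = bool(hit)
            occupied[rows, cols] = True
            pts, _cum = bspec.path()
            tang = pts[-1] - pts[-5] if len(pts) > 5 else pts[-1] - pts[0]
            endpoints.append((pts[-1], math.atan2(tang[0], tang[1])))
            truths.append(truth)
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place bivalent {i} after bounded retries")

    # stray green foci inside the ribbon but off the midline centre
    for _ in range(spec.n_stray_foci):
        if not truths:
            break
        t = truths[int(rng.integers(len(truths)))]
        # rebuild an off-centre point near that bivalent's centroid
        ang = rng.uniform(0.0, 2.0 * math.pi)
        offset = rng.uniform(0.55, 0.95) * (spec.ribbon_width / 2.0 + 2.0)
        centre = np.array([t.centroid_r, t.centroid_c]) + offset * np.array(
            [math.sin(ang), math.cos(ang)]
        )
        _add_gaussian(canvas[1], centre, spec.foci_sigma, spec.foci_intensity)

    canvas += rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    if spec.salt_fraction > 0:
        n_salt = int(spec.salt_fraction * h * w)
        for ch in range(3):
            rr = rng.integers(0, h, n_salt)
            cc = rng.integers(0, w, n_salt)
            canvas[ch, rr, cc] += rng.uniform(0.3, 0.8, n_salt)
    if spec.illumination_gradient > 0:
        rr, cc = np.mgrid[0:h, 0:w]
        plane = 1.0 + spec.illumination_gradient * ((rr / (h - 1) + cc / (w - 1)) / 2.0 - 0.5)
        canvas *= plane[None, :, :]
    img = (np.clip(canvas, 0.0, 1.0) * 65535.0).round().astype(np.uint16)
    return img, truths


def manifest_frame(truths: list[BivalentTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        rows.append({
            "cell_id": t.cell_id,
            "bivalent_id": t.bivalent_id,
            "arc_length_px": t.arc_length_px,
            "centromere_pos_px": t.centromere_pos_px,
            "foci_pos_px": ";".join(f"{p:.3f}" for p in t.foci_pos_px),
            "overlaps": int(t.overlaps),
            "centroid_r": t.centroid_r,
            "centroid_c": t.centroid_c,
            "is_xy": int(t.is_xy),
        })
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def parse_foci_field(value) -> tuple[float, ...]:
    """Parse the semicolon-delimited foci list used in manifest/measurement CSVs."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ()
    s = str(value).strip()
    if not s:
        return ()
    return tuple(float(x) for x in s.split(";"))


def generate_dataset(
    cells: list[CellSpec], out_dir: str | Path, *, overwrite: bool = False,
    config: dict | None = None,
) -> pd.DataFrame:
    """Write one TIFF per cell plus a pooled manifest CSV and a config sidecar.

    Cell ids are ``cell_000`` ... in list order. Refuses to write into an
    existing non-empty directory unless ``overwrite`` is set.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty (pass overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for i, spec in enumerate(cells):
        cell_id = f"cell_{i:03d}"
        img, truths = generate_cell(spec)
        for t in truths:
            t.cell_id = cell_id
        tifffile.imwrite(out / f"{cell_id}.tif", img, photometric="minisblack")
        frames.append(manifest_frame(truths))
    manifest = (
        pd.concat(frames, ignore_index=True)
        if frames else pd.DataFrame(columns=MANIFEST_COLUMNS)
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    sidecar = config if config is not None else {
        "n_cells": len(cells),
        "cells": [
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in vars(c).items()}
            for c in cells
        ],
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return manifest
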