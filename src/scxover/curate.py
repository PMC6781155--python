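"""Rule-based curation: error diagnosis, chromosome-1 isolation, accuracy.

The two dominant automated-measurement error classes are incorrectly merged
bivalents (two overlapping ribbons traced as one) and extra foci (detections
absent from a careful manual count). Both are diagnosed from the output
tables alone: merges through residual skeleton branching or an outlying SC
length relative to the cell's robust length distribution, extra foci through
a per-bivalent maximum and a centrality re-check of each focus against the
midline. Chromosome 1 is isolated as the longest bivalent per cell falling
inside configurable SC-length and centromere-position windows. Accuracy
against a reference table is summarized per metric by Pearson's r and the
mean signed percent bias.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synth import parse_foci_field

FLAG_NAMES = (
    "extra_foci",
    "merged_bivalent",
    "short_skeleton",
    "ambiguous_centromere",
    "no_centromere",
    "manual_reject",
)


@dataclass
class CurationFlags:
    extra_foci: bool = False
    merged_bivalent: bool = False
    short_skeleton: bool = False
    ambiguous_centromere: bool = False
    no_centromere: bool = False
    manual_reject: bool = False

    def to_set(self) -> frozenset[str]:
        return frozenset(k for k, v in asdict(self).items() if v)

    @property
    def clean(self) -> bool:
        return not any(asdict(self).values())


@dataclass
class CurationParams:
    max_foci: int = 4
    center_tol_px: float = 2.5
    robust_z: float = 3.5
    min_length_px: float = 30.0


@dataclass
class Chr1Filter:
    """Windows isolating chromosome 1: the metacentric with the longest SC."""

    sc_length_um_window: tuple[float, float] = (10.0, 17.0)
    centromere_norm_window: tuple[float, float] = (0.15, 0.40)
    require_longest_in_cell: bool = True

    def __post_init__(self):
        for lo, hi in (self.sc_length_um_window, self.centromere_norm_window):
            if lo >= hi:
                raise ValueError("window bounds must be ordered")


def diagnose(row: pd.Series, cell_lengths: np.ndarray,
             params: CurationParams | None = None) -> CurationFlags:
    """Curation flags for one measurement row given its cell's SC lengths."""
    params = params or CurationParams()
    flags = CurationFlags()
    length = float(row["sc_length_px"])
    lengths = np.asarray(cell_lengths, dtype=float)
    med = float(np.median(lengths))
    mad = float(np.median(np.abs(lengths - med)))
    row_flags_raw = str(row.get("flags") or "")
    if int(row.get("branch_points", 0)) > 0 or "multiple_centromeres" in row_flags_raw:
        flags.merged_bivalent = True
    elif len(lengths) >= 3 and mad > 1e-9:
        if (length - med) / (1.4826 * mad) > params.robust_z:
            flags.merged_bivalent = True
    elif length > 1.6 * med and len(lengths) >= 3:
        flags.merged_bivalent = True
    if length < params.min_length_px:
        flags.short_skeleton = True
    offsets = parse_foci_field(row.get("foci_offset_px"))
    if int(row["n_foci"]) > params.max_foci or any(o > params.center_tol_px for o in offsets):
        flags.extra_foci = True
    row_flags = str(row.get("flags") or "")
    flags.ambiguous_centromere = "ambiguous_centromere" in row_flags
    flags.no_centromere = "no_centromere" in row_flags
    return flags


def diagnose_frame(
    measurements: pd.DataFrame,
    params: CurationParams | None = None,
    reject_list: set[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Apply ``diagnose`` per row; adds one boolean column per flag plus
    a combined ``flags`` string and a ``clean`` column."""
    params = params or CurationParams()
    out = measurements.copy()
    for name in FLAG_NAMES:
        out[name] = False
    for cell_id, grp in measurements.groupby("cell_id", sort=False):
        lengths = grp["sc_length_px"].to_numpy(dtype=float)
        for idx, row in grp.iterrows():
            fl = diagnose(row, lengths, params)
            if reject_list and (str(cell_id), int(row["object_index"])) in reject_list:
                fl.manual_reject = True
            for name in FLAG_NAMES:
                out.loc[idx, name] = getattr(fl, name)
    out["clean"] = ~out[list(FLAG_NAMES)].any(axis=1)
    out["flags"] = [
        ";".join(n for n in FLAG_NAMES if row[n]) for _, row in out.iterrows()
    ]
    return out


def filter_chromosome1(measurements: pd.DataFrame,
                       chr1: Chr1Filter | None = None) -> pd.DataFrame:
    """Chromosome-1 candidates: at most one unflagged in-window row per cell.

    With ``require_longest_in_cell`` the candidate must be the longest
    measured bivalent of its cell (flagged or not); a cell whose longest
    bivalent is flagged contributes nothing. The output gains an ``is_chr1``
    column and is a subset of the input (the operation is idempotent).
    """
    chr1 = chr1 or Chr1Filter()
    if measurements.empty:
        out = measurements.copy()
        out["is_chr1"] = pd.Series(dtype=bool)
        return out
    lo_um, hi_um = chr1.sc_length_um_window
    lo_c, hi_c = chr1.centromere_norm_window
    picks = []
    for _cell, grp in measurements.groupby("cell_id", sort=False):
        if chr1.require_longest_in_cell:
            cand = grp.loc[[grp["sc_length_px"].idxmax()]]
        else:
            cand = grp.sort_values("sc_length_px", ascending=False)
        for idx, row in cand.iterrows():
            if "clean" in row.index and not bool(row["clean"]):
                continue
            if not lo_um <= float(row["sc_length_um"]) <= hi_um:
                continue
            cn = row["centromere_pos_norm"]
            if pd.isna(cn) or not lo_c <= float(cn) <= hi_c:
                continue
            picks.append(idx)
            break
    out = measurements.loc[picks].copy()
    out["is_chr1"] = True
    return out


def match_to_manifest(measurements: pd.DataFrame, manifest: pd.DataFrame,
                      max_dist_px: float = 80.0) -> pd.DataFrame:
    """Assign ground-truth ``bivalent_id`` to measurements by centroid.

    Greedy one-to-one nearest-centroid matching within each cell; unmatched
    measurements get a missing id. Used to score automated output against a
    synthetic manifest.
    """
    out = measurements.copy()
    out["bivalent_id"] = pd.NA
    for cell, grp in measurements.groupby("cell_id", sort=False):
        truth = manifest[manifest["cell_id"] == cell]
        if truth.empty:
            continue
        pairs = []
        for idx, row in grp.iterrows():
            d = np.hypot(truth["centroid_r"].to_numpy() - float(row["centroid_r"]),
                         truth["centroid_c"].to_numpy() - float(row["centroid_c"]))
            for j, dist in zip(truth.index, d):
                if dist <= max_dist_px:
                    pairs.append((dist, idx, j))
        pairs.sort()
        used_meas: set = set()
        used_truth: set = set()
        for dist, idx, j in pairs:
            if idx in used_meas or j in used_truth:
                continue
            out.loc[idx, "bivalent_id"] = int(manifest.loc[j, "bivalent_id"])
            used_meas.add(idx)
            used_truth.add(j)
    return out


def _oriented_reference(ref: pd.DataFrame) -> pd.DataFrame:
    """Orient reference rows so the centromere is in the proximal half."""
    out = ref.copy()
    foci = [parse_foci_field(v) for v in out["foci_pos_px"]]
    lengths = out["arc_length_px"].to_numpy(dtype=float)
    cpos = out["centromere_pos_px"].to_numpy(dtype=float)
    new_c = []
    new_f = []
    for L, c, f in zip(lengths, cpos, foci):
        if c > L / 2.0:
            c = L - c
            f = tuple(sorted(L - np.asarray(f))) if f else ()
        new_c.append(c)
        new_f.append(tuple(f))
    out["centromere_pos_px"] = new_c
    out["_foci"] = new_f
    return out.drop(columns=["foci_pos_px"])


def compare_to_reference(auto: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-metric Pearson r and mean signed percent bias, automated vs reference.

    Tables are joined on (cell_id, bivalent_id). Metrics: SC length,
    centromere position, and MLH1 focus position (foci paired by order,
    only for bivalents where both tables report the same count; mismatched
    or missing rows are dropped and counted).
    """
    if "bivalent_id" not in auto.columns:
        raise ValueError("automated table must carry a bivalent_id column (see match_to_manifest)")
    a = auto.dropna(subset=["bivalent_id"]).copy()
    a["bivalent_id"] = a["bivalent_id"].astype(int)
    r = _oriented_reference(reference)
    merged = a.merge(r, on=["cell_id", "bivalent_id"], suffixes=("_auto", "_ref"))
    if merged.empty:
        raise ValueError("no joinable (cell_id, bivalent_id) pairs")

    metrics: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    sc_a = merged["sc_length_px"].to_numpy(dtype=float)
    sc_r = merged["arc_length_px"].to_numpy(dtype=float)
    metrics["sc_length"] = (sc_a, sc_r, 0)

    cm = merged.dropna(subset=["centromere_pos_px_auto"])
    metrics["centromere_pos"] = (
        cm["centromere_pos_px_auto"].to_numpy(dtype=float),
        cm["centromere_pos_px_ref"].to_numpy(dtype=float),
        len(merged) - len(cm),
    )

    fa: list[float] = []
    fr: list[float] = []
    dropped = 0
    for _, row in merged.iterrows():
        auto_f = parse_foci_field(row["foci_pos_px"])
        ref_f = row["_foci"]
        if len(auto_f) == len(ref_f) and len(auto_f) > 0:
            fa.extend(auto_f)
            fr.extend(ref_f)
        else:
            dropped += 1
    metrics["foci_pos"] = (np.asarray(fa), np.asarray(fr), dropped)

    rows = []
    for name, (x, y, n_drop) in metrics.items():
        n = len(x)
        if n >= 3 and np.std(x) > 0 and np.std(y) > 0:
            rcoef = float(sps.pearsonr(x, y).statistic)
        else:
            rcoef = float("nan")
        with np.errstate(divide="ignore", invalid="ignore"):
            bias = float(np.mean(100.0 * (x - y) / y)) if n else float("nan")
        rows.append({"metric": name, "n": n, "r": rcoef,
                     "bias_percent": bias, "n_dropped": n_drop})
    return pd.DataFrame(rows, columns=["metric", "n", "r", "bias_percent", "n_dropped"])
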