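"""Crossover-patterning statistics.

Implements the analyses applied to per-cell MLH1 counts and per-bivalent
chromosome-1 measurements:

* count summaries per mouse and pooled per group (mean, sample SD, SE, CV),
* genetic map length assuming one MLH1 focus = 50 cM,
* focus-class tables (counts and percentages of 0/1/2/3-focus bivalents),
* normalized-position histograms (5% bins) and two-sample KS comparisons,
* crossover-interference strength: maximum-likelihood gamma shape ("nu")
  fitted to inter-focus distances of two-focus bivalents (absolute
  micrometres or distance normalized by SC length), with configurable
  removal of outlying short distances,
* the intra-chromosomal component of the genetic-shuffling measure r-bar,
* mouse-level permutation tests comparing within-mouse and among-mouse
  variance between groups,
* logistic regression of focus class (1 vs 2) on SC length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import polygamma, psi

CM_PER_FOCUS = 50.0


class DegenerateSampleError(ValueError):
    """Zero-variance sample: the gamma shape estimate is unbounded."""


# ---------------------------------------------------------------------------
# summaries

@dataclass
class SummaryRow:
    """Per-group count summary: n, mean, sample SD (n-1), SE = SD/sqrt(n),
    CV = 100 * SD / mean."""

    n: int
    mean: float
    sd: float
    se: float
    cv: float
    labels: dict | None = None

    @classmethod
    def from_values(cls, values, **labels) -> "SummaryRow":
        x = np.asarray(values, dtype=float)
        n = len(x)
        mean = float(x.mean()) if n else float("nan")
        if n < 2:
            return cls(n=n, mean=mean, sd=float("nan"), se=float("nan"),
                       cv=float("nan"), labels=labels or None)
        sd = float(x.std(ddof=1))
        return cls(n=n, mean=mean, sd=sd, se=sd / math.sqrt(n),
                   cv=100.0 * sd / mean, labels=labels or None)

    @classmethod
    def from_moments(cls, mean: float, sd: float, n: int, **labels) -> "SummaryRow":
        """Summary row reconstructed from a printed (mean, SD, n) triple."""
        if n < 2:
            return cls(n=n, mean=mean, sd=float("nan"), se=float("nan"),
                       cv=float("nan"), labels=labels or None)
        return cls(n=int(n), mean=float(mean), sd=float(sd),
                   se=float(sd) / math.sqrt(n), cv=100.0 * float(sd) / float(mean),
                   labels=labels or None)


def summarize_counts(df: pd.DataFrame, value_col: str,
                     group_cols: list[str]) -> pd.DataFrame:
    """One SummaryRow per group of ``group_cols``; rounding is left to report
    time (report files print 3 decimal places)."""
    rows = []
    for key, grp in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        s = SummaryRow.from_values(grp[value_col].to_numpy())
        rows.append({**dict(zip(group_cols, key)), "n": s.n, "mean": s.mean,
                     "sd": s.sd, "se": s.se, "cv": s.cv})
    return pd.DataFrame(rows)


@dataclass
class PooledSummary:
    n: int
    weighted_mean: float   # n-weighted mean of mouse means (= raw-value mean)
    unweighted_mean: float  # plain average across mice
    sd: float
    se: float
    cv: float


def pool_group(ns, means, sds=None) -> PooledSummary:
    """Pool per-mouse summaries into a group row.

    The pooled mean weights each mouse by its cell count (equal to the raw
    pooled mean); the unweighted across-mice mean is reported alongside.
    When SDs are given, the pooled SD combines within- and between-mouse
    sums of squares on n - 1 denominators.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    if len(ns) == 0:
        raise ValueError("cannot pool an empty group")
    n_tot = float(ns.sum())
    wmean = float((ns * means).sum() / n_tot)
    umean = float(means.mean())
    if sds is None or n_tot < 2:
        return PooledSummary(int(n_tot), wmean, umean,
                             float("nan"), float("nan"), float("nan"))
    sds = np.asarray(sds, dtype=float)
    ss = float(((ns - 1) * sds**2).sum() + (ns * (means - wmean) ** 2).sum())
    sd = math.sqrt(ss / (n_tot - 1))
    return PooledSummary(int(n_tot), wmean, umean, sd,
                         sd / math.sqrt(n_tot), 100.0 * sd / wmean)


def map_length_cM(mean_foci_per_cell: float) -> float:
    """Genetic map length in centimorgans, at 50 cM per MLH1 focus."""
    if mean_foci_per_cell < 0:
        raise ValueError("mean focus count must be non-negative")
    return CM_PER_FOCUS * float(mean_foci_per_cell)


# ---------------------------------------------------------------------------
# focus classes and positions

def focus_class_table(n_foci: pd.Series | np.ndarray,
                      groups: pd.Series | np.ndarray | None = None,
                      max_class: int = 3) -> pd.DataFrame:
    """Counts and percentages of bivalents with 0..max_class foci per group,
    plus an overall row labelled "all"."""
    counts = np.asarray(n_foci, dtype=int)
    glab = np.asarray(groups) if groups is not None else np.full(len(counts), "all")
    rows = []
    keys = list(pd.unique(glab))
    for key in keys + (["all"] if len(keys) > 1 or (keys and keys[0] != "all") else []):
        sel = counts if key == "all" else counts[glab == key]
        total = len(sel)
        row = {"group": key, "total": total}
        for k in range(max_class + 1):
            c = int((sel == k).sum())
            row[f"n{k}"] = c
            row[f"pct{k}"] = 100.0 * c / total if total else 0.0
        rows.append(row)
    if not rows:
        row = {"group": "all", "total": 0}
        for k in range(max_class + 1):
            row[f"n{k}"] = 0
            row[f"pct{k}"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BinnedPositions:
    edges: np.ndarray
    series: dict[str, np.ndarray]  # series name -> per-bin counts


def position_histogram(positions: dict[str, np.ndarray] | pd.DataFrame,
                       focus_class: int, bin_width: float = 0.05) -> BinnedPositions:
    """Bin normalized positions into [0, 1] bins of ``bin_width`` (5% default).

    ``positions`` maps bivalents to their normalized focus positions: for
    the 1-focus class one series ("focus1"); for the 2-foci class separate
    first/second-focus series ("focus1", "focus2"), each conserving the
    number of bivalents. Accepts a DataFrame with a ``foci_pos_norm`` column
    (semicolon-delimited) filtered to the requested class.
    """
    if focus_class not in (1, 2):
        raise ValueError("focus_class must be 1 or 2")
    if isinstance(positions, pd.DataFrame):
        from .synth import parse_foci_field
        lists = [parse_foci_field(v) for v in positions["foci_pos_norm"]]
        lists = [f for f in lists if len(f) == focus_class]
        series_vals = {
            f"focus{i + 1}": np.array([f[i] for f in lists], dtype=float)
            for i in range(focus_class)
        }
    else:
        series_vals = {k: np.asarray(v, dtype=float) for k, v in positions.items()}
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    series = {}
    for name, vals in series_vals.items():
        if len(vals) and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("normalized positions must lie in [0, 1]")
        counts, _ = np.histogram(np.clip(vals, 0, np.nextafter(1.0, 0)), bins=edges)
        series[name] = counts
    return BinnedPositions(edges=edges, series=series)


def ks_compare(positions_a, positions_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov on raw (unbinned) normalized positions."""
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 positions")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# interference

@dataclass
class InterferenceFit:
    nu: float
    scale: float
    n_distances: int
    mode: str  # "absolute_um" | "normalized"
    n_excluded: int = 0
    excluded: tuple[float, ...] = ()


def fit_gamma_mle(x, tol: float = 1e-8, max_iter: int = 200) -> tuple[float, float]:
    """Maximum-likelihood gamma (shape, scale) via the digamma equation.

    Solves log(a) - psi(a) = log(mean) - mean(log x) with a safeguarded
    Newton iteration (bisection fallback keeps the iterate inside a bracket).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 or np.any(x <= 0):
        raise ValueError("need at least two strictly positive distances")
    m = x.mean()
    s_stat = math.log(m) - np.log(x).mean()
    if s_stat < 1e-12 or x.var() < 1e-12 * m**2:
        raise DegenerateSampleError("degenerate sample (shape unbounded)")
    a = (3.0 - s_stat + math.sqrt((s_stat - 3.0) ** 2 + 24.0 * s_stat)) / (12.0 * s_stat)
    lo, hi = 1e-8, 1e8
    for _ in range(max_iter):
        f = math.log(a) - psi(a) - s_stat
        if f > 0:
            lo = max(lo, a)  # f decreasing in a
        else:
            hi = min(hi, a)
        fp = 1.0 / a - polygamma(1, a)
        step = f / fp
        a_new = a - step
        if not lo < a_new < hi:
            a_new = 0.5 * (lo + hi)
        if abs(a_new - a) <= tol * max(1.0, a):
            a = a_new
            break
        a = a_new
    return float(a), float(m / a)


def inter_focus_distances(foci_pos_px, sc_length_px, px_per_um: float,
                          mode: str = "absolute_um") -> float:
    """Distance between the two foci of one bivalent, in the requested mode."""
    if len(foci_pos_px) != 2:
        raise ValueError("inter-focus distance requires exactly two foci")
    d_px = abs(foci_pos_px[1] - foci_pos_px[0])
    if mode == "absolute_um":
        return d_px / px_per_um
    if mode == "normalized":
        return d_px / sc_length_px
    raise ValueError("mode must be 'absolute_um' or 'normalized'")


def fit_interference(
    two_focus: pd.DataFrame,
    mode: str = "absolute_um",
    px_per_um: float = 9.8152,
    outlier_min_distance_um: float = 1.0,
    min_n: int = 10,
) -> InterferenceFit:
    """Gamma shape ("nu") of inter-focus distances on two-focus bivalents.

    Distances whose absolute value falls below ``outlier_min_distance_um``
    micrometres are excluded (and reported) before fitting: implausibly
    short inter-focus distances are double detections of one physical
    focus, not genuine double crossovers.
    """
    from .synth import parse_foci_field
    d_abs = []
    d_mode = []
    for _, row in two_focus.iterrows():
        foci = parse_foci_field(row["foci_pos_px"])
        if len(foci) != 2:
            continue
        d_abs.append(inter_focus_distances(foci, row["sc_length_px"], px_per_um, "absolute_um"))
        d_mode.append(inter_focus_distances(foci, row["sc_length_px"], px_per_um, mode))
    d_abs = np.asarray(d_abs)
    d_mode = np.asarray(d_mode)
    keep = d_abs >= outlier_min_distance_um
    excluded = tuple(float(v) for v in d_mode[~keep])
    kept = d_mode[keep]
    if len(kept) < min_n:
        raise ValueError(f"need at least {min_n} distances after exclusions, got {len(kept)}")
    nu, scale = fit_gamma_mle(kept)
    return InterferenceFit(nu=nu, scale=scale, n_distances=len(kept), mode=mode,
                           n_excluded=int((~keep).sum()), excluded=excluded)


# ---------------------------------------------------------------------------
# intra-chromosomal r-bar

def rbar_intra(positions_norm) -> float:
    """Intra-chromosomal genetic shuffling for one bivalent.

    With crossovers at sorted normalized positions partitioning the bivalent
    into proportions a_0..a_m, returns (1 - sum a_i^2) / 2: the probability
    that a uniformly chosen locus pair is separated by an odd number of
    crossovers in a random gamete when each crossover involves a random
    chromatid with probability 1/2 (no chromatid interference). Ranges from
    0 (no crossover) to 0.5.
    """
    pos = np.asarray(positions_norm, dtype=float)
    if len(pos) == 0:
        return 0.0
    if np.any(pos < 0) or np.any(pos > 1):
        raise ValueError("positions must lie in [0, 1]")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending")
    segments = np.diff(np.concatenate([[0.0], pos, [1.0]]))
    return float(0.5 * (1.0 - np.sum(segments**2)))


def rbar_intra_mc(positions_norm, n_gametes: int = 1_000_000,
                  rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo chromatid oracle for ``rbar_intra``.

    Simulates gametes in which each crossover independently involves a
    random chromatid with probability 1/2, scores recombination for locus
    pairs drawn uniformly on the chromosome, and averages. Kept independent
    of the closed form so the two can be checked against each other.
    """
    rng = rng or np.random.default_rng()
    pos = np.asarray(positions_norm, dtype=float)
    u = rng.uniform(0.0, 1.0, n_gametes)
    v = rng.uniform(0.0, 1.0, n_gametes)
    lo = np.minimum(u, v)
    hi = np.maximum(u, v)
    parity = np.zeros(n_gametes, dtype=bool)
    for x in pos:
        involved = rng.random(n_gametes) < 0.5
        parity ^= involved & (lo < x) & (x < hi)
    return float(parity.mean())


def rbar_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-bivalent intra-chromosomal r-bar from ``foci_pos_norm`` lists."""
    from .synth import parse_foci_field
    out = measurements.copy()
    out["rbar_intra"] = [
        rbar_intra(sorted(parse_foci_field(v))) for v in out["foci_pos_norm"]
    ]
    return out


# ---------------------------------------------------------------------------
# permutation tests

@dataclass
class PermutationResult:
    observed: float
    n_permutations: int
    p_value: float
    seed: int
    level: str  # "within_mouse_variance" | "among_mouse_variance"


def permutation_test_variance(
    counts_by_mouse: dict[str, np.ndarray],
    status_by_mouse: dict[str, str],
    level: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for a variance difference between two status groups.

    ``within_mouse_variance``: the statistic is the difference between the
    two groups in the mean of per-mouse variances of MLH1 count.
    ``among_mouse_variance``: the difference in the variance of per-mouse
    mean counts. Status labels are permuted at the mouse level; the
    two-sided p-value uses the add-one correction
    p = (1 + #{|T*| >= |T_obs|}) / (n_perm + 1).
    """
    if level not in ("within_mouse_variance", "among_mouse_variance"):
        raise ValueError("unknown level")
    mice = sorted(counts_by_mouse)
    labels = np.array([status_by_mouse[m] for m in mice])
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError("need exactly two status groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"status group {g!r} has fewer than 2 mice")
    if level == "within_mouse_variance":
        v = np.array([np.var(np.asarray(counts_by_mouse[m], dtype=float), ddof=1)
                      for m in mice])
        stat = lambda sel: v[sel].mean() - v[~sel].mean()  # noqa: E731
    else:
        v = np.array([np.mean(np.asarray(counts_by_mouse[m], dtype=float))
                      for m in mice])
        stat = lambda sel: np.var(v[sel], ddof=1) - np.var(v[~sel], ddof=1)  # noqa: E731
    sel_obs = labels == groups[0]
    t_obs = float(stat(sel_obs))
    rng = np.random.default_rng(seed)
    n_a = int(sel_obs.sum())
    n = len(mice)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        sel = np.zeros(n, dtype=bool)
        sel[perm[:n_a]] = True
        if abs(stat(sel)) >= abs(t_obs) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(observed=t_obs, n_permutations=n_perm,
                             p_value=p, seed=seed, level=level)


# ---------------------------------------------------------------------------
# logistic model

@dataclass
class LogisticFit:
    params: dict[str, float]
    pvalues: dict[str, float]
    n: int
    converged: bool


def logistic_focus_model(sc_lengths, focus_classes, covariate=None) -> LogisticFit:
    """Logistic regression of P(2 foci vs 1) on SC length (+ optional covariate).

    Raises on a single-class sample or perfect separation rather than
    returning silently unstable estimates.
    """
    length = np.asarray(sc_lengths, dtype=float)
    cls = np.asarray(focus_classes, dtype=int)
    if not set(np.unique(cls)) <= {1, 2}:
        raise ValueError("focus classes must be 1 or 2")
    if len(np.unique(cls)) < 2:
        raise ValueError("both focus classes must be present")
    y = (cls == 2).astype(float)
    cols = {"sc_length": length}
    if covariate is not None:
        cols["covariate"] = np.asarray(covariate, dtype=float)
    X = sm.add_constant(pd.DataFrame(cols))
    try:
        with warnings.catch_warnings():
            # separation/convergence surface as an explicit error below
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False) or np.abs(fit.params).max() > 1e3:
        raise ValueError("logistic fit did not converge (possible separation)")
    return LogisticFit(params=dict(fit.params), pvalues=dict(fit.pvalues),
                       n=len(y), converged=True)
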