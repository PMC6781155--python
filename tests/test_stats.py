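"""Crossover-patterning statistics: summaries, interference, r-bar, tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from scxover.stats import (
    DegenerateSampleError,
    SummaryRow,
    fit_gamma_mle,
    fit_interference,
    focus_class_table,
    ks_compare,
    logistic_focus_model,
    map_length_cM,
    permutation_test_variance,
    pool_group,
    position_histogram,
    rbar_intra,
    rbar_intra_mc,
    summarize_counts,
)


class TestSummaryRow:
    def test_published_worked_example(self):
        # printed per-mouse row: n=26, mean=23.269, SD=0.667
        s = SummaryRow.from_moments(23.269, 0.667, 26)
        assert round(s.se, 3) == 0.131
        assert s.cv == pytest.approx(2.865, abs=0.002)

    def test_forced_by_definitions(self):
        s = SummaryRow.from_values([22, 23, 24])
        assert s.mean == 23 and s.sd == pytest.approx(1.0)
        assert s.se == pytest.approx(0.577, abs=5e-4)
        assert s.cv == pytest.approx(4.348, abs=5e-4)

    def test_constant_vector(self):
        s = SummaryRow.from_values([23, 23, 23])
        assert s.sd == 0.0 and s.cv == 0.0

    def test_insufficient_n_gives_missing_spread(self):
        s = SummaryRow.from_values([23])
        assert s.mean == 23 and math.isnan(s.sd) and math.isnan(s.se)

    @given(st.lists(st.floats(1.0, 100.0), min_size=2, max_size=40))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_identities(self, values):
        s = SummaryRow.from_values(values)
        assert s.se * math.sqrt(s.n) == pytest.approx(s.sd, abs=1e-9)
        assert s.cv * s.mean == pytest.approx(100.0 * s.sd, abs=1e-6)
        assert s.cv >= 0

    def test_groupby_frame(self):
        df = pd.DataFrame({"mouse": ["a"] * 3 + ["b"] * 2, "count": [22, 23, 24, 20, 22]})
        out = summarize_counts(df, "count", ["mouse"]).set_index("mouse")
        assert out.loc["a", "n"] == 3 and out.loc["a", "mean"] == 23


def _wild_rows():
    from scxover.tables import load_count_summary
    d = load_count_summary()
    return d[d["status"] == "wild"]


class TestPoolGroup:
    def test_wild_group_means_match_published(self):
        w = _wild_rows()
        pooled = pool_group(w["n_cells"], w["mean"], w["sd"])
        assert pooled.n == 221
        assert round(pooled.unweighted_mean, 2) == 23.50
        assert round(pooled.weighted_mean, 2) == 23.53

    def test_pooled_spread_matches_published_group_row(self):
        w = _wild_rows()
        pooled = pool_group(w["n_cells"], w["mean"], w["sd"])
        assert pooled.se == pytest.approx(0.085, abs=5e-4)
        assert pooled.cv == pytest.approx(5.4, abs=0.05)

    def test_single_mouse_pools_to_itself(self):
        pooled = pool_group([10], [23.0], [1.0])
        assert pooled.weighted_mean == 23.0 == pooled.unweighted_mean
        assert pooled.sd == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pool_group([], [])


class TestMapLength:
    @pytest.mark.parametrize("mean, cm", [(23.504, 1175.2), (0.0, 0.0), (23.0, 1150.0)])
    def test_values(self, mean, cm):
        assert map_length_cM(mean) == pytest.approx(cm, abs=0.05)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            map_length_cM(-1.0)


class TestFocusClassTable:
    def test_published_single_mouse_percentage(self):
        # 21 chromosome-1 bivalents, 13 with a single focus -> 62%
        n_foci = [1] * 13 + [2] * 8
        t = focus_class_table(n_foci).set_index("group")
        assert t.loc["all", "n1"] == 13
        assert round(t.loc["all", "pct1"]) == 62

    def test_rare_three_focus_percentage(self):
        from scxover.tables import load_chr1_summary
        d = load_chr1_summary()
        total = int(d["n_bivalents"].sum())
        n3 = int(d["n3"].sum())
        assert total == 255 and n3 == 4
        assert round(100.0 * n3 / total, 1) == 1.6

    def test_empty_input_gives_zero_table(self):
        t = focus_class_table([]).set_index("group")
        assert t.loc["all", "total"] == 0 and t.loc["all", "pct0"] == 0.0

    def test_counts_sum_to_total_per_group(self):
        rng = np.random.default_rng(1)
        n = rng.integers(0, 4, 60)
        g = rng.choice(["a", "b"], 60)
        t = focus_class_table(n, g)
        for _, row in t.iterrows():
            assert row[["n0", "n1", "n2", "n3"]].sum() == row["total"]


class TestPositionHistogram:
    def test_single_focus_falls_in_expected_bin(self):
        out = position_histogram({"focus1": np.array([0.50])}, focus_class=1)
        idx = 10  # [0.50, 0.55)
        assert out.series["focus1"][idx] == 1
        assert out.series["focus1"].sum() == 1

    def test_two_focus_series_conserve_counts(self):
        rng = np.random.default_rng(2)
        n = 40
        df = pd.DataFrame({"foci_pos_norm": [
            f"{a:.4f};{b:.4f}" for a, b in zip(rng.uniform(0, 0.4, n),
                                               rng.uniform(0.6, 1.0, n))]})
        out = position_histogram(df, focus_class=2)
        assert out.series["focus1"].sum() == n
        assert out.series["focus2"].sum() == n

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            position_histogram({"focus1": np.array([1.2])}, focus_class=1)

    def test_uniform_positions_pass_chi_square(self):
        rejections = 0
        for seed in range(40):
            x = np.random.default_rng(seed).uniform(0, 1, 400)
            out = position_histogram({"focus1": x}, focus_class=1)
            p = sps.chisquare(out.series["focus1"]).pvalue
            rejections += p < 0.01
        assert rejections / 40 <= 0.05


class TestKSCompare:
    def test_identical_samples_d_zero(self):
        x = np.linspace(0.1, 0.9, 20)
        d, _ = ks_compare(x, x)
        assert d == 0.0

    def test_disjoint_supports_d_one(self):
        d, p = ks_compare(np.linspace(0.0, 0.4, 15), np.linspace(0.6, 1.0, 15))
        assert d == 1.0 and p < 1e-4

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([0.5], [0.1, 0.9])

    def test_null_calibration(self):
        rejections = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            _, p = ks_compare(rng.uniform(0, 1, 40), rng.uniform(0, 1, 40))
            rejections += p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.10


class TestGammaMLE:
    def test_recovers_interference_scale_shape(self):
        rng = np.random.default_rng(11)
        x = rng.gamma(shape=11.0, scale=0.5, size=10_000)
        shape, scale = fit_gamma_mle(x)
        assert 10.0 <= shape <= 12.0
        assert scale == pytest.approx(0.5, rel=0.1)

    def test_exponential_is_shape_one(self):
        rng = np.random.default_rng(3)
        shape, _ = fit_gamma_mle(rng.exponential(2.0, size=10_000))
        assert 0.9 <= shape <= 1.1

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateSampleError, match="unbounded"):
            fit_gamma_mle(np.full(50, 2.0))

    def test_agrees_with_independent_mle(self):
        # cross-check the Newton solver against scipy's gamma MLE (floc=0)
        rng = np.random.default_rng(7)
        x = rng.gamma(shape=4.0, scale=1.3, size=2_000)
        shape, scale = fit_gamma_mle(x)
        a_ref, _, scale_ref = sps.gamma.fit(x, floc=0)
        assert shape == pytest.approx(a_ref, rel=1e-3)
        assert scale == pytest.approx(scale_ref, rel=1e-3)


class TestFitInterference:
    def _frame(self, d_px, L=130.0):
        return pd.DataFrame({
            "sc_length_px": L,
            "foci_pos_px": [f"10.0;{10.0 + d}" for d in d_px],
        })

    def test_short_distances_excluded_as_outliers(self):
        rng = np.random.default_rng(5)
        good = rng.gamma(11.0, 9.0, 200)  # px; ~10 um mean at 9.8152 px/um
        bad = np.array([3.0, 5.0])  # < 1 um
        fit = fit_interference(self._frame(np.concatenate([good, bad])),
                               mode="absolute_um")
        assert fit.n_excluded == 2
        assert fit.n_distances == 200
        assert 8.0 <= fit.nu <= 14.0

    def test_normalized_mode_uses_sc_length(self):
        d = np.full(30, 65.0)
        df = self._frame(d, L=130.0)
        df["foci_pos_px"] = [f"10.0;{10.0 + v}" for v in d + np.linspace(-5, 5, 30)]
        fit = fit_interference(df, mode="normalized")
        assert fit.mode == "normalized"
        assert 0.4 <= fit.nu * fit.scale <= 0.6  # mean normalized distance ~ 0.5

    def test_insufficient_distances_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_interference(self._frame(np.full(5, 60.0)))


class TestRbar:
    @pytest.mark.parametrize("positions, expected", [
        ((), 0.0),
        ((0.5,), 0.25),
        ((0.2, 0.8), 0.28),
    ])
    def test_closed_form_values(self, positions, expected):
        assert rbar_intra(positions) == pytest.approx(expected, abs=1e-12)

    def test_monte_carlo_oracle_agrees(self):
        rng = np.random.default_rng(17)
        for _ in range(12):
            m = rng.integers(0, 4)
            pos = np.sort(rng.uniform(0, 1, m))
            closed = rbar_intra(pos)
            mc = rbar_intra_mc(pos, n_gametes=400_000, rng=rng)
            assert mc == pytest.approx(closed, abs=0.003)

    @given(st.lists(st.floats(0.0, 1.0), min_size=0, max_size=6))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_bounded_in_0_half(self, positions):
        v = rbar_intra(sorted(positions))
        assert 0.0 <= v <= 0.5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rbar_intra([0.8, 0.2])
        with pytest.raises(ValueError):
            rbar_intra([-0.1])


def _mouse_data(rng, n_mice, n_cells=20, sd=1.2, mean=23.0):
    return {f"m{i}": rng.normal(mean, sd, n_cells) for i in range(n_mice)}


class TestPermutationVariance:
    def test_matches_exhaustive_enumeration(self):
        """4+4 mice: Monte-Carlo permutation p equals the exhaustive
        label-assignment p within Monte-Carlo error."""
        rng = np.random.default_rng(23)
        counts = _mouse_data(rng, 8)
        mice = sorted(counts)
        status = {m: ("wild" if i < 4 else "lab") for i, m in enumerate(mice)}
        res = permutation_test_variance(counts, status, "within_mouse_variance",
                                        n_perm=4000, seed=1)
        v = np.array([np.var(counts[m], ddof=1) for m in mice])
        t_obs = v[:4].mean() - v[4:].mean()
        hits = total = 0
        for comb in itertools.combinations(range(8), 4):
            sel = np.zeros(8, bool)
            sel[list(comb)] = True
            total += 1
            hits += abs(v[sel].mean() - v[~sel].mean()) >= abs(t_obs) - 1e-12
        exact = hits / total
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_power_against_tenfold_variance_ratio(self):
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            counts = {}
            status = {}
            for i in range(8):
                counts[f"w{i}"] = rng.normal(23, 0.5, 20)
                status[f"w{i}"] = "wild"
                counts[f"l{i}"] = rng.normal(23, 0.5 * math.sqrt(10), 20)
                status[f"l{i}"] = "lab"
            res = permutation_test_variance(counts, status, "within_mouse_variance",
                                            n_perm=400, seed=seed)
            hits += res.p_value < 0.05
        assert hits / n_rep >= 0.8

    def test_among_mouse_level_and_reproducibility(self):
        rng = np.random.default_rng(9)
        counts = _mouse_data(rng, 10)
        status = {m: ("wild" if i % 2 else "lab") for i, m in enumerate(sorted(counts))}
        a = permutation_test_variance(counts, status, "among_mouse_variance",
                                      n_perm=500, seed=42)
        b = permutation_test_variance(counts, status, "among_mouse_variance",
                                      n_perm=500, seed=42)
        assert a.p_value == b.p_value
        assert 0 < a.p_value <= 1

    def test_too_few_mice_rejected(self):
        rng = np.random.default_rng(0)
        counts = _mouse_data(rng, 3)
        status = {"m0": "wild", "m1": "lab", "m2": "lab"}
        with pytest.raises(ValueError, match="fewer than 2"):
            permutation_test_variance(counts, status, "within_mouse_variance")


class TestLogisticModel:
    def test_recovers_simulated_slope(self):
        rng = np.random.default_rng(31)
        n = 500
        length = rng.uniform(10, 16, n)
        beta = 1.5
        p = 1 / (1 + np.exp(-(beta * (length - 13.0))))
        cls = np.where(rng.random(n) < p, 2, 1)
        fit = logistic_focus_model(length, cls)
        assert 1.1 <= fit.params["sc_length"] <= 1.9
        assert fit.pvalues["sc_length"] < 0.05

    def test_null_slope_not_significant(self):
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(500 + seed)
            length = rng.uniform(10, 16, 500)
            cls = rng.choice([1, 2], 500)
            fit = logistic_focus_model(length, cls)
            hits += fit.pvalues["sc_length"] > 0.05
        assert hits / n_rep >= 0.9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            logistic_focus_model([10.0, 12.0, 14.0], [1, 1, 1])

    def test_perfect_separation_rejected(self):
        length = np.concatenate([np.linspace(10, 11, 20), np.linspace(15, 16, 20)])
        cls = np.array([1] * 20 + [2] * 20)
        with pytest.raises(ValueError):
            logistic_focus_model(length, cls)
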