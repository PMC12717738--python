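"""Agreement statistics: hand-computed oracles, library cross-checks,
simulation recoveries and distributional properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tripecg.agreement import (
    AgreementError,
    PairedSeries,
    bh_fdr,
    bland_altman,
    clustered_bland_altman,
    compare_tables,
    comparison_table,
    icc_2_1,
    limits_of_agreement,
    repeatability_coefficient,
    tost_ni,
)


class TestBlandAltman:
    def test_identical_pairs(self):
        s = PairedSeries(np.arange(5.0), np.arange(5.0))
        out = bland_altman(s)
        assert out["bias"] == 0.0
        assert out["sd_diff"] == 0.0
        assert out["prop_bias_slope"] == 0.0
        assert "constant_differences" in out["flags"]

    def test_hand_computed_moments(self):
        # d = (-1, -1, 1): mean -1/3, sample SD sqrt(4/3)
        s = PairedSeries(np.array([0.0, 1.0, 3.0]), np.array([1.0, 2.0, 2.0]))
        out = bland_altman(s)
        assert out["bias"] == pytest.approx(-1.0 / 3.0)
        assert out["sd_diff"] == pytest.approx(np.sqrt(4.0 / 3.0))

    def test_constant_offset_skips_regression(self):
        s = PairedSeries(np.array([3.0, 5.0, 9.0]), np.array([1.0, 3.0, 7.0]))
        out = bland_altman(s)
        assert out["bias"] == 2.0
        assert out["sd_diff"] == 0.0
        assert "constant_differences" in out["flags"]

    def test_proportional_bias_detected(self):
        x = np.linspace(10, 50, 40)
        s = PairedSeries(x * 1.2, x)  # difference grows with the mean
        out = bland_altman(s)
        assert out["prop_bias_slope"] > 0
        assert out["prop_bias_p"] < 1e-6

    def test_too_few_pairs(self):
        with pytest.raises(AgreementError):
            PairedSeries(np.array([1.0]), np.array([2.0]))


class TestLoaRc:
    def test_printed_inter_reader_qtc_row(self):
        lo, hi = limits_of_agreement(0.02, 1.32)
        assert round(hi, 2) == 2.61
        assert round(lo, 2) == -2.57

    def test_printed_inter_reader_qrs_row(self):
        lo, hi = limits_of_agreement(1.08, 2.77)
        assert round(hi, 2) == 6.51
        assert round(lo, 2) == -4.35

    def test_degenerate_sd(self):
        assert limits_of_agreement(3.0, 0.0) == (3.0, 3.0)
        assert repeatability_coefficient(0.0) == 0.0

    @given(st.floats(-100, 100), st.floats(0, 100))
    def test_affine_and_bracketing(self, bias, sd):
        lo, hi = limits_of_agreement(bias, sd)
        assert lo == pytest.approx(bias - 1.96 * sd)
        assert hi == pytest.approx(bias + 1.96 * sd)
        assert lo <= bias <= hi
        assert repeatability_coefficient(sd) == pytest.approx(1.96 * sd)


def icc21_bruteforce(table: np.ndarray) -> float:
    """Independent oracle: two-way ANOVA by explicit summation loops."""
    n, k = table.shape
    grand = sum(table[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(table[i]) / k for i in range(n)]
    col = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sst = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestIcc:
    def test_perfect_agreement(self):
        table = np.column_stack([np.array([0.0, 10.0, 20.0])] * 2)
        icc, ci = icc_2_1(table)
        assert icc == pytest.approx(1.0)

    def test_hand_anova_example(self):
        # rater2 = rater1 + 2 with rater1 = (0, 10, 20): MSR 200, MSC 6, MSE 0
        r1 = np.array([0.0, 10.0, 20.0])
        icc, _ = icc_2_1(np.column_stack([r1, r1 + 2]))
        assert icc == pytest.approx(200.0 / 204.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(AgreementError, match="undefined"):
            icc_2_1(np.full((4, 2), 7.0))

    def test_incomplete_table_rejected(self):
        table = np.ones((4, 2))
        table[1, 1] = np.nan
        with pytest.raises(AgreementError):
            icc_2_1(table)

    @given(st.integers(0, 10**4))
    def test_matches_bruteforce_on_random_integer_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        k = int(rng.integers(2, 5))
        table = rng.integers(0, 6, size=(n, k)).astype(float)
        if np.ptp(table) == 0:
            return
        icc, _ = icc_2_1(table)
        assert icc == pytest.approx(icc21_bruteforce(table), abs=1e-10)

    def test_point_and_ci_match_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(8, 20))
            table = rng.normal(50, 10, size=(n, 1))
            ratings = np.hstack([table + rng.normal(0, 2, size=(n, 1)),
                                 table + rng.normal(0, 2, size=(n, 1))])
            icc, (lo, hi) = icc_2_1(ratings)
            df = pd.DataFrame({
                "subject": np.repeat(np.arange(n), 2),
                "rater": np.tile(["a", "b"], n),
                "score": ratings.ravel(),
            })
            ref = pingouin.intraclass_corr(df, targets="subject",
                                           raters="rater", ratings="score")
            mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
            row = ref[mask].iloc[0]
            ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
            assert icc == pytest.approx(row["ICC"], abs=1e-9)
            # pingouin reports the CI rounded to 2 decimals
            assert lo == pytest.approx(row[ci_col][0], abs=0.011)
            assert hi == pytest.approx(row[ci_col][1], abs=0.011)


class TestClusteredBlandAltman:
    def test_no_clustering_signal_reduces_to_simple(self, rng):
        d = rng.normal(0, 1, size=60)
        subj = np.repeat(np.arange(30), 2)
        out = clustered_bland_altman(d, subj)
        simple_sd = np.std(d, ddof=1)
        assert out["sd_total"] == pytest.approx(simple_sd, rel=0.25)
        assert not out["fallback_simple"]

    def test_recovers_known_components(self, rng):
        # subject effect SD 2 + residual SD 1, 30 subjects x 4 pairs
        n_subj, n_rep = 30, 4
        subj_eff = rng.normal(0, 2.0, size=n_subj)
        d = (np.repeat(subj_eff, n_rep)
             + rng.normal(0, 1.0, size=n_subj * n_rep))
        out = clustered_bland_altman(d, np.repeat(np.arange(n_subj), n_rep))
        assert np.sqrt(out["var_subject"]) == pytest.approx(2.0, rel=0.30)
        assert np.sqrt(out["var_residual"]) == pytest.approx(1.0, rel=0.30)
        # total LOA wider than the naive within-subject LOA
        assert out["sd_total"] == pytest.approx(np.sqrt(5.0), rel=0.30)

    def test_single_subject_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="single subject"):
            out = clustered_bland_altman([1.0, 2.0, 3.0], ["s1", "s1", "s1"])
        assert out["fallback_simple"]


class TestTost:
    def test_all_zero_differences_pass(self):
        out = tost_ni(np.zeros(10))
        assert out["ni_pass_5ms"] and out["e14_pass_10ms"]
        assert "degenerate_zero_sd" in out["flags"]

    def test_constant_six_fails_5ms_margin(self):
        out = tost_ni(np.full(10, 6.0))
        assert not out["ni_pass_5ms"]

    def test_power_at_study_scale(self):
        # differences ~ N(0, 3), n = 140: the 90% CI half-width is ~0.42 ms,
        # so the ±5 ms margin is met essentially always
        rng = np.random.default_rng(42)
        passes = sum(
            tost_ni(rng.normal(0, 3, size=140))["ni_pass_5ms"]
            for _ in range(1000))
        assert passes / 1000 > 0.99

    def test_ci_matches_t_formula(self):
        from scipy import stats

        d = np.array([1.0, 2.0, 0.5, 1.5, 2.5, 0.0])
        out = tost_ni(d)
        se = d.std(ddof=1) / np.sqrt(d.size)
        t_crit = stats.t.ppf(0.95, d.size - 1)
        assert out["ci90_lower"] == pytest.approx(d.mean() - t_crit * se)
        assert out["ci90_upper"] == pytest.approx(d.mean() + t_crit * se)

    def test_agrees_with_statsmodels_ttost(self):
        sm = pytest.importorskip("statsmodels.stats.weightstats")
        rng = np.random.default_rng(3)
        d = rng.normal(1.0, 2.0, size=50)
        out = tost_ni(d, margin=5.0)
        p, (t1, p1, _), (t2, p2, _) = sm.ttost_paired(d, np.zeros_like(d),
                                                      -5.0, 5.0)
        assert out["tost_p"] == pytest.approx(p, abs=1e-10)

    @given(st.integers(0, 10**3))
    def test_margin_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(rng.uniform(-4, 4), rng.uniform(0.1, 5), size=20)
        small = tost_ni(d, margin=5.0)
        large = tost_ni(d, margin=8.0)
        if small["ni_pass_5ms"]:
            assert large["ni_pass_5ms"]


class TestBhFdr:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(AgreementError):
            bh_fdr([0.1, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_dominates_raw(self, ps):
        adj = bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, size=40)
        ref = mt.multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(p), ref, atol=1e-12)


class TestCompareTables:
    def _table(self, rng, n=30, noise_sd=0.0, seed_vals=None):
        vals = seed_vals if seed_vals is not None else {
            "hr_bpm": rng.normal(65, 8, n),
            "pr_ms": rng.normal(160, 15, n),
            "qrs_ms": rng.normal(95, 10, n),
            "qtcf_ms": rng.normal(400, 20, n),
            "soko_v5_uv": rng.normal(2000, 400, n),
            "soko_v6_uv": rng.normal(1800, 350, n),
        }
        df = pd.DataFrame(vals)
        if noise_sd:
            df = df + rng.normal(0, noise_sd, df.shape)
        df.insert(0, "subject_id", [f"S{i:02d}" for i in range(n)])
        df.insert(1, "visit_label", "D0")
        return df

    def test_self_comparison(self, rng):
        t = self._table(rng)
        results = compare_tables(t, t.copy())
        for res in results.values():
            assert res.bias == 0.0
            assert res.sd_diff == 0.0
            assert res.icc == pytest.approx(1.0)

    def test_reader_noise_sd_recovered(self):
        rng = np.random.default_rng(17)
        n, sd = 140, 2.0
        base = {
            "hr_bpm": rng.normal(65, 8, n), "pr_ms": rng.normal(160, 15, n),
            "qrs_ms": rng.normal(95, 10, n), "qtcf_ms": rng.normal(400, 20, n),
            "soko_v5_uv": rng.normal(2000, 400, n),
            "soko_v6_uv": rng.normal(1800, 350, n),
        }
        a = self._table(rng, n, seed_vals=base)
        b = self._table(rng, n, seed_vals=base)
        noisy_a = a.copy()
        noisy_b = b.copy()
        for col in base:
            noisy_a[col] = a[col] + rng.normal(0, sd, n)
            noisy_b[col] = b[col] + rng.normal(0, sd, n)
        results = compare_tables(noisy_a, noisy_b)
        expected = np.sqrt(2) * sd
        for res in results.values():
            assert res.sd_diff == pytest.approx(expected, rel=0.30)

    def test_disjoint_keys_rejected(self, rng):
        a = self._table(rng)
        b = self._table(rng)
        b["subject_id"] = "T" + b["subject_id"]
        with pytest.raises(AgreementError, match="empty join"):
            compare_tables(a, b)

    def test_report_table_layout(self, rng):
        t = self._table(rng)
        table = comparison_table(compare_tables(t, t.copy()))
        assert list(table["parameter"]) == ["hr_bpm", "pr_ms", "qrs_ms",
                                            "qtcf_ms", "soko_v5_uv", "soko_v6_uv"]
        for col in ("icc", "bias", "sd_bias", "loa_upper", "loa_lower", "rc"):
            assert col in table.columns
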