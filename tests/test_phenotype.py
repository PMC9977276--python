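"""Growth-curve fitting, assay rates, ANOVA/Tukey, efficiency ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ancseq.phenotype import (
    AssayTable,
    GrowthCurveData,
    LogisticGrowthModel,
    anova_tukey,
    efficiency_ratio,
    fit_logistic,
    logistic,
    reduction_rate,
)
from ancseq.synthetic import simulate_growth_curves


class TestLogisticFit:
    def test_noiseless_exact_recovery(self):
        t = np.arange(0.0, 49.0)
        K, r, N0 = 1.2, 0.35, 0.01
        curve = GrowthCurveData("wt", 1, t, logistic(t, K, r, N0))
        fit = fit_logistic(curve)
        assert fit.success
        assert fit.K == pytest.approx(K, rel=1e-6)
        assert fit.r == pytest.approx(r, rel=1e-6)
        assert fit.N0 == pytest.approx(N0, rel=1e-6)

    def test_derived_times_identities(self):
        t = np.arange(0.0, 49.0)
        fit = fit_logistic(GrowthCurveData("wt", 1, t, logistic(t, 1.2, 0.35, 0.01)))
        assert fit.doubling_time == pytest.approx(np.log(2) / fit.r, abs=1e-12)
        assert fit.t_mid == pytest.approx(np.log((fit.K - fit.N0) / fit.N0) / fit.r, abs=1e-9)
        assert fit.doubling_time == pytest.approx(np.log(2) / 0.35, rel=1e-6)

    def test_time_origin_equivariance(self):
        t = np.arange(0.0, 49.0)
        y = logistic(t, 1.0, 0.4, 0.02)
        base = fit_logistic(GrowthCurveData("s", 1, t, y))
        delta = 5.0
        shifted = fit_logistic(GrowthCurveData("s", 1, t + delta, y))
        assert shifted.K == pytest.approx(base.K, abs=1e-8)
        assert shifted.r == pytest.approx(base.r, abs=1e-8)
        assert shifted.t_mid == pytest.approx(base.t_mid + delta, abs=1e-6)

    def test_degenerate_fit_flagged_not_silent(self):
        t = np.arange(0.0, 10.0)
        fit = fit_logistic(GrowthCurveData("s", 1, t, np.zeros_like(t)))
        assert not fit.success
        assert fit.message

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 5 time points"):
            fit_logistic(GrowthCurveData("s", 1, [0, 1, 2, 3], [0.1, 0.2, 0.3, 0.4]))

    def test_noisy_recovery_median_error_under_2pct(self):
        true = {"wt": (1.2, 0.35, 0.01)}
        curves = simulate_growth_curves(true, noise_sd=0.01, n_replicates=50, seed=77)
        res = LogisticGrowthModel(curves).fit()
        df = res.to_frame()
        assert df["success"].all()
        r_err = np.abs(df["r"] - 0.35) / 0.35
        K_err = np.abs(df["K"] - 1.2) / 1.2
        assert np.median(r_err) < 0.02
        assert np.median(K_err) < 0.02

    def test_model_from_dataframe_and_summary(self):
        curves = simulate_growth_curves(
            {"wt": (1.2, 0.35, 0.01), "anc": (1.1, 0.30, 0.01)},
            noise_sd=0.005, n_replicates=5, seed=5,
        )
        rows = []
        for c in curves:
            for t, y in zip(c.time, c.od600):
                rows.append({"strain": c.strain, "replicate": c.replicate,
                             "time_h": t, "od600": y})
        res = LogisticGrowthModel.from_dataframe(pd.DataFrame(rows)).fit()
        summ = res.summary().set_index("strain")
        assert set(summ.index) == {"wt", "anc"}
        assert (summ["n"] == 5).all()
        assert summ.loc["anc", "doubling_time_h"] > summ.loc["wt", "doubling_time_h"]


class TestReductionRate:
    def test_exact_line(self):
        t = np.array([0.25, 0.5, 0.75, 1.0])
        est = reduction_rate(t, 0.25 * t, protein_mg=0.05)
        assert est.rate == pytest.approx(5.0, abs=1e-12)
        assert est.se == pytest.approx(0.0, abs=1e-10)

    def test_constant_product_is_zero_rate(self):
        est = reduction_rate([0.25, 0.5, 0.75, 1.0], [2, 2, 2, 2], protein_mg=1.0)
        assert est.rate == pytest.approx(0.0, abs=1e-12)

    def test_sampling_distribution_matches_ols_theory(self):
        rng = np.random.default_rng(42)
        t = np.array([0.25, 0.5, 0.75, 1.0])
        slope, sd = 9.0, 0.1
        estimates = []
        for _ in range(200):
            y = slope * t + rng.normal(0, sd, t.size)
            estimates.append(reduction_rate(t, y, 1.0).rate)
        analytic_se = sd / np.sqrt(((t - t.mean()) ** 2).sum())
        assert abs(np.mean(estimates) - slope) < analytic_se

    def test_invalid_protein_mass_rejected(self):
        with pytest.raises(ValueError, match="protein"):
            reduction_rate([0.25, 0.5, 0.75], [1, 2, 3], protein_mg=0.0)


class TestAnovaTukey:
    def test_two_group_tukey_equals_pooled_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
        res = anova_tukey(AssayTable(["a", "b"], [a, b]))
        t_p = stats.ttest_ind(a, b).pvalue
        assert res.pairwise.loc[0, "p_adj"] == pytest.approx(t_p, abs=1e-6)
        assert res.p_value == pytest.approx(t_p, abs=1e-9)

    def test_all_identical_degenerate(self):
        res = anova_tukey(AssayTable(["a", "b"], [np.ones(3), np.ones(3)]))
        assert res.degenerate
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_zero_within_variance_unequal_means(self):
        res = anova_tukey(AssayTable(["a", "b"], [np.ones(3), 2 * np.ones(3)]))
        assert res.degenerate
        assert res.p_value == 0.0
        assert res.pairwise.loc[0, "p_adj"] == 0.0

    def test_location_shift_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, 5) for m in (0.0, 0.5, 1.0)]
        base = anova_tukey(AssayTable(["a", "b", "c"], groups))
        shifted = anova_tukey(AssayTable(["a", "b", "c"], [g + 7.0 for g in groups]))
        scaled = anova_tukey(AssayTable(["a", "b", "c"], [g * 3.0 for g in groups]))
        assert shifted.f_statistic == pytest.approx(base.f_statistic, rel=1e-10)
        assert scaled.f_statistic == pytest.approx(base.f_statistic, rel=1e-10)
        assert np.allclose(shifted.pairwise["p_adj"], base.pairwise["p_adj"], atol=1e-10)

    def test_p_monotone_in_mean_difference(self):
        rng = np.random.default_rng(3)
        noise = [rng.normal(0, 1, 6) for _ in range(2)]
        ps = []
        for diff in [0.2, 0.8, 2.0, 5.0]:
            res = anova_tukey(AssayTable(["a", "b"], [noise[0], noise[1] + diff]))
            ps.append(res.pairwise.loc[0, "p_adj"])
        assert ps == sorted(ps, reverse=True)

    def test_unbalanced_groups_tukey_kramer(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, n) for n in (3, 5, 8)]
        res = anova_tukey(AssayTable(["a", "b", "c"], groups))
        assert ((res.pairwise["p_adj"] >= 0) & (res.pairwise["p_adj"] <= 1)).all()
        assert len(res.pairwise) == 3

    def test_single_replicate_group_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            anova_tukey(AssayTable(["a", "b"], [np.array([1.0]), np.ones(3)]))


class TestEfficiencyRatio:
    def test_simple_ratio(self):
        assert efficiency_ratio(4.0, 2.0).ratio == 2.0

    def test_ammonia_conversion(self):
        r = efficiency_ratio(4.0, 4.0, from_ammonia=True)
        assert r.ratio == pytest.approx(2.0)

    def test_below_floor_flagged_not_rejected(self):
        r = efficiency_ratio(0.9, 1.0)
        assert r.ratio == pytest.approx(0.9)
        assert r.below_floor

    def test_nonpositive_n2_rejected(self):
        with pytest.raises(ValueError):
            efficiency_ratio(1.0, 0.0)
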