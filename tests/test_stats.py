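"""OLS / exponential / rank-based regression, group tests, corrections."""

import numpy as np
import pandas as pd
import pytest

from mtaging.stats import (StatsError, bin_delta, bonferroni, chisq_yates,
                           exp_regression, hodges_lehmann_shift, kruskal_dunn,
                           ols_fit, rank_fit)


def frame(**cols):
    return pd.DataFrame(cols)


class TestOls:
    def test_noiseless_recovery(self):
        age = np.linspace(20, 90, 40)
        df = frame(y=3 + 2 * age, age=age)
        fit = ols_fit(df, "y", ["age"])
        assert fit.coefficients["age"] == pytest.approx(2.0)
        assert fit.coefficients["intercept"] == pytest.approx(3.0)

    def test_constant_response(self):
        df = frame(y=np.full(30, 7.0), age=np.linspace(0, 1, 30))
        fit = ols_fit(df, "y", ["age"])
        assert fit.coefficients["age"] == pytest.approx(0.0, abs=1e-10)
        assert fit.p_values["age"] == pytest.approx(1.0)

    def test_simulated_slope_within_3_se(self):
        rng = np.random.default_rng(7)
        age = rng.uniform(0, 100, 200)
        y = 5 - 0.8 * age + rng.normal(0, 1, 200)
        fit = ols_fit(frame(y=y, age=age), "y", ["age"])
        assert abs(fit.coefficients["age"] + 0.8) < 3 * fit.standard_errors["age"]

    def test_rank_deficient_design(self):
        df = frame(y=np.arange(20.0), a=np.arange(20.0), b=2 * np.arange(20.0))
        with pytest.raises(StatsError, match="rank-deficient"):
            ols_fit(df, "y", ["a", "b"])

    def test_type_one_error_calibration(self):
        """Null rejection rate of the slope t-test at alpha=0.05."""
        rng = np.random.default_rng(11)
        n, reps = 100, 2000
        age = rng.uniform(0, 100, n)
        rejections = 0
        for _ in range(reps):
            y = rng.normal(0, 1, n)
            fit = ols_fit(frame(y=y, age=age), "y", ["age"])
            rejections += fit.p_values["age"] < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestExpRegression:
    def test_noiseless_exponential_recovery(self):
        age = np.linspace(1, 99, 60)
        metric = np.exp(-2.0 + 0.03 * age) - 0.01
        fit = exp_regression(frame(m=metric, age=age), "m", "age")
        assert fit.coefficients["age"] == pytest.approx(0.03, abs=1e-9)
        assert fit.coefficients["intercept"] == pytest.approx(-2.0, abs=1e-9)
        assert fit.model_kind == "log_linear"

    def test_all_zero_metric(self):
        df = frame(m=np.zeros(30), age=np.linspace(0, 1, 30))
        fit = exp_regression(df, "m", "age")
        assert fit.coefficients["age"] == pytest.approx(0.0, abs=1e-10)
        assert fit.coefficients["intercept"] == pytest.approx(np.log(0.01))

    def test_negative_metric_rejected(self):
        df = frame(m=[-0.1, 0.2, 0.3] * 5, age=list(range(15)))
        with pytest.raises(StatsError, match="negative"):
            exp_regression(df, "m", "age")

    def test_equals_ols_on_transformed_response(self):
        rng = np.random.default_rng(5)
        df = frame(
            m=rng.gamma(2, 0.1, 80),
            age=rng.uniform(0, 100, 80),
            cov=rng.normal(0, 1, 80),
        )
        ef = exp_regression(df, "m", "age", ["cov"])
        df["ln"] = np.log(df["m"] + 0.01)
        of = ols_fit(df, "ln", ["age", "cov"])
        for term in ("intercept", "age", "cov"):
            assert ef.coefficients[term] == pytest.approx(of.coefficients[term])
            assert ef.p_values[term] == pytest.approx(of.p_values[term])


class TestBinDelta:
    def test_linear_bin_change(self):
        fit = ols_fit(frame(y=100 - 12.882 * np.linspace(0, 100, 50),
                            age=np.linspace(0, 100, 50)), "y", ["age"])
        assert bin_delta(fit, 30.0, 15.0) == pytest.approx(-193.23, abs=1e-6)

    def test_zero_slope_log_linear(self):
        df = frame(m=np.full(30, 0.5), age=np.linspace(0, 99, 30))
        fit = exp_regression(df, "m", "age")
        assert bin_delta(fit, 30.0) == pytest.approx(0.0, abs=1e-9)

    def test_exponential_bins_accelerate(self):
        age = np.linspace(1, 99, 80)
        metric = np.exp(-3.0 + 0.028 * age) - 0.01
        fit = exp_regression(frame(m=metric, age=age), "m", "age")
        assert bin_delta(fit, 60.0) > 2 * bin_delta(fit, 30.0) > 0

    def test_missing_covariate_profile(self):
        rng = np.random.default_rng(0)
        df = frame(m=rng.gamma(2, 0.1, 40), age=rng.uniform(0, 99, 40),
                   cov=rng.normal(size=40))
        fit = exp_regression(df, "m", "age", ["cov"])
        # sample means are the default profile; an explicit profile overrides
        d_default = bin_delta(fit, 30.0)
        d_at_zero = bin_delta(fit, 30.0, covariate_profile={"cov": 0.0})
        assert np.isfinite(d_default) and np.isfinite(d_at_zero)


class TestRankFit:
    def test_binary_predictor_equals_hodges_lehmann(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 15)
        b = rng.normal(1.3, 1, 17)      # 15*17 pairwise diffs: odd count
        df = frame(y=np.concatenate([a, b]), x=[0.0] * 15 + [1.0] * 17)
        fit = rank_fit(df, "y", ["x"])
        assert fit.coefficients["x"] == pytest.approx(
            hodges_lehmann_shift(a, b), abs=1e-6)

    def test_noiseless_data_matches_ols(self):
        age = np.linspace(10, 90, 30)
        df = frame(y=1.5 + 0.7 * age, age=age)
        fit = rank_fit(df, "y", ["age"])
        assert fit.coefficients["age"] == pytest.approx(0.7, abs=1e-6)

    def test_location_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(9)
        df = frame(y=rng.normal(0, 1, 60), x=rng.normal(0, 1, 60))
        base = rank_fit(df, "y", ["x"]).coefficients["x"]
        shifted = df.assign(y=df.y + 100.0)
        scaled = df.assign(y=df.y * 3.0)
        assert rank_fit(shifted, "y", ["x"]).coefficients["x"] == pytest.approx(
            base, abs=1e-6)
        assert rank_fit(scaled, "y", ["x"]).coefficients["x"] == pytest.approx(
            3 * base, abs=1e-5)

    def test_robust_to_gross_outliers(self):
        """With 10% wild outliers the rank slope stays nearer the truth than
        OLS in the large majority of replicates."""
        rng = np.random.default_rng(21)
        wins = 0
        reps = 40
        for _ in range(reps):
            n = 200
            x = rng.uniform(-2, 2, n)
            y = 1.0 + 2.0 * x + rng.normal(0, 1, n)
            idx = rng.choice(n, size=20, replace=False)
            y[idx] += rng.normal(0, 40, 20)
            df = frame(y=y, x=x)
            r = rank_fit(df, "y", ["x"]).coefficients["x"]
            o = ols_fit(df, "y", ["x"]).coefficients["x"]
            wins += abs(r - 2.0) < abs(o - 2.0)
        assert wins / reps >= 0.9

    def test_small_sample_rejected(self):
        df = frame(y=np.arange(5.0), x=np.arange(5.0))
        with pytest.raises(StatsError, match="n >= 10"):
            rank_fit(df, "y", ["x"])


class TestKruskalDunn:
    def test_identical_groups(self):
        g = {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0, 1.0]}
        res = kruskal_dunn(g)
        assert res.H_statistic == 0.0
        assert all(p == 1.0 for *_, p in res.pairwise)

    def test_two_separated_groups_hand_computed_z(self):
        res = kruskal_dunn({"lo": [1.0, 2.0, 3.0], "hi": [10.0, 11.0, 12.0]})
        # pooled ranks 1..6, mean ranks 2 and 5, var = 6*7/12 = 3.5
        z_expected = (2 - 5) / np.sqrt(3.5 * (1 / 3 + 1 / 3))
        (gi, gj, z, raw, adj) = res.pairwise[0]
        assert z == pytest.approx(z_expected)
        assert adj == pytest.approx(min(1.0, raw))  # single pair: no inflation

    def test_tie_correction_changes_z(self):
        with_ties = kruskal_dunn({"a": [1.0, 1.0, 2.0], "b": [2.0, 3.0, 3.0]})
        z_t = abs(with_ties.pairwise[0][2])
        no_ties = kruskal_dunn({"a": [1.0, 1.5, 2.0], "b": [2.5, 3.0, 3.5]})
        z_n = abs(no_ties.pairwise[0][2])
        assert z_t != pytest.approx(z_n)

    def test_familywise_error_under_null(self):
        rng = np.random.default_rng(13)
        reps, any_sig = 400, 0
        for _ in range(reps):
            groups = {k: rng.normal(0, 1, 12) for k in "abcd"}
            res = kruskal_dunn(groups)
            any_sig += any(adj < 0.05 for *_, adj in res.pairwise)
        rate = any_sig / reps
        assert rate <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)

    def test_single_group_rejected(self):
        with pytest.raises(StatsError):
            kruskal_dunn({"a": [1.0, 2.0]})


class TestChisqYates:
    def test_top100_size_distribution_table(self):
        stat, p = chisq_yates([[73, 6], [9, 12]])
        assert p == pytest.approx(8.08e-7, abs=0.005e-7)

    def test_proportional_table_null(self):
        stat, p = chisq_yates([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_diagonal_table_closed_form(self):
        # |O-E| = 25 in each cell, E = 25: (24.5^2/25)*4 = 96.04
        stat, p = chisq_yates([[50, 0], [0, 50]])
        assert stat == pytest.approx(96.04)
        assert p < 1e-20

    def test_symmetry_under_transpose_and_swap(self):
        t = [[73, 6], [9, 12]]
        base = chisq_yates(t)
        assert chisq_yates(np.transpose(t)) == pytest.approx(base)
        assert chisq_yates(t[::-1]) == pytest.approx(base)
        assert chisq_yates([row[::-1] for row in t]) == pytest.approx(base)

    def test_zero_margin(self):
        with pytest.raises(StatsError, match="margin"):
            chisq_yates([[0, 0], [5, 5]])

    def test_non_integer_rejected(self):
        with pytest.raises(StatsError):
            chisq_yates([[1.5, 2], [3, 4]])


class TestBonferroni:
    def test_association_scan_thresholds(self):
        assert bonferroni(0.05, 38) == pytest.approx(1.32e-3, abs=0.005e-3)
        assert bonferroni(0.05, 2) == 0.025
        assert bonferroni(0.05, 1) == 0.05

    @pytest.mark.parametrize("alpha,m", [(0.0, 5), (1.5, 5), (0.05, 0)])
    def test_invalid_inputs(self, alpha, m):
        with pytest.raises(StatsError):
            bonferroni(alpha, m)
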