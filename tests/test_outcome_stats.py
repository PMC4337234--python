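import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patterngrid.errors import ContractError, DegenerateDataError
from patterngrid.outcome_stats import (
    PairedTestResult,
    correlation_matrix,
    hierarchical_regression,
    icc_agreement,
    paired_t,
    regression_from_correlations,
)


class TestPairedT:
    def test_from_summary_statistics(self):
        res = PairedTestResult.from_stats(1.06, 1.87, 27)
        assert res.t == pytest.approx(2.945, abs=5e-3)
        assert res.cohen_d == pytest.approx(0.567, abs=5e-3)
        assert res.df == 26
        assert res.ci_low < res.mean_diff < res.ci_high

    def test_processing_shift_effect_size(self):
        res = PairedTestResult.from_stats(0.46, 0.65, 27)
        assert res.cohen_d == pytest.approx(0.708, abs=5e-3)

    def test_identical_pre_post(self):
        res = paired_t([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.cohen_d == 0.0 and res.p == 1.0

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t([2, 3, 4], [1, 2, 3])

    def test_too_few_pairs(self):
        with pytest.raises(ContractError):
            paired_t([1.0], [2.0])

    @given(
        diffs=st.lists(
            st.floats(-3, 3).map(lambda v: round(v, 2)), min_size=3, max_size=30
        )
    )
    @settings(derandomize=True, max_examples=100)
    def test_t_equals_d_times_sqrt_n(self, diffs):
        post = np.zeros(len(diffs))
        if np.std(diffs, ddof=1) == 0:
            return
        res = paired_t(np.asarray(diffs), post)
        assert abs(res.t) == pytest.approx(
            abs(res.cohen_d) * np.sqrt(res.n), rel=1e-12
        )

    def test_scipy_agreement(self):
        import scipy.stats as st_

        rng = np.random.default_rng(7)
        pre, post = rng.normal(5, 2, 30), rng.normal(4, 2, 30)
        res = paired_t(pre, post)
        ref = st_.ttest_rel(pre, post)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        cm = correlation_matrix(df)
        assert np.allclose(np.diag(cm.r), 1.0)
        assert np.allclose(cm.r, cm.r.T)
        assert (np.abs(cm.r.to_numpy()) <= 1).all()

    def test_exactly_linear_pair(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8],
                           "z": [4.0, 3, 2, 1]})
        cm = correlation_matrix(df)
        assert cm.r.loc["x", "y"] == pytest.approx(1.0)
        assert cm.r.loc["x", "z"] == pytest.approx(-1.0)

    def test_pairwise_n_with_missing_values(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, np.nan, 5, 0],
                           "y": [2.0, 1, 4, 4, np.nan, 1],
                           "z": [1.0, 2, 2, 3, 4, 5]})
        cm = correlation_matrix(df)
        assert cm.n.loc["x", "y"] == 4
        assert cm.n.loc["x", "z"] == 5
        assert cm.n.loc["z", "z"] == 6

    def test_constant_variable_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "c": [2.0, 2, 2, 2]})
        cm = correlation_matrix(df)
        assert "c" in cm.degenerate
        assert np.isnan(cm.r.loc["x", "c"])

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(42)
        n = 500
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        cm = correlation_matrix(pd.DataFrame({"x": x, "y": y}))
        assert cm.r.loc["x", "y"] == pytest.approx(0.5, abs=0.08)


def _planted_frame(n=200, seed=1):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = 0.3 * x1 + rng.normal(size=n)
    x3 = rng.normal(size=n)
    y = 0.4 * x1 + 0.5 * x2 + rng.normal(size=n)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2, "x3": x3})


class TestHierarchicalRegression:
    def test_single_predictor_beta_equals_zero_order_r(self):
        df = _planted_frame()
        steps = hierarchical_regression(df, "y", [["x1"]])
        r = df["y"].corr(df["x1"])
        assert steps[0].beta["x1"] == pytest.approx(r, abs=1e-10)
        assert steps[0].r_squared == pytest.approx(r**2, abs=1e-10)
        assert steps[0].delta_r_squared == pytest.approx(r**2, abs=1e-10)

    def test_r_squared_non_decreasing_and_delta_consistent(self):
        df = _planted_frame()
        steps = hierarchical_regression(df, "y", [["x1"], ["x2", "x3"]])
        assert steps[1].r_squared >= steps[0].r_squared
        assert steps[1].delta_r_squared == pytest.approx(
            steps[1].r_squared - steps[0].r_squared, abs=1e-12
        )
        assert steps[1].n == len(df)

    def test_noise_predictors_rarely_significant(self):
        # null simulation at the regression level: nominal type-I behavior
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 400
        for _ in range(reps):
            n = 30
            df = pd.DataFrame(
                {
                    "y": rng.normal(size=n),
                    "x1": rng.normal(size=n),
                    "n1": rng.normal(size=n),
                    "n2": rng.normal(size=n),
                }
            )
            steps = hierarchical_regression(df, "y", [["x1"], ["n1", "n2"]])
            rejections += steps[1].p_delta_f < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 3 * se

    def test_collinear_design_rejected(self):
        df = _planted_frame()
        df["x1b"] = df["x1"] * 2
        with pytest.raises(ContractError, match="collinear"):
            hierarchical_regression(df, "y", [["x1", "x1b"]])

    def test_listwise_deletion(self):
        df = _planted_frame(n=50)
        df.loc[0, "x2"] = np.nan
        steps = hierarchical_regression(df, "y", [["x1"], ["x2"]])
        assert steps[0].n == 49

    def test_delta_f_equals_standard_formula(self):
        df = _planted_frame()
        steps = hierarchical_regression(df, "y", [["x1"], ["x2", "x3"]])
        s2 = steps[1]
        n, q, k = s2.n, 2, 3
        expect = (s2.delta_r_squared / q) / ((1 - s2.r_squared) / (n - k - 1))
        assert s2.delta_f == pytest.approx(expect, rel=1e-12)


class TestRegressionFromCorrelations:
    def test_single_predictor(self):
        corr = pd.DataFrame(
            [[1.0, 0.5], [0.5, 1.0]], index=["x", "y"], columns=["x", "y"]
        )
        steps = regression_from_correlations(corr, "y", [["x"]])
        assert steps[0].beta["x"] == pytest.approx(0.5)
        assert steps[0].r_squared == pytest.approx(0.25)

    def test_orthogonal_predictors_r2_is_sum_of_squares(self):
        labels = ["a", "b", "y"]
        corr = pd.DataFrame(np.eye(3), index=labels, columns=labels)
        corr.loc["a", "y"] = corr.loc["y", "a"] = 0.3
        corr.loc["b", "y"] = corr.loc["y", "b"] = 0.4
        steps = regression_from_correlations(corr, "y", [["a", "b"]])
        assert steps[0].r_squared == pytest.approx(0.09 + 0.16)

    def test_non_positive_definite_rejected(self):
        labels = ["a", "b", "y"]
        corr = pd.DataFrame(np.ones((3, 3)), index=labels, columns=labels)
        with pytest.raises(ContractError):
            regression_from_correlations(corr, "y", [["a", "b"]])

    def test_agrees_with_sample_regression_to_1e8(self):
        df = _planted_frame(n=120, seed=9)
        fitted = hierarchical_regression(df, "y", [["x1"], ["x2", "x3"]])
        corr = df.corr()
        derived = regression_from_correlations(corr, "y", [["x1"], ["x2", "x3"]])
        for a, b in zip(fitted, derived):
            assert a.r_squared == pytest.approx(b.r_squared, abs=1e-8)
            for term in a.predictors:
                assert a.beta[term] == pytest.approx(b.beta[term], abs=1e-8)


class TestICC:
    def test_identical_coders(self):
        assert icc_agreement([0, 1, 2, 3, 2], [0, 1, 2, 3, 2]).value == 1.0

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 4, size=800)
        b = rng.integers(0, 4, size=800)
        assert abs(icc_agreement(a, b).value) < 0.1

    def test_known_reliability_structure(self):
        rng = np.random.default_rng(5)
        truth = rng.normal(0, 1, size=1500)
        noise = np.sqrt(1 / 3)  # ICC = 1 / (1 + 1/3) = 0.75
        a = truth + rng.normal(0, noise, 1500)
        b = truth + rng.normal(0, noise, 1500)
        assert icc_agreement(a, b).value == pytest.approx(0.75, abs=0.05)

    def test_zero_between_subject_variance_degenerate(self):
        res = icc_agreement([1, 1, 1, 1], [2, 2, 2, 2])
        assert res.degenerate

    def test_too_few_pairs(self):
        with pytest.raises(ContractError):
            icc_agreement([1, 2], [1, 2])
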