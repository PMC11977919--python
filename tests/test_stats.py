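import itertools

import numpy as np
import pytest
from scipy import stats as sps

from cgmetrics.core import SubjectRecord
from cgmetrics.errors import CollinearityError, DegenerateSampleError
from cgmetrics.stats import (
    REGRESSION_COVARIATES,
    compare_means,
    compare_medians,
    compare_proportions,
    fit_regression,
)


def make_records(rng, n, y_fn, arm=None):
    """Records with random covariates; response supplied via a dict."""
    recs, resp = [], {}
    for i in range(n):
        sid = f"s{i}"
        cov = {
            "aid_system": int(arm[i]) if arm is not None else int(rng.random() < 0.45),
            "hba1c_baseline": rng.normal(60, 12),
            "age": rng.uniform(18, 80),
            "time_with_aid": rng.uniform(100, 1200),
            "setting": int(rng.random() < 0.5),
            "diabetes_duration": rng.uniform(1, 40),
            "gender": int(rng.random() < 0.5),
            "bmi": rng.uniform(18, 40),
        }
        recs.append(SubjectRecord(subject_id=sid, **cov))
        resp[sid] = y_fn(cov)
    return recs, resp


class TestCompareMeans:
    def test_identical_samples(self):
        c = compare_means([1, 2, 3], [1, 2, 3])
        assert c.difference == 0 and c.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_pooled_t(self):
        # a={1,2,3}, b={4,5,6}: sp2=1, se=sqrt(2/3), df=4
        c = compare_means([1, 2, 3], [4, 5, 6])
        se = np.sqrt(2 / 3)
        assert c.difference == pytest.approx(3.0)
        t = 3.0 / se
        assert c.p_value == pytest.approx(2 * sps.t.sf(t, 4))
        half = sps.t.ppf(0.975, 4) * se
        assert c.ci95 == pytest.approx((3 - half, 3 + half))

    def test_ci_symmetric_about_difference(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 15)
        c = compare_means(a, b)
        assert c.ci95[0] + c.ci95[1] == pytest.approx(2 * c.difference)
        assert c.ci95[0] <= c.difference <= c.ci95[1]

    def test_agrees_with_scipy_ttest(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1.3, 9)
        c = compare_means(a, b)
        ref = sps.ttest_ind(b, a, equal_var=True)
        assert c.p_value == pytest.approx(ref.pvalue)

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(DegenerateSampleError):
            compare_means([2.0, 2.0], [2.0, 2.0])

    def test_orientation_b_minus_a(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        c1, c2 = compare_means(a, b), compare_means(b, a)
        assert c1.difference == pytest.approx(-c2.difference)


class TestCompareMedians:
    def test_pure_shift_recovered(self, rng):
        a = rng.normal(0, 1, 12)
        c = compare_medians(a, a + 5)
        assert c.difference == pytest.approx(5.0)

    def test_brute_force_pairwise_enumeration(self):
        # pairwise differences {2, 9, 1, 8} -> median 5.0
        c = compare_medians([1, 2, 1.5], [3, 10, 9.5])
        diffs = sorted(b - a for a in [1, 2, 1.5] for b in [3, 10, 9.5])
        assert c.difference == pytest.approx(float(np.median(diffs)))

    def test_identical_samples_estimate_zero(self):
        c = compare_medians([1, 2, 3, 4], [1, 2, 3, 4])
        assert c.difference == 0

    def test_exhaustive_grid_against_pure_python_oracle(self, rng):
        for na, nb in itertools.product([3, 5, 9, 17, 30], repeat=2):
            a, b = rng.normal(0, 2, na), rng.normal(1, 2, nb)
            c = compare_medians(a, b)
            diffs = sorted(float(y - x) for x in a for y in b)
            k = len(diffs)
            oracle = diffs[k // 2] if k % 2 else (diffs[k // 2 - 1] + diffs[k // 2]) / 2
            assert c.difference == pytest.approx(oracle)

    def test_ci_brackets_estimate_and_shift_coverage(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(2.0, 1, 25)
        c = compare_medians(a, b)
        assert c.ci95[0] <= c.difference <= c.ci95[1]

    def test_p_matches_scipy_mannwhitney(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.8, 1, 12)
        c = compare_medians(a, b)
        ref = sps.mannwhitneyu(b, a, alternative="two-sided", method="exact")
        assert c.p_value == pytest.approx(ref.pvalue)

    def test_large_samples_use_normal_approximation(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.2, 1, 30)
        c = compare_medians(a, b)
        ref = sps.mannwhitneyu(b, a, alternative="two-sided", method="asymptotic")
        assert c.p_value == pytest.approx(ref.pvalue)


class TestCompareProportions:
    def test_printed_counts_difference_and_wald_ci(self):
        c = compare_proportions(9, 79, 21, 60)
        assert round(c.difference) == 24
        assert round(c.ci95[0]) == 10 and round(c.ci95[1]) == 38
        assert c.p_value < 0.005

    def test_printed_response_fractions(self):
        c = compare_proportions(30, 121, 2, 75)
        assert round(c.group_a_summary[0]) == 25
        assert round(c.group_b_summary[0]) == 3
        assert c.p_value < 0.001

    def test_equal_proportions_zero_difference(self):
        c = compare_proportions(5, 20, 10, 40)
        assert c.difference == 0

    def test_antisymmetric_under_group_swap(self):
        c1 = compare_proportions(9, 79, 21, 60)
        c2 = compare_proportions(21, 60, 9, 79)
        assert c1.difference == pytest.approx(-c2.difference)
        assert c1.p_value == pytest.approx(c2.p_value)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            compare_proportions(5, 0, 1, 10)
        with pytest.raises(ValueError):
            compare_proportions(11, 10, 1, 10)


class TestRegression:
    def test_noiseless_recovery_machine_precision(self, rng):
        beta = {"aid_system": 4.2, "hba1c_baseline": -0.5, "age": 0.19,
                "bmi": 0.07, "setting": 0.8, "diabetes_duration": 0.03,
                "gender": 1.2}

        def y_fn(cov):
            return 80.0 + sum(beta[k] * cov[k] for k in beta) + 0.2 * (
                cov["time_with_aid"] / 30.44)

        recs, resp = make_records(rng, 40, y_fn)
        fit = fit_regression(recs, "tir", response_values=resp)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficients.loc["aid_system", "beta"] == pytest.approx(4.2, abs=1e-8)
        assert fit.coefficients.loc["time_with_aid_months", "beta"] == pytest.approx(
            0.2, abs=1e-8)
        assert fit.coefficients.loc["const", "beta"] == pytest.approx(80.0, abs=1e-6)

    def test_matches_normal_equations(self, rng):
        recs, resp = make_records(
            rng, 60, lambda c: rng.normal(70, 8) + 3 * c["aid_system"])
        fit = fit_regression(recs, "tir", response_values=resp)
        from cgmetrics.stats import records_frame

        X = records_frame(recs)[REGRESSION_COVARIATES].to_numpy()
        X = np.column_stack([np.ones(len(X)), X])
        y = np.array([resp[f"s{i}"] for i in range(60)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.coefficients["beta"].to_numpy(), beta, rtol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        recs, resp = make_records(rng, 50, lambda c: rng.normal(70, 8))
        fit = fit_regression(recs, "tir", response_values=resp)
        resid = fit.results.resid.to_numpy()
        X = fit.results.model.exog
        assert np.max(np.abs(X.T @ resid)) < 1e-6

    def test_listwise_deletion_counted(self, rng):
        recs, resp = make_records(rng, 30, lambda c: 70.0)
        recs[0].bmi = np.nan
        resp["s1"] = np.nan
        fit = fit_regression(recs, "tir", response_values=resp)
        assert fit.n == 28 and fit.n_dropped == 2

    def test_collinear_design_names_columns(self, rng):
        recs, resp = make_records(rng, 30, lambda c: 70.0)
        for r in recs:
            r.bmi = 2.0 * r.age  # exact collinearity
        with pytest.raises(CollinearityError) as ei:
            fit_regression(recs, "tir", response_values=resp)
        assert "age" in ei.value.columns and "bmi" in ei.value.columns

    def test_planted_arm_effect_recovered_on_average(self, rng):
        # 139 subjects, effect 5.0 TIR points, noise SD 8, many replicates
        arm = np.array([0] * 79 + [1] * 60)
        betas = []
        for _ in range(120):
            recs, resp = make_records(
                rng, 139,
                lambda c: 75 - 0.4 * (c["hba1c_baseline"] - 60)
                + 5.0 * c["aid_system"] + rng.normal(0, 8),
                arm=arm)
            fit = fit_regression(recs, "tir", response_values=resp)
            betas.append(fit.coefficients.loc["aid_system", "beta"])
        assert np.mean(betas) == pytest.approx(5.0, abs=0.5)
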