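import numpy as np
import pytest
from scipy import stats as sps

from cgmetrics.core import SLOTS_PER_DAY
from cgmetrics.errors import UndefinedMetricsError
from cgmetrics.roc import (
    RocSeries,
    fit_t_location_scale,
    roc_series,
    trc_metrics,
)

from conftest import make_trace


def ols_slope_15min(window):
    """Independent closed-form OLS slope on x = 0, 1/3, 2/3, 1."""
    x = np.array([0, 1 / 3, 2 / 3, 1.0])
    xc = x - x.mean()
    return float(np.sum(xc * (window - np.mean(window))) / np.sum(xc**2))


class TestRocSeries:
    def test_constant_window_slope_zero(self):
        s = roc_series(make_trace([6.0, 6.0, 6.0, 6.0]))
        assert s.slopes[0] == pytest.approx(0.0)

    def test_exact_linear_ramp(self):
        s = roc_series(make_trace([5.0, 5.5, 6.0, 6.5]))
        assert s.slopes[0] == pytest.approx(1.5)

    def test_matches_closed_form_ols_on_random_windows(self, rng):
        for _ in range(200):
            w = rng.uniform(2, 20, 4)
            s = roc_series(make_trace(w))
            assert s.slopes[0] == pytest.approx(ols_slope_15min(w), abs=1e-10)

    def test_spec_example_window(self):
        s = roc_series(make_trace([5.0, 6.0, 5.5, 7.0]))
        assert s.slopes[0] == pytest.approx(ols_slope_15min(np.array([5.0, 6.0, 5.5, 7.0])))

    def test_window_tiling_counts_on_full_trace(self):
        n = 60 * SLOTS_PER_DAY
        tr = make_trace(np.full(n, 6.0), n_days=60)
        s = roc_series(tr)
        # direct enumeration: starts 0, 3, 6, ... with start+3 <= n-1
        expected = len([st for st in range(0, n, 3) if st + 3 <= n - 1])
        assert expected == 5759
        assert s.n_candidate_windows == expected
        assert s.n_valid_windows == expected

    def test_windows_share_endpoints_and_disjoint_option(self):
        tr = make_trace(np.full(12, 6.0))
        assert roc_series(tr, step=3).window_starts.tolist()[:3] == [0, 3, 6]
        assert roc_series(tr, step=4).window_starts.tolist()[:2] == [0, 4]

    def test_windows_with_missing_slot_skipped(self):
        v = np.array([5.0, np.nan, 6.0, 6.5, 7.0, 7.5, 8.0])
        s = roc_series(make_trace(v))  # padded to one day with missing slots
        assert s.n_valid_windows == 1  # only the window starting at slot 3
        assert s.window_starts.tolist() == [3]
        assert s.slopes[0] == pytest.approx(1.5)

    def test_short_trace_empty_series(self):
        tr = make_trace([6.0])
        s = roc_series(tr)
        assert s.n_candidate_windows >= 0 and s.n_valid_windows == 0


class TestTrc:
    def test_all_zero_slopes(self):
        m = trc_metrics(RocSeries(np.arange(4), np.zeros(4), 4, 4))
        assert m.trc == 0 and m.aarc == 0

    def test_brute_force_counts(self):
        m = trc_metrics(RocSeries(np.arange(4), np.array([2.0, -2.0, 0.0, 0.0]), 4, 4))
        assert m.trc_plus == 25 and m.trc_minus == 25 and m.trc == 50
        assert m.aarc == pytest.approx(1.0)

    def test_threshold_strict(self):
        m = trc_metrics(RocSeries(np.arange(2), np.array([1.5, -1.5]), 2, 2))
        assert m.trc == 0.0

    def test_zero_valid_windows_raises(self):
        with pytest.raises(UndefinedMetricsError):
            trc_metrics(RocSeries(np.empty(0, int), np.empty(0), 5, 0))

    def test_additivity_and_triangle_inequality(self, rng):
        for _ in range(50):
            slopes = rng.standard_t(3, 200)
            m = trc_metrics(RocSeries(np.arange(200), slopes, 200, 200))
            assert m.trc == m.trc_plus + m.trc_minus
            assert m.aarc >= abs(slopes.mean()) - 1e-12

    def test_sign_equivariance(self, rng):
        slopes = rng.standard_t(3, 500)
        m1 = trc_metrics(RocSeries(np.arange(500), slopes, 500, 500))
        m2 = trc_metrics(RocSeries(np.arange(500), -slopes, 500, 500))
        assert m1.trc_plus == m2.trc_minus and m1.trc_minus == m2.trc_plus
        assert m1.aarc == pytest.approx(m2.aarc)

    def test_negating_trace_negates_slopes(self, rng):
        w = rng.uniform(4, 12, 4)
        s1 = roc_series(make_trace(w)).slopes[0]
        s2 = roc_series(make_trace(2 * w.mean() - w)).slopes[0]
        assert s2 == pytest.approx(-s1)


class TestTFit:
    def test_recovers_t3_parameters(self):
        rng = np.random.default_rng(7)
        x = sps.t.rvs(3, loc=0, scale=1, size=20000, random_state=rng)
        fit = fit_t_location_scale(x)
        assert abs(fit.location) < 0.05
        assert fit.scale == pytest.approx(1.0, rel=0.05)
        assert fit.df == pytest.approx(3.0, rel=0.10)
        assert fit.sd == pytest.approx(fit.scale * np.sqrt(fit.df / (fit.df - 2)))

    def test_normal_limit_matches_normal_mle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.5, 2.0, 20000)
        fit = fit_t_location_scale(x)
        assert fit.df > 50
        assert fit.location == pytest.approx(x.mean(), abs=0.02 * 2.0)
        assert fit.scale == pytest.approx(x.std(), rel=0.02)

    def test_location_of_symmetric_sample_is_center(self):
        rng = np.random.default_rng(3)
        half = sps.t.rvs(4, size=500, random_state=rng)
        x = np.concatenate([5 + half, 5 - half])  # exactly symmetric about 5
        fit = fit_t_location_scale(x)
        assert fit.location == pytest.approx(5.0, abs=1e-3)

    def test_agrees_with_scipy_reference_fit(self):
        rng = np.random.default_rng(19)
        x = sps.t.rvs(4, loc=-0.1, scale=0.8, size=5000, random_state=rng)
        ours = fit_t_location_scale(x)
        df_ref, loc_ref, scale_ref = sps.t.fit(x)
        assert ours.location == pytest.approx(loc_ref, abs=0.02)
        assert ours.scale == pytest.approx(scale_ref, rel=0.02)
        assert ours.df == pytest.approx(df_ref, rel=0.05)

    def test_sd_nan_when_variance_undefined(self):
        rng = np.random.default_rng(23)
        x = sps.t.rvs(1.5, size=5000, random_state=rng)  # infinite variance
        fit = fit_t_location_scale(x)
        assert fit.df < 2 and np.isnan(fit.sd)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_t_location_scale(np.zeros(10))
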