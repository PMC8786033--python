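"""Lag scan and lag-shifted regression."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from vaxlens import (
    LagShiftedRegression,
    SimulationConfig,
    fit_quality_exceeds_marginals,
    lag_scan,
    lag_scan_panel,
    raw_scale_coefficients,
    shifted_regression,
    simulate_attentiveness,
    simulate_covid_stats,
)
from vaxlens.attentiveness import CorrelationResult
from vaxlens.lagreg import STAT_VARIABLES, LagScanResult, RegressionFit
from scipy import stats

from conftest import toy_panel


def series(values, start="2021-01-01"):
    return pd.Series(values, index=pd.date_range(start, periods=len(values)))


class TestLagScan:
    def test_identity_gives_lag_zero_r_one(self, rng):
        x = series(np.cumsum(rng.standard_normal(120)))
        result = lag_scan(x, x, max_lag=10)
        assert result.lag == 0 and result.r == pytest.approx(1.0)

    def test_pure_shift_of_random_walk_recovered(self, rng):
        x = series(np.cumsum(rng.standard_normal(200)))
        y = x.copy()
        y.index = y.index + pd.Timedelta(days=5)  # y(t) = x(t-5)
        result = lag_scan(y, x, max_lag=30)
        assert result.lag == 5 and result.r == pytest.approx(1.0)
        # exhaustive-scan oracle: no other lag reaches |r| = 1
        others = result.scan_table[result.scan_table.lag != 5]
        assert (others.r.abs() < 1 - 1e-9).all()

    def test_negative_relation_keeps_sign(self, rng):
        x = series(np.cumsum(rng.standard_normal(200)))
        y = -x.copy()
        y.index = y.index + pd.Timedelta(days=10)
        result = lag_scan(y, x, max_lag=30)
        assert result.lag == 10 and result.r == pytest.approx(-1.0)

    def test_max_lag_zero_equals_plain_pearson(self, rng):
        x = series(rng.standard_normal(80))
        y = series(rng.standard_normal(80))
        result = lag_scan(y, x, max_lag=0)
        r, p = stats.pearsonr(y.values, x.values)
        assert result.r == pytest.approx(r) and result.p == pytest.approx(p)

    def test_constant_predictor_errors(self):
        y = series(np.arange(50, dtype=float))
        x = series(np.ones(50))
        with pytest.raises(ValueError, match="constant"):
            lag_scan(y, x, max_lag=5)

    def test_common_window_uses_same_days_at_every_lag(self, rng):
        x = series(np.cumsum(rng.standard_normal(100)))
        y = series(rng.standard_normal(100))
        result = lag_scan(y, x, max_lag=10, window="common")
        assert result.scan_table.n.nunique() == 1
        pairwise = lag_scan(y, x, max_lag=10, window="pairwise")
        assert pairwise.scan_table.n.iloc[0] > result.scan_table.n.iloc[0]


class TestShiftedRegression:
    def test_zero_lags_match_normal_equations_oracle(self, panel60, rng):
        y = series(
            5 + 0.1 * panel60["new_cases"].values + rng.standard_normal(60),
            start="2020-06-09",
        )
        fit = shifted_regression(y, panel60, [0] * 8)
        X = np.column_stack(
            [np.ones(60)] + [panel60[v].values for v in STAT_VARIABLES]
        )
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y.values)
        np.testing.assert_allclose(fit.beta, beta_oracle, rtol=1e-8)
        # residuals orthogonal to the design
        resid = y.values - X @ fit.beta
        assert np.max(np.abs(X.T @ resid)) / np.linalg.norm(y.values) < 1e-8

    def test_noise_free_exact_recovery(self):
        cfg = SimulationConfig(seed=11, noise_sd=0.0, events=())
        panel = simulate_covid_stats(cfg)
        y = simulate_attentiveness(panel, cfg)
        fit = shifted_regression(y, panel, cfg.true_lags)
        truth = raw_scale_coefficients(panel, cfg)
        nonzero = truth != 0
        rel = np.abs(fit.beta[nonzero] - truth[nonzero]) / np.abs(truth[nonzero])
        assert rel.max() < 1e-6
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_has_near_zero_adjusted_r2(self, rng):
        panel = toy_panel(n_days=300, seed=2)
        y = series(10 + rng.standard_normal(300), start="2020-06-09")
        fit = shifted_regression(y, panel, [0] * 8)
        assert abs(fit.adj_r2) < 0.1

    def test_adjusted_r2_below_squared_fit_correlation(self, panel60, rng):
        y = series(
            3 + 0.05 * panel60["total_cases"].values + rng.standard_normal(60),
            start="2020-06-09",
        )
        fit = shifted_regression(y, panel60, [0] * 8)
        assert fit.adj_r2 <= fit.fit_corr.r ** 2 + 1e-12

    def test_shift_convention_uses_past_predictor_values(self):
        # y(t) = x1(t-3) exactly: regressing with lag 3 on x1 recovers slope 1
        panel = toy_panel(n_days=80, seed=4)
        x1 = panel["new_cases"]
        y = x1.copy()
        y.index = y.index + pd.Timedelta(days=3)
        lags = [3, 0, 0, 0, 0, 0, 0, 0]
        fit = shifted_regression(y, panel, lags)
        assert fit.beta[1] == pytest.approx(1.0, abs=1e-6)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_first_shifted_days_dropped_listwise(self, panel60, rng):
        y = series(rng.uniform(5, 15, 60), start="2020-06-09")
        fit = shifted_regression(y, panel60, [7, 0, 0, 0, 0, 0, 0, 0])
        assert fit.n_used == 60 - 7
        assert fit.fitted.index[0] == y.index[7]

    def test_too_small_sample_errors(self, rng):
        panel = toy_panel(n_days=12, seed=0)
        y = series(rng.uniform(1, 5, 12), start="2020-06-09")
        with pytest.raises(ValueError, match="sample size"):
            shifted_regression(y, panel, [5, 0, 0, 0, 0, 0, 0, 0])

    def test_out_of_bounds_lags_rejected(self, panel60, rng):
        y = series(rng.uniform(1, 5, 60), start="2020-06-09")
        with pytest.raises(ValueError):
            shifted_regression(y, panel60, [31, 0, 0, 0, 0, 0, 0, 0])


class TestEstimatorInterface:
    def test_get_params_and_clone(self):
        est = LagShiftedRegression(lags=[0] * 8, max_lag=20)
        params = est.get_params()
        assert params["max_lag"] == 20
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_fit_scans_when_lags_none(self):
        cfg = SimulationConfig(seed=1, noise_sd=0.0, events=())
        panel = simulate_covid_stats(cfg)
        y = simulate_attentiveness(panel, cfg)
        est = LagShiftedRegression().fit(panel, y)
        assert tuple(est.lags_) == cfg.true_lags
        assert len(est.scan_results_) == 8

    def test_predict_matches_fitted_values(self, panel60, rng):
        y = series(5 + 0.2 * panel60["new_deaths"].values + rng.standard_normal(60),
                   start="2020-06-09")
        est = LagShiftedRegression(lags=[0] * 8).fit(panel60, y)
        predicted = est.predict(panel60)
        np.testing.assert_allclose(
            predicted.loc[est.fit_.fitted.index].values, est.fit_.fitted.values, rtol=1e-10
        )


class TestFitQuality:
    def make_fit(self, r):
        corr = CorrelationResult.from_r(r, 0.0, 100)
        return RegressionFit(
            beta=np.zeros(9), lags=np.zeros(8, dtype=int),
            fitted=pd.Series(dtype=float), adj_r2=r**2, fit_corr=corr,
            n_used=100, condition_number=1.0,
        )

    def make_scan(self, r):
        return LagScanResult("x", 0, r, 0.0)

    def test_multiple_fit_beats_marginals_by_nesting(self, panel60, rng):
        y = series(2 + 0.3 * panel60["new_cases"].values + 0.1 * rng.standard_normal(60),
                   start="2020-06-09")
        scans = lag_scan_panel(y, panel60, max_lag=5)
        fit = shifted_regression(y, panel60, [s.lag for s in scans])
        assert fit_quality_exceeds_marginals(fit, scans)

    def test_reports_false_when_fit_weaker(self):
        assert not fit_quality_exceeds_marginals(self.make_fit(0.95), [self.make_scan(0.99)])
        assert fit_quality_exceeds_marginals(self.make_fit(0.95), [self.make_scan(0.60)])
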