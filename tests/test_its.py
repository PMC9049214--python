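import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from abxaudit.its import (MonthlySeries, aggregate_monthly,
                          cumby_huizinga_test, default_hac_lag, durbin_watson,
                          fit_segmented, make_design, newey_west_cov,
                          seasonal_adjust)
from abxaudit.synthetic import simulate_monthly_series

MONTHS = pd.period_range("2017-06", periods=50, freq="M")


class TestDesign:
    def test_interruption_coding(self):
        X = make_design(MONTHS, "2020-03")
        assert X.loc["2020-02", "intv"] == 0
        assert X.loc["2020-03", "intv"] == 1
        assert X.loc["2020-03", "taft"] == 0
        assert X.loc["2020-04", "taft"] == 1
        assert X.loc["2021-07", "taft"] == 16

    def test_intv_zero_implies_taft_zero_and_taft_monotone(self):
        X = make_design(MONTHS)
        assert (X.loc[X["intv"] == 0, "taft"] == 0).all()
        assert (np.diff(X["taft"]) >= 0).all()


class TestAggregateMonthly:
    @staticmethod
    def _frame(n_per_month=100, months=26):
        idx = pd.period_range("2018-01", periods=months, freq="M")
        rows = []
        for i, m in enumerate(idx):
            for j in range(n_per_month):
                rows.append({"month": m, "has_antibiotic": j < 10,
                             "appropriateness": "inappropriate" if j < 4
                             else ("appropriate" if j < 10 else None),
                             "area_type": "urban" if j % 2 else "rural"})
        return pd.DataFrame(rows)

    def test_rx_rate_single_month_value(self):
        series = aggregate_monthly(self._frame(), "rx_rate")
        assert series.values[0] == pytest.approx(10.0)
        assert len(series) == 26

    def test_inappropriate_prop_denominator_is_antibiotic_visits(self):
        series = aggregate_monthly(self._frame(), "inappropriate_prop")
        assert series.values[0] == pytest.approx(40.0)

    def test_stratified_numerators_sum_to_overall(self):
        frame = self._frame()
        overall = aggregate_monthly(frame, "rx_rate")
        strata = aggregate_monthly(frame, "rx_rate", by="area_type")
        total = sum(s.numer for s in strata.values())
        assert np.allclose(total, overall.numer)

    def test_zero_denominator_month_flagged(self):
        frame = self._frame()
        frame = frame[frame["month"] != pd.Period("2018-03", freq="M")]
        series = aggregate_monthly(frame, "rx_rate")
        assert series.missing.sum() == 1
        assert np.isnan(series.values[2])


class TestSeasonalAdjust:
    def test_pure_trend_has_no_seasonal_factors(self):
        values = 5.0 + 0.1 * np.arange(48)
        adj = seasonal_adjust(values, MONTHS[:48])
        assert np.allclose(adj.factors, 0.0, atol=1e-8)
        assert np.allclose(adj.adjusted, values, atol=1e-8)

    def test_injected_month_effect_recovered(self):
        rng = np.random.default_rng(2)
        t = np.arange(len(MONTHS))
        injected = 2.0 * np.cos(2 * np.pi * (MONTHS.month - 1) / 12)
        values = 20.0 - 0.05 * t + injected + rng.normal(0, 0.05, len(t))
        adj = seasonal_adjust(values, MONTHS)
        target = 2.0 * np.cos(2 * np.pi * (np.arange(1, 13) - 1) / 12)
        target -= target.mean()
        assert np.allclose(adj.factors.sort_index().to_numpy(), target,
                           atol=0.15)

    def test_monthly_series_counts_adjust_on_percent_scale(self):
        rng = np.random.default_rng(4)
        denom = np.full(len(MONTHS), 400.0)
        numer = rng.binomial(400, 0.12, len(MONTHS)).astype(float)
        series = MonthlySeries(MONTHS, numer, denom, "rx_rate")
        adj = seasonal_adjust(series)
        assert np.allclose(adj.raw, 100 * numer / denom)

    def test_adjusted_plus_factor_reconstructs_raw(self):
        rng = np.random.default_rng(3)
        values = rng.normal(10, 2, len(MONTHS))
        adj = seasonal_adjust(values, MONTHS)
        back = adj.adjusted + adj.factors.loc[MONTHS.month].to_numpy()
        assert np.allclose(back, values)
        assert adj.factors.sum() == pytest.approx(0.0, abs=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="24"):
            seasonal_adjust(np.arange(20.0))


class TestSegmentedFit:
    def test_noiseless_series_recovers_coefficients_exactly(self):
        Y, _ = simulate_monthly_series(beta=(20, -0.2, -2.8, 0.3), T=50,
                                       interruption_index=33, sd=0.0)
        fit = fit_segmented(Y[0], MONTHS, "2020-03")
        assert np.allclose(fit.params, [20, -0.2, -2.8, 0.3], atol=1e-9)
        assert fit.trend_after[0] == pytest.approx(0.1)
        assert np.allclose(fit.residuals, 0.0, atol=1e-9)

    def test_null_series_estimates_center_on_zero(self):
        Y, _ = simulate_monthly_series(beta=(20, 0.0, 0.0, 0.0), T=50,
                                       interruption_index=33, rho=0.0,
                                       sd=1.0, replicates=200, seed=8)
        b2 = [fit_segmented(Y[r], MONTHS).params["intv"] for r in range(200)]
        assert abs(np.mean(b2)) < 3 * np.std(b2) / np.sqrt(200)

    def test_ols_equals_normal_equation_solution(self):
        rng = np.random.default_rng(12)
        y = rng.normal(10, 1, 50)
        fit = fit_segmented(y, MONTHS)
        X = make_design(MONTHS).to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.params.to_numpy(), beta)

    def test_fitted_plus_residual_reconstructs_series(self):
        rng = np.random.default_rng(13)
        y = rng.normal(10, 1, 50)
        fit = fit_segmented(y, MONTHS)
        assert np.allclose(fit.fitted + fit.residuals, y)

    def test_too_few_post_observations_rejected(self):
        with pytest.raises(ValueError, match="each side"):
            fit_segmented(np.arange(36.0), MONTHS[:36], "2020-03")


class TestNeweyWest:
    @staticmethod
    def _fit():
        rng = np.random.default_rng(17)
        y = 10 + np.cumsum(rng.normal(0, 0.3, 50))
        return fit_segmented(y, MONTHS)

    def test_lag_zero_reduces_to_white(self):
        fit = self._fit()
        X = fit.design.to_numpy()
        e = fit.residuals
        V = newey_west_cov(X, e, L=0)
        XtXi = np.linalg.inv(X.T @ X)
        white = XtXi @ (X.T * e ** 2) @ X @ XtXi
        assert np.allclose(V, white)

    def test_matches_statsmodels_hac(self):
        fit = self._fit()
        res = sm.OLS(fit.fitted + fit.residuals, fit.design).fit(
            cov_type="HAC", cov_kwds={"maxlags": 3, "use_correction": False})
        V = newey_west_cov(fit.design.to_numpy(), fit.residuals, L=3)
        assert np.allclose(V, res.cov_params().to_numpy(), rtol=1e-8)

    @pytest.mark.parametrize("T,L", [(50, 3), (100, 4), (30, 3), (200, 4)])
    def test_default_lag_formula(self, T, L):
        assert default_hac_lag(T) == L

    def test_iid_noise_hac_ses_close_to_ols_ses(self):
        # asymptotic agreement needs a longer series: truncated-kernel
        # HAC estimates run low for short interrupted designs
        months = pd.period_range("2017-06", periods=240, freq="M")
        X = make_design(months, "2027-06")
        rng = np.random.default_rng(19)
        ratios = []
        for _ in range(100):
            y = 10 + rng.normal(0, 1, 240)
            res_ols = sm.OLS(y, X).fit()
            V = newey_west_cov(X.to_numpy(), np.asarray(res_ols.resid),
                               L=default_hac_lag(240))
            ratios.append(np.sqrt(V[2, 2]) / res_ols.bse.iloc[2])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)


class TestDurbinWatson:
    def test_alternating_residuals_T4(self):
        # hand computation: ((-2)^2 + 2^2 + (-2)^2) / 4 = 3
        assert durbin_watson([1, -1, 1, -1]) == pytest.approx(3.0)

    def test_alternating_residuals_approach_four(self):
        e = np.tile([1.0, -1.0], 500)
        assert durbin_watson(e) == pytest.approx(4.0, abs=0.01)

    def test_constant_residuals_give_zero(self):
        assert durbin_watson(np.full(20, 2.5)) == pytest.approx(0.0)

    def test_white_noise_near_two(self):
        rng = np.random.default_rng(23)
        assert durbin_watson(rng.normal(size=5000)) == pytest.approx(2.0,
                                                                     abs=0.1)

    def test_all_zero_residuals_flagged_nan(self):
        assert np.isnan(durbin_watson(np.zeros(10)))


class TestCumbyHuizinga:
    def test_statistic_is_T_times_R2_on_fixture(self):
        y = np.array([10.0, 12.0, 9.0, 14.0, 11.0, 13.0, 10.5, 12.5])
        months = pd.period_range("2019-11", periods=8, freq="M")
        fit = fit_segmented(y, months, "2020-03", hac_lag=0)
        out = cumby_huizinga_test(fit, lags=1)
        # independent computation of T * R^2 of the auxiliary regression
        e = fit.residuals
        Z = np.column_stack([fit.design.to_numpy(),
                             np.concatenate([[0.0], e[:-1]])])
        coef = np.linalg.pinv(Z) @ e
        r2 = 1 - np.sum((e - Z @ coef) ** 2) / np.sum((e - e.mean()) ** 2)
        assert out.loc[0, "statistic"] == pytest.approx(len(e) * r2)
        assert out.loc[0, "df"] == 1

    def test_matches_statsmodels_breusch_godfrey(self):
        from statsmodels.stats.diagnostic import acorr_breusch_godfrey
        rng = np.random.default_rng(29)
        y = 10 + np.cumsum(rng.normal(0, 0.4, 50))
        fit = fit_segmented(y, MONTHS)
        res = sm.OLS(y, fit.design).fit()
        mine = cumby_huizinga_test(fit, lags=3)
        lm, lmpval, _, _ = acorr_breusch_godfrey(res, nlags=3)
        assert mine.loc[2, "statistic"] == pytest.approx(lm, rel=1e-6)
        assert mine.loc[2, "pvalue"] == pytest.approx(lmpval, rel=1e-6)

    def test_size_near_nominal_under_iid_noise(self):
        Y, _ = simulate_monthly_series(beta=(20, -0.1, 0, 0), T=50,
                                       interruption_index=33, rho=0.0,
                                       sd=1.0, replicates=300, seed=31)
        rej = np.mean([
            cumby_huizinga_test(fit_segmented(Y[r], MONTHS),
                                lags=1)["pvalue"].iloc[0] < 0.05
            for r in range(300)])
        assert 0.01 <= rej <= 0.12

    def test_power_against_strong_ar1(self):
        Y, _ = simulate_monthly_series(beta=(20, -0.1, 0, 0), T=50,
                                       interruption_index=33, rho=0.8,
                                       sd=1.0, replicates=200, seed=37)
        rej = np.mean([
            cumby_huizinga_test(fit_segmented(Y[r], MONTHS),
                                lags=1)["pvalue"].iloc[0] < 0.05
            for r in range(200)])
        assert rej > 0.5

    def test_lag_bounds_validated(self):
        y = np.arange(50.0)
        fit = fit_segmented(y + np.random.default_rng(0).normal(size=50),
                            MONTHS)
        with pytest.raises(ValueError):
            cumby_huizinga_test(fit, lags=0)
        with pytest.raises(ValueError):
            cumby_huizinga_test(fit, lags=20)
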