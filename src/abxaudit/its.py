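"""Interrupted time-series machinery for monthly prescription outcomes.

The monthly outcome is either the antibiotic prescription rate
(antibiotic visits / all visits, %) or the proportion of inappropriate
prescriptions (inappropriate / antibiotic visits, %).  The series is
seasonally adjusted by classical additive decomposition (2x12 centred
moving-average trend; month factors re-centred to sum to zero) and then
fitted with the segmented regression

    Y_t = b0 + b1 * t + b2 * Intv_t + b3 * taft_t + e_t

where ``t`` counts months from the series start, ``Intv_t`` switches
from 0 to 1 at the interruption month (March 2020 by default, when the
WHO declared COVID-19 a pandemic) and ``taft_t`` counts months elapsed
since the interruption (0 at and before it).  ``b2`` is the immediate
level change and ``b3`` the slope change; the post-interruption trend is
``b1 + b3``.  Standard errors are Newey-West
(heteroskedasticity- and autocorrelation-consistent with Bartlett
weights); residual autocorrelation is checked with the Durbin-Watson
statistic and a Cumby-Huizinga-type score test (its Breusch-Godfrey
special case under an i.i.d. null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.stattools import durbin_watson as _sm_dw
from statsmodels.tsa.seasonal import seasonal_decompose

log = logging.getLogger(__name__)

DEFAULT_INTERRUPTION = "2020-03"


@dataclass
class MonthlySeries:
    months: pd.PeriodIndex
    numer: np.ndarray
    denom: np.ndarray
    outcome: str                     # rx_rate | inappropriate_prop
    label: str = "overall"

    @property
    def values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.denom > 0,
                            100.0 * self.numer / np.maximum(self.denom, 1), np.nan)

    @property
    def missing(self) -> np.ndarray:
        return self.denom == 0

    def __len__(self) -> int:
        return len(self.months)


def aggregate_monthly(frame: pd.DataFrame, outcome: str = "rx_rate",
                      by: str | None = None):
    """Monthly outcome series from the visit-level frame.

    ``rx_rate``: numerator = antibiotic visits, denominator = all
    visits.  ``inappropriate_prop``: numerator = inappropriate visits,
    denominator = antibiotic visits.  Months inside the observed span
    with a zero denominator are kept and flagged missing.  With ``by``
    set, returns ``{stratum: MonthlySeries}``.
    """
    if outcome not in {"rx_rate", "inappropriate_prop"}:
        raise ValueError(f"unknown outcome {outcome!r}")
    if by is not None:
        return {value: _with_label(aggregate_monthly(sub, outcome), str(value))
                for value, sub in frame.groupby(by)}
    months = pd.period_range(frame["month"].min(), frame["month"].max(),
                             freq="M")
    grouped = frame.groupby("month")
    if outcome == "rx_rate":
        numer = grouped["has_antibiotic"].sum()
        denom = grouped.size()
    else:
        abx = frame[frame["has_antibiotic"]]
        g = abx.groupby("month")
        numer = (abx["appropriateness"] == "inappropriate").groupby(
            abx["month"]).sum()
        denom = g.size()
    numer = numer.reindex(months, fill_value=0).to_numpy(dtype=float)
    denom = denom.reindex(months, fill_value=0).to_numpy(dtype=float)
    n_empty = int((denom == 0).sum())
    if n_empty:
        log.info("%d months with zero denominator flagged missing", n_empty)
    return MonthlySeries(months=months, numer=numer, denom=denom,
                         outcome=outcome)


def _with_label(series: MonthlySeries, label: str) -> MonthlySeries:
    series.label = label
    return series


@dataclass
class SeasonalAdjustment:
    factors: pd.Series               # indexed 1..12 by calendar month, sum 0
    trend: np.ndarray
    raw: np.ndarray
    adjusted: np.ndarray


def seasonal_adjust(series, months: pd.PeriodIndex | None = None
                    ) -> SeasonalAdjustment:
    """Classical additive decomposition of a monthly series.

    Trend is the 2x12 centred moving average; the factor of calendar
    month m is the mean detrended value of that month, re-centred so the
    twelve factors sum to zero; adjusted = raw - factor.  Accepts a
    :class:`MonthlySeries`, or a plain value array with its ``months``
    index.
    """
    if isinstance(series, MonthlySeries):
        values, months = series.values, series.months
    else:
        values = np.asarray(series, dtype=float)
    if len(values) < 24:
        raise ValueError("need at least 24 months for seasonal adjustment")
    if months is None:
        months = pd.period_range("2000-01", periods=len(values), freq="M")
    dec = seasonal_decompose(pd.Series(values,
                                       index=months.to_timestamp()),
                             model="additive", period=12)
    factors = pd.Series(dec.seasonal.to_numpy()[:12],
                        index=months.month[:12]).sort_index()
    factors -= factors.mean()        # exact zero sum
    adjusted = values - factors.loc[months.month].to_numpy()
    return SeasonalAdjustment(factors=factors, trend=dec.trend.to_numpy(),
                              raw=values, adjusted=adjusted)


def make_design(months: pd.PeriodIndex,
                interruption: str = DEFAULT_INTERRUPTION) -> pd.DataFrame:
    """Segmented-regression design: intercept, t, step, post slope.

    ``taft`` is 0 through the interruption month and 1, 2, ... after, so
    the step coefficient is the immediate level change at the
    interruption itself.
    """
    cut = pd.Period(interruption, freq="M")
    t0 = np.arange(len(months), dtype=float)
    intv = (months >= cut).astype(float)
    taft = np.clip((months - cut).map(lambda d: d.n), 0, None).astype(float)
    return pd.DataFrame({"const": 1.0, "t0": t0, "intv": intv, "taft": taft},
                        index=months)


def default_hac_lag(T: int) -> int:
    """Newey-West automatic truncation lag, floor(4 (T/100)^(2/9))."""
    return int(np.floor(4.0 * (T / 100.0) ** (2.0 / 9.0)))


@dataclass
class ITSFit:
    params: pd.Series                # const, t0, intv, taft
    bse: pd.Series                   # HAC standard errors
    conf_int: pd.DataFrame
    pvalues: pd.Series
    residuals: np.ndarray
    fitted: np.ndarray
    design: pd.DataFrame = field(repr=False)
    hac_lag: int = 0
    dw: float = float("nan")
    trend_after: tuple = (np.nan, np.nan, np.nan)   # estimate, lo, hi
    label: str = "overall"

    def summary_row(self) -> dict:
        ci = self.conf_int
        return {
            "label": self.label,
            "trend_before": self.params["t0"],
            "trend_before_lo": ci.loc["t0", 0], "trend_before_hi": ci.loc["t0", 1],
            "level_change": self.params["intv"],
            "level_change_lo": ci.loc["intv", 0],
            "level_change_hi": ci.loc["intv", 1],
            "slope_change": self.params["taft"],
            "slope_change_lo": ci.loc["taft", 0],
            "slope_change_hi": ci.loc["taft", 1],
            "trend_after": self.trend_after[0],
            "trend_after_lo": self.trend_after[1],
            "trend_after_hi": self.trend_after[2],
            "dw": self.dw, "hac_lag": self.hac_lag,
        }


def fit_segmented(values, months: pd.PeriodIndex,
                  interruption: str = DEFAULT_INTERRUPTION,
                  hac_lag: int | None = None, label: str = "overall") -> ITSFit:
    """OLS segmented regression with Newey-West covariance.

    ``values`` is the (seasonally adjusted) monthly outcome.  Months
    with NaN values are dropped from the fit.  Requires at least four
    observations on each side of the interruption.
    """
    y = np.asarray(values, dtype=float)
    X = make_design(months, interruption)
    keep = ~np.isnan(y)
    Xk = X.loc[keep]
    y = y[keep]
    cut = pd.Period(interruption, freq="M")
    n_pre = int((X.index[keep] < cut).sum())
    n_post = int((X.index[keep] >= cut).sum())
    if n_pre < 4 or n_post < 4:
        raise ValueError("need >= 4 observations on each side of the "
                         f"interruption (got {n_pre} pre, {n_post} post)")
    if np.linalg.matrix_rank(Xk.to_numpy()) < Xk.shape[1]:
        raise ValueError("rank-deficient segmented design")
    T = len(y)
    L = default_hac_lag(T) if hac_lag is None else int(hac_lag)
    # small-sample correction T/(T-k) and t quantiles for the intervals
    res = sm.OLS(y, Xk).fit(cov_type="HAC",
                            cov_kwds={"maxlags": L, "use_correction": True},
                            use_t=True)
    resid = np.asarray(res.resid)
    dw = durbin_watson(resid)
    # post-interruption trend b1 + b3 with its HAC-based interval
    c = np.array([0.0, 1.0, 0.0, 1.0])
    est = float(c @ res.params)
    se = float(np.sqrt(c @ res.cov_params() @ c))
    z = stats.t.ppf(0.975, res.df_resid)
    fit = ITSFit(params=res.params, bse=res.bse,
                 conf_int=res.conf_int(), pvalues=res.pvalues,
                 residuals=resid, fitted=np.asarray(res.fittedvalues),
                 design=Xk, hac_lag=L, dw=dw,
                 trend_after=(est, est - z * se, est + z * se), label=label)
    return fit


def newey_west_cov(X, residuals, L: int) -> np.ndarray:
    """Sandwich HAC covariance with Bartlett weights w_l = 1 - l/(L+1).

    At L=0 this reduces to the heteroskedasticity-only (White)
    covariance.  Written out directly from the moment definition; the
    statsmodels HAC fit is cross-checked against it in the test suite.
    """
    X = np.asarray(X, dtype=float)
    e = np.asarray(residuals, dtype=float)
    T, k = X.shape
    if not 0 <= L < T:
        raise ValueError("need 0 <= L < T")
    g = X * e[:, None]                       # moment contributions
    S = g.T @ g / T                          # lag-0 term
    for lag in range(1, L + 1):
        w = 1.0 - lag / (L + 1.0)
        gamma = g[lag:].T @ g[:-lag] / T     # lag-l cross products
        S += w * (gamma + gamma.T)
    bread = np.linalg.inv(X.T @ X / T)
    return bread @ S @ bread / T


def durbin_watson(residuals) -> float:
    """d = sum (e_t - e_{t-1})^2 / sum e_t^2, in [0, 4]."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two residuals")
    if np.allclose(e, 0):
        log.warning("Durbin-Watson undefined for all-zero residuals")
        return float("nan")
    return float(_sm_dw(e))


def cumby_huizinga_test(fit: ITSFit, lags: int = 1) -> pd.DataFrame:
    """Score test for residual autocorrelation at lag orders 1..lags.

    For each order q the auxiliary regression of the residuals on the
    original regressors plus q lagged residuals (zeros prepended) gives
    statistic T * R^2, referred to chi-square(q) -- the Breusch-Godfrey
    special case of the Cumby-Huizinga test under an i.i.d. null.
    """
    e = fit.residuals
    T = e.size
    if not 1 <= lags < T / 4:
        raise ValueError("need 1 <= lags < T/4")
    X = fit.design.to_numpy()
    rows = []
    for q in range(1, lags + 1):
        lagged = np.column_stack([
            np.concatenate([np.zeros(l), e[:-l]]) for l in range(1, q + 1)])
        Z = np.column_stack([X, lagged])
        coef, *_ = np.linalg.lstsq(Z, e, rcond=None)
        u = e - Z @ coef
        ss_tot = np.sum((e - e.mean()) ** 2)
        r2 = 1.0 - np.sum(u ** 2) / ss_tot if ss_tot > 0 else 0.0
        stat = T * r2
        rows.append({"lags": q, "statistic": stat, "df": q,
                     "pvalue": float(stats.chi2.sf(stat, q))})
    return pd.DataFrame(rows)
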