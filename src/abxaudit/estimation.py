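"""Rate estimation: exact and simultaneous confidence intervals,
diagnosis-spectrum standardization, and a random-intercept logistic
model for inappropriate prescribing.

Binomial rates carry Clopper-Pearson exact 95% intervals; the joint
split of prescriptions over the four appropriateness classes carries
Goodman simultaneous multinomial intervals.  Crude subgroup rates are
additionally standardized to the diagnosis-category mix of the whole
population over the whole period, which removes case-mix differences
between subgroups.

The odds-ratio model is a logistic regression of the binary outcome
"visit classified inappropriate" (every other class, including
not-linked, forms the reference outcome) on institution, patient and
physician covariates, with a normally distributed random intercept per
institution.  The marginal likelihood integrates the random effect with
a Laplace approximation, which is accurate here because institution
cluster sizes are large.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# interval estimates

@dataclass(frozen=True)
class RateEstimate:
    """x/n as a percentage with a 95% interval (percent scale)."""

    x: float
    n: float
    rate: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    method: str = "clopper_pearson"
    flags: tuple = ()


def clopper_pearson_ci(x: int, n: int, alpha: float = 0.05) -> RateEstimate:
    """Exact binomial interval via beta quantiles, on the percent scale.

    Lower bound is the alpha/2 quantile of Beta(x, n-x+1) (0 when x=0);
    upper is the 1-alpha/2 quantile of Beta(x+1, n-x) (1 when x=n).
    """
    if n < 1:
        raise ValueError("rate undefined for n=0")
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    lo, hi = proportion_confint(x, n, alpha=alpha, method="beta")
    return RateEstimate(x=x, n=n, rate=100.0 * x / n, ci_low=100.0 * lo,
                        ci_high=100.0 * hi, alpha=alpha)


@dataclass(frozen=True)
class MultinomialCI:
    counts: tuple
    n: int
    proportions: tuple
    ci_low: tuple
    ci_high: tuple
    crit: float          # chi-square critical value A
    k: int
    alpha: float = 0.05
    method: str = "goodman"


def goodman_simultaneous_ci(counts, alpha: float = 0.05) -> MultinomialCI:
    """Goodman (1965) simultaneous intervals for multinomial proportions.

    With A the chi-square(1) quantile at 1 - alpha/k, category bounds are
    the roots of the quadratic (n + A) p^2 - (2 x + A) p + x^2 / n = 0:

        [2x + A +- sqrt(A (A + 4 x (n - x) / n))] / (2 (n + A))
    """
    x = np.asarray(counts, dtype=float)
    k = x.size
    if k < 2:
        raise ValueError("need at least two categories")
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    n = x.sum()
    if n < 1:
        raise ValueError("need n >= 1")
    crit = stats.chi2.ppf(1 - alpha / k, df=1)
    half = np.sqrt(crit * (crit + 4 * x * (n - x) / n))
    lo = (2 * x + crit - half) / (2 * (n + crit))
    hi = (2 * x + crit + half) / (2 * (n + crit))
    return MultinomialCI(counts=tuple(x), n=int(n), proportions=tuple(x / n),
                         ci_low=tuple(lo), ci_high=tuple(hi), crit=float(crit),
                         k=k, alpha=alpha)


# --------------------------------------------------------------------------
# direct standardization

@dataclass(frozen=True)
class StandardPopulation:
    """Diagnosis-category weights of the reference population."""

    weights: dict

    def __post_init__(self):
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"standard weights sum to {total}, not 1")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   category_col: str = "category") -> "StandardPopulation":
        """Category shares over all visits of the whole study population."""
        counts = frame[category_col].value_counts(dropna=True)
        w = (counts / counts.sum()).to_dict()
        return cls(weights=w)


def standardized_rate(stratum_rates: dict,
                      standard: StandardPopulation) -> RateEstimate:
    """Directly standardized rate Sum_c w_c r_c (percent scale).

    ``stratum_rates`` maps category -> (x, n) counts in the stratum.
    Categories present in the standard but empty in the stratum
    contribute zero and are flagged.  The variance is the weighted
    binomial variance Sum_c w_c^2 r_c (1 - r_c) / n_c; the interval is
    the normal approximation.
    """
    est = 0.0
    var = 0.0
    x_tot = n_tot = 0.0
    flags = []
    for cat, w in standard.weights.items():
        if cat not in stratum_rates or stratum_rates[cat][1] == 0:
            flags.append(cat)
            continue
        x, n = stratum_rates[cat]
        r = x / n
        est += w * r
        var += w * w * r * (1 - r) / n
        x_tot += x
        n_tot += n
    se = np.sqrt(var)
    z = stats.norm.ppf(0.975)
    return RateEstimate(x=x_tot, n=n_tot, rate=100 * est,
                        ci_low=100 * max(est - z * se, 0.0),
                        ci_high=100 * min(est + z * se, 1.0),
                        method="standardized", flags=tuple(flags))


# --------------------------------------------------------------------------
# random-intercept logistic regression

#: Covariates of the inappropriate-prescribing model with their
#: reference level first (treatment coding).
DEFAULT_COVARIATES = {
    "area_type": ["rural", "urban"],
    "level": ["CHSS_VC", "CHSC_TH"],
    "patient_age": ["18-44", "<6", "6-17", "45-64", ">=65"],
    "patient_gender": ["male", "female"],
    "payment": ["insurance", "out_of_pocket"],
    "year": [2017, 2018, 2019, 2020, 2021],
    "physician_age": ["<30", "30-39", "40-49", "50-59", ">=60"],
    "physician_gender": ["male", "female"],
    "physician_education": ["high_school_or_below", "bachelor_or_above"],
}


@dataclass
class ORModel:
    terms: pd.DataFrame          # term, level, beta, se, or, ci_low, ci_high, reference
    sigma_u: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    beta: np.ndarray = field(repr=False, default=None)
    cov: np.ndarray = field(repr=False, default=None)


def build_design(frame: pd.DataFrame, covariates: dict | None = None):
    """Treatment-coded design matrix with an intercept.

    Returns ``(X, names)`` where each non-intercept column is
    ``covariate=level`` for a non-reference level.
    """
    covariates = covariates or DEFAULT_COVARIATES
    cols = [np.ones(len(frame))]
    names = ["intercept"]
    for cov, levels in covariates.items():
        values = frame[cov]
        for level in levels[1:]:
            cols.append((values == level).to_numpy(dtype=float))
            names.append(f"{cov}={level}")
    return np.column_stack(cols), names


def _laplace_loglik(beta, log_sigma, X, y, group_idx, n_groups,
                    newton_iter=30):
    """Marginal log-likelihood with a 1-D Laplace approximation per group.

    For each group j the random intercept mode u_j solves
    sum_i (y_i - p_i) = u_j / sigma^2; the group's contribution is
    ll_j(u_j) - u_j^2 / (2 sigma^2) - 0.5 log(1 + sigma^2 H_j), with
    H_j the Fisher information of the within-group Bernoulli terms.
    The log(sigma) terms cancel analytically, so sigma -> 0 smoothly
    recovers the ordinary logistic likelihood.
    """
    sigma2 = np.exp(2.0 * log_sigma)
    eta0 = X @ beta
    u = np.zeros(n_groups)
    for _ in range(newton_iter):
        p = 1.0 / (1.0 + np.exp(-(eta0 + u[group_idx])))
        score = np.bincount(group_idx, weights=y - p, minlength=n_groups)
        score -= u / sigma2
        hess = np.bincount(group_idx, weights=p * (1 - p), minlength=n_groups)
        hess += 1.0 / sigma2
        step = score / hess
        u += np.clip(step, -4.0, 4.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + u[group_idx]
    # log Bernoulli likelihood, numerically safe
    ll_obs = -(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y))
    p = 1.0 / (1.0 + np.exp(-eta))
    H = np.bincount(group_idx, weights=p * (1 - p), minlength=n_groups)
    ll = (ll_obs.sum() - 0.5 * np.sum(u * u) / sigma2
          - 0.5 * np.sum(np.log1p(sigma2 * H)))
    return ll


def fit_random_intercept_logit(y, X, groups, names=None, start_sigma=0.3,
                               maxiter=300):
    """ML fit of a logistic model with one normal random intercept.

    ``groups`` is an array of cluster labels.  Returns the packed
    parameter vector ``(beta, log sigma)``, its covariance from the
    numerically differentiated observed information, and the log
    likelihood.  Raises on non-convergence or complete separation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, uniques = pd.factorize(np.asarray(groups))
    n_groups = len(uniques)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    # plain logistic start values
    import statsmodels.api as sm
    try:
        start_beta = sm.Logit(y, X).fit(disp=0, maxiter=200).params
    except Exception:
        start_beta = np.zeros(X.shape[1])
    theta0 = np.append(start_beta, np.log(max(start_sigma, 1e-3)))

    def negloglik(theta):
        return -_laplace_loglik(theta[:-1], theta[-1], X, y, codes, n_groups)

    bounds = [(None, None)] * X.shape[1] + [(-6.0, 3.0)]
    res = optimize.minimize(negloglik, theta0, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": maxiter, "ftol": 1e-11})
    if not res.success and "ROUND" not in str(res.message).upper():
        raise RuntimeError(f"random-intercept fit did not converge: "
                           f"{res.message} after {res.nit} iterations")
    theta = res.x
    if np.max(np.abs(theta[:-1])) > 15:
        raise RuntimeError("coefficients diverged; data may be completely "
                           "separated")
    cov = _numeric_cov(negloglik, theta)
    return theta, cov, -res.fun, n_groups


def _numeric_cov(negloglik, theta, h=1e-4):
    """Inverse of the central-difference Hessian of the negative loglik."""
    p = theta.size
    hess = np.zeros((p, p))
    f0 = negloglik(theta)
    steps = h * np.maximum(1.0, np.abs(theta))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = steps[i]
            ej = np.zeros(p); ej[j] = steps[j]
            if i == j:
                fpp = negloglik(theta + ei)
                fmm = negloglik(theta - ei)
                hess[i, i] = (fpp - 2 * f0 + fmm) / steps[i] ** 2
            else:
                fpp = negloglik(theta + ei + ej)
                fpm = negloglik(theta + ei - ej)
                fmp = negloglik(theta - ei + ej)
                fmm = negloglik(theta - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                    4 * steps[i] * steps[j])
    try:
        return np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(hess)


def fit_inappropriate_or_model(frame: pd.DataFrame,
                               covariates: dict | None = None,
                               group_col: str = "institution_id") -> ORModel:
    """Odds ratios of inappropriate prescribing among antibiotic visits.

    ``frame`` is the visit-level frame from
    :func:`abxaudit.appropriateness.classify_visits`; only
    antibiotic-prescribing visits enter.  The outcome is 1 for
    ``inappropriate`` and 0 for every other class (appropriate,
    potentially appropriate, not linked).
    """
    covariates = covariates or DEFAULT_COVARIATES
    abx = frame[frame["has_antibiotic"]].reset_index(drop=True)
    if abx.empty:
        raise ValueError("no antibiotic-prescribing visits in frame")
    y = (abx["appropriateness"] == "inappropriate").to_numpy(dtype=float)
    X, names = build_design(abx, covariates)
    theta, cov, loglik, n_groups = fit_random_intercept_logit(
        y, X, abx[group_col].to_numpy(), names=names)
    beta = theta[:-1]
    sigma_u = float(np.exp(theta[-1]))
    se = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))
    z = stats.norm.ppf(0.975)

    rows = []
    idx = {n: i for i, n in enumerate(names)}
    for covname, levels in covariates.items():
        rows.append({"term": covname, "level": str(levels[0]), "beta": 0.0,
                     "se": 0.0, "or": 1.0, "ci_low": 1.0, "ci_high": 1.0,
                     "reference": True})
        for level in levels[1:]:
            i = idx[f"{covname}={level}"]
            rows.append({"term": covname, "level": str(level),
                         "beta": beta[i], "se": se[i],
                         "or": float(np.exp(beta[i])),
                         "ci_low": float(np.exp(beta[i] - z * se[i])),
                         "ci_high": float(np.exp(beta[i] + z * se[i])),
                         "reference": False})
    terms = pd.DataFrame(rows)
    return ORModel(terms=terms, sigma_u=sigma_u, loglik=loglik,
                   converged=True, n_obs=len(abx), n_groups=n_groups,
                   beta=beta, cov=cov)
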