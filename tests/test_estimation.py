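import numpy as np
import pytest
from scipy import optimize, stats

from abxaudit.estimation import (StandardPopulation, build_design,
                                 clopper_pearson_ci,
                                 fit_random_intercept_logit,
                                 goodman_simultaneous_ci, standardized_rate)
from abxaudit.synthetic import simulate_logistic_clustered


class TestClopperPearson:
    def test_printed_influenza_interval(self):
        est = clopper_pearson_ci(32, 323)
        assert round(est.rate, 1) == 9.9
        assert round(est.ci_low, 1) == 6.9
        assert round(est.ci_high, 1) == 13.7

    def test_boundaries(self):
        assert clopper_pearson_ci(0, 10).ci_low == 0.0
        assert clopper_pearson_ci(10, 10).ci_high == 100.0

    def test_zero_n_raises(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(0, 0)

    def test_bounds_equal_binomial_tail_inversion(self):
        """Oracle: invert the exact binomial tail probabilities by
        bisection instead of using beta quantiles."""
        x, n, alpha = 5, 20, 0.05
        lower = optimize.brentq(
            lambda p: stats.binom.sf(x - 1, n, p) - alpha / 2, 1e-9, 1 - 1e-9)
        upper = optimize.brentq(
            lambda p: stats.binom.cdf(x, n, p) - alpha / 2, 1e-9, 1 - 1e-9)
        est = clopper_pearson_ci(x, n)
        assert est.ci_low / 100 == pytest.approx(lower, abs=1e-7)
        assert est.ci_high / 100 == pytest.approx(upper, abs=1e-7)

    def test_width_shrinks_with_n_at_fixed_proportion(self):
        widths = [clopper_pearson_ci(3 * m, 10 * m).ci_high
                  - clopper_pearson_ci(3 * m, 10 * m).ci_low
                  for m in (1, 5, 25, 125)]
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestGoodman:
    def test_bounds_solve_defining_quadratic(self):
        """Oracle: recover each bound as a numerical root of
        (n+A) p^2 - (2x+A) p + x^2/n = 0."""
        counts = np.array([231, 154, 83, 32])
        ci = goodman_simultaneous_ci(counts)
        n = counts.sum()
        A = ci.crit
        for x, lo, hi in zip(counts, ci.ci_low, ci.ci_high):
            roots = np.sort(np.roots([n + A, -(2 * x + A), x * x / n]))
            assert lo == pytest.approx(roots[0], abs=1e-10)
            assert hi == pytest.approx(roots[1], abs=1e-10)

    def test_matches_statsmodels_goodman(self):
        from statsmodels.stats.proportion import \
            multinomial_proportions_confint
        counts = [60, 25, 10, 5]
        ci = goodman_simultaneous_ci(counts)
        ref = multinomial_proportions_confint(counts, alpha=0.05,
                                              method="goodman")
        assert np.allclose(ci.ci_low, ref[:, 0], atol=1e-10)
        assert np.allclose(ci.ci_high, ref[:, 1], atol=1e-10)

    def test_degenerate_category_bounds_contained(self):
        ci = goodman_simultaneous_ci([50, 0, 0])
        assert ci.ci_high[0] <= 1.0
        assert ci.ci_low[0] > 0.0
        assert ci.ci_low[1] == 0.0

    def test_two_category_intervals_mirror(self):
        ci = goodman_simultaneous_ci([60, 40])
        assert ci.ci_low[0] == pytest.approx(1 - ci.ci_high[1])
        assert ci.ci_low[0] < 0.6 < ci.ci_high[0]
        assert ci.ci_low[1] < 0.4 < ci.ci_high[1]

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            goodman_simultaneous_ci([10])

    def test_width_shrinks_with_n(self):
        w = []
        for m in (1, 10, 100):
            ci = goodman_simultaneous_ci([30 * m, 50 * m, 20 * m])
            w.append(ci.ci_high[0] - ci.ci_low[0])
        assert w[0] > w[1] > w[2]


class TestStandardization:
    STANDARD = StandardPopulation({"a": 0.5, "b": 0.3, "c": 0.2})

    def test_toy_weighted_sum(self):
        rates = {"a": (10, 100), "b": (20, 100), "c": (40, 100)}
        est = standardized_rate(rates, self.STANDARD)
        assert est.rate == pytest.approx(100 * 0.19)

    def test_constant_rates_are_invariant(self):
        rates = {"a": (30, 100), "b": (60, 200), "c": (15, 50)}
        est = standardized_rate(rates, self.STANDARD)
        assert est.rate == pytest.approx(30.0)

    def test_matching_spectrum_reduces_to_crude(self):
        # stratum spectrum equals the standard weights exactly
        rates = {"a": (11, 500), "b": (45, 300), "c": (60, 200)}
        est = standardized_rate(rates, self.STANDARD)
        crude = 100 * (11 + 45 + 60) / 1000
        assert est.rate == pytest.approx(crude)

    def test_point_estimate_invariant_to_common_scaling(self):
        r1 = {"a": (10, 100), "b": (20, 100), "c": (40, 100)}
        r2 = {k: (7 * x, 7 * n) for k, (x, n) in r1.items()}
        assert standardized_rate(r1, self.STANDARD).rate == pytest.approx(
            standardized_rate(r2, self.STANDARD).rate)

    def test_empty_category_flagged(self):
        est = standardized_rate({"a": (10, 100), "b": (20, 100)},
                                self.STANDARD)
        assert est.flags == ("c",)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            StandardPopulation({"a": 0.7, "b": 0.7})


class TestRandomInterceptLogit:
    def test_degenerate_sigma_matches_plain_logistic(self):
        import statsmodels.api as sm
        y, X, g = simulate_logistic_clustered(60, 80, beta=(-1.0, 0.5),
                                              sigma_u=0.0, seed=3)
        theta, cov, ll, ng = fit_random_intercept_logit(y, X, g)
        plain = sm.Logit(y, X).fit(disp=0).params
        assert np.allclose(theta[:-1], plain, atol=0.02)
        assert np.exp(theta[-1]) < 0.05

    def test_recovers_known_or_with_random_effects(self):
        # generating OR exp(0.5) ~ 1.65 with sigma_u = 0.3
        y, X, g = simulate_logistic_clustered(200, 60, beta=(-1.0, 0.5),
                                              sigma_u=0.3, seed=4)
        theta, cov, ll, ng = fit_random_intercept_logit(y, X, g)
        se = np.sqrt(np.diag(cov))
        assert abs(theta[1] - 0.5) < 3 * se[1]
        assert 0.15 < np.exp(theta[-1]) < 0.45

    def test_matches_lme4_glmer_laplace_fit(self, tmp_path):
        """Independent oracle: R lme4 glmer (nAGQ=1, the same Laplace
        approximation) on identical data."""
        import subprocess

        import pandas as pd
        y, X, g = simulate_logistic_clustered(40, 40, beta=(-0.8, 0.6),
                                              sigma_u=0.4, seed=10)
        csv = tmp_path / "glmm.csv"
        pd.DataFrame({"y": y, "x": X[:, 1], "g": g}).to_csv(csv, index=False)
        theta, cov, ll, _ = fit_random_intercept_logit(y, X, g)
        script = (
            'suppressMessages(library(lme4));'
            f'd <- read.csv("{csv}");'
            'm <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=1);'
            'cat(fixef(m), attr(VarCorr(m)$g, "stddev"),'
            '    as.numeric(logLik(m)), sep="\\n")')
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        b0, b1, sigma, loglik = map(float, out.stdout.split())
        assert theta[0] == pytest.approx(b0, abs=5e-3)
        assert theta[1] == pytest.approx(b1, abs=5e-3)
        assert np.exp(theta[-1]) == pytest.approx(sigma, abs=5e-3)
        assert ll == pytest.approx(loglik, abs=0.05)

    def test_rank_deficient_design_raises(self):
        y, X, g = simulate_logistic_clustered(20, 20, seed=5)
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank"):
            fit_random_intercept_logit(y, X, g)

    def test_reference_levels_get_or_one(self, pipeline_bundle):
        import pandas as pd

        from abxaudit.estimation import fit_inappropriate_or_model
        bundle, gt, config = pipeline_bundle
        frame = bundle["classified_visits"].copy()
        frame["month"] = pd.PeriodIndex(frame["month"], freq="M")
        covariates = {"area_type": ["rural", "urban"],
                      "patient_gender": ["male", "female"]}
        model = fit_inappropriate_or_model(frame, covariates=covariates)
        refs = model.terms[model.terms["reference"]]
        assert (refs["or"] == 1.0).all()
        assert model.sigma_u >= 0
        assert model.n_obs == int(frame["has_antibiotic"].sum())


def test_build_design_columns():
    import pandas as pd
    frame = pd.DataFrame({"area_type": ["rural", "urban", "urban"]})
    X, names = build_design(frame, {"area_type": ["rural", "urban"]})
    assert names == ["intercept", "area_type=urban"]
    assert X[:, 1].tolist() == [0.0, 1.0, 1.0]
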