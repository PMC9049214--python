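# Methods

This note documents the statistical procedures implemented in
`abxaudit`, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Data model

A *visit* is the unit of analysis: all prescription and diagnosis rows
sharing the composite key (institution id, patient id, calendar date).
Key matching is exact string equality plus the calendar date; no fuzzy
matching is attempted, because the source identifier is defined as
exactly those three components. Physician attributes attach to
prescription rows; a visit's physician is the one on the majority of its
prescriptions, ties broken by first appearance in file order. Rows with
unparseable dates, empty codes, unknown code systems, or dates outside
the study window (default 2017-06-01 to 2021-07-31) are dropped and
counted by reason; a diagnosis row dropped this way does not drop the
visit, which can end up "not linked to any diagnosis". Institutions with
fewer than `min_months = 10` distinct calendar months containing at
least one visit are excluded before analysis, with a per-institution
report of month and visit counts.

## Antibiotic coding

The inclusion rule — ATC `J01*` or a nitroimidazole generic name — and
the three label axes (ATC level-4 class, broad/narrow spectrum, AWaRe
category) are driven by `data/antibiotic_catalog.csv`, which users can
edit or replace; validation enforces the invariants (spectrum consistent
with the ATC class; Reserve only for fosfomycin; Unclassified only for
cefathiamidine, cefoperazone/tazobactam, cefoperazone/sulbactam and
etimicin). The broad-spectrum classes are J01DC, J01DD, J01DE (2nd- to
4th-generation cephalosporins), J01MA (fluoroquinolones), J01FA
(macrolides), J01CR (penicillin combinations) and J01GA/J01GB
(aminoglycosides). Nitroimidazoles are accepted under both J01XD
(parenteral) and P01AB (oral). Route is carried through but plays no
role in classification. A few agents in the shipped catalogue
(cefathiamidine, etimicin, cefoperazone/tazobactam) lack official WHO
ATC codes; they carry synthetic codes in the correct level-4 class,
marked by a `90`+ suffix, which is safe because classification is
data-driven. Pattern tables count individual prescribed items, not
visits.

## Diagnosis tiers and appropriateness

`data/tier_map.csv` maps code prefixes to 30 diagnostic categories in
three tiers, plus three TCM pattern groups. Matching strips punctuation
and takes the longest matching prefix, so specific rules (e.g. `J18` →
pneumonia, tier 1) override chapter-level fallbacks (`J` → other
non-infectious, tier 3). Single-letter fallback prefixes make the map
near-total over ICD-10, mirroring a source population in which only a
trace of prescriptions could not be linked to any diagnosis; genuinely
unmatched codes are counted and treated as absent.

Visit assignment priority: lowest tier wins; within a tier, allopathic
(ICD-10) beats TCM; remaining ties go to the lowest category index in
the mapping file. The tie-break affects only the category label, never
the appropriateness class. For category-specific rate tables every TCM
category collapses into one umbrella TCM group.

The TCM handling has three modes: `expert` (the shipped mapping, playing
the role of the original expert review), and the two sensitivity modes
`all_tier2` / `all_tier3` that override every TCM code's tier. Forcing
tier 3 can only move visits toward *inappropriate*; forcing tier 2 can
never produce *inappropriate* from a TCM-bearing visit — both
monotonicities are property-tested.

## Interval estimation and standardization

* Clopper–Pearson: lower bound = Beta(x, n−x+1) quantile at α/2 (0 when
  x = 0), upper = Beta(x+1, n−x) quantile at 1−α/2 (1 when x = n);
  computed via `statsmodels` and cross-checked in tests against direct
  inversion of the binomial tails by bisection. Exact coverage over an
  (n, p) grid is verified ≥ 95% by binomial enumeration.
* Goodman simultaneous intervals: with A = χ²₁(1 − α/k), bounds are
  [2x + A ± √(A(A + 4x(n−x)/n))] / (2(n+A)); implemented in closed form
  and cross-checked against both numerical root-finding and
  `statsmodels`. Joint coverage at k = 4, n = 500 is verified ≥ 95% by
  simulation.
* Directly standardized rates use the whole population's
  diagnosis-category shares as weights: Σ_c w_c r_{g,c}, variance
  Σ_c w_c² r_{g,c}(1−r_{g,c})/n_{g,c} with a normal-approximation
  interval. A category with no visits in a stratum contributes zero and
  is flagged in the output rather than silently renormalized.
* Report tables round percentages half away from zero to one decimal.

## Random-intercept logistic model

The inappropriate-prescribing model is y = 1{visit classified
inappropriate} among antibiotic-prescribing visits (not-linked visits
count in the reference outcome), with treatment-coded covariates (area
type, institution level, patient age/gender/payment, visit year,
physician age/gender/education; reference levels rural, station/clinic,
18–44, male, insurance, 2017, <30, male, high school or below) and a
N(0, σ_u²) intercept per institution. The marginal likelihood uses a
one-dimensional Laplace approximation per cluster; the inner mode search
is a damped Newton iteration vectorized over clusters, and the
log(σ) terms cancel analytically so the fit degrades gracefully to
ordinary logistic regression as σ_u → 0. Outer optimization is L-BFGS-B
over (β, log σ_u); Wald CIs come from the numerically differentiated
observed information. On test data the fit agrees with `lme4::glmer`
(its default Laplace, nAGQ = 1) to four decimals in coefficients, σ_u
and log-likelihood, and recovers generating odds ratios at
σ_u ∈ {0, 0.3}. No installed Python library offers a frequentist
binomial GLMM, which is why this component is implemented here.
Laplace is adequate because institution clusters are large (hundreds to
thousands of visits); with very small clusters adaptive quadrature would
be preferable.

## Interrupted time series

Monthly series are built per stratum; months with a zero denominator are
flagged missing and excluded from the fit. Seasonal adjustment is
classical additive decomposition (trend = 2×12 centred moving average;
factor of calendar month m = mean detrended value of that month,
re-centred to sum to zero; adjusted = raw − factor). This deliberately
replaces the X-12-ARIMA procedure used in the original SAS workflow: a
full X-12 reimplementation is out of scope, and for series of this
length the classical factors capture the injected 12-month cycle in
simulation.

The segmented design is (1, t, Intv, taft) with Intv stepping to 1 at
the interruption month (parameter, default 2020-03) and taft = 0 through
the interruption then 1, 2, …, so the step coefficient is the immediate
level change at the interruption itself; this offset convention is a
configuration choice, exposed in `make_design`. At least four
observations are required on each side. Coefficient covariances are
Newey–West with Bartlett weights w_l = 1 − l/(L+1), default lag
L = ⌊4(T/100)^{2/9}⌋ (3 at T = 50), with the T/(T−k) small-sample
correction and t-distribution quantiles for intervals — the convention
of Stata's `newey`. The post-interruption trend β₁+β₃ is reported with a
CI from the same HAC covariance (the HAC-or-OLS choice for this derived
quantity is not fixed by convention; HAC is used for everything).

A caveat established by simulation (2000 replicates, T = 50,
interruption at month 34, AR(1) ρ = 0.3): truncated-kernel HAC standard
errors for the step coefficient average ~25–30% below the true sampling
standard deviation, so nominal 95% intervals cover the generating level
change in only ~82–86% of replicates (~85–89% with Andrews–Monahan
prewhitening). This is the well-known finite-sample downward bias of
kernel HAC for a local contrast, not an implementation artifact — a
hand-written sandwich matches `statsmodels` exactly, and point estimates
are unbiased (mean level-change estimate −2.84 vs −2.8 generating).
Interval widths at T ≈ 50 should therefore be read as optimistic.

Diagnostics: Durbin–Watson d = Σ(e_t−e_{t−1})²/Σe_t² (flagged undefined
for all-zero residuals), and a score test for autocorrelation at lags
1..q — the auxiliary regression of residuals on the original regressors
plus q lagged residuals, statistic T·R² against χ²(q). This is the
Breusch–Godfrey special case of the Cumby–Huizinga test, valid under the
i.i.d. null being tested; the general instrumented form is not needed
for OLS residuals. Size ≈ 5% under white noise and high power against
AR(1) ρ = 0.8 are both verified by simulation.

## Synthetic data generator

`simulate_dataset` emulates: four institution types with configurable
counts and monthly visit volumes (default 12 institutions, 50 months,
≈53k visits — a deliberate ~200× scale-down of the source population
that keeps every estimator comfortably identified); patient/physician
attribute margins matching the published characteristics table; a
diagnosis spectrum over the 30 categories plus TCM (≈13% TCM); Bernoulli
prescribing on the logit scale with per-tier base probabilities (default
0.56/0.50/0.073 for tiers 1/2/3), institution intercepts
(σ_u = 0.3), a cosine 12-month seasonal term, a linear drift, and a
step-plus-slope change at March 2020 whose default size (−0.25 logit
≈ −2.8 percentage points at the overall rate) matches the reported
immediate drop. Covariate effects and the drift are centred at their
population means, so the tier base probabilities remain interpretable as
marginal tier-wise rates. Antibiotic items are drawn from a mixture over
the catalogue with roughly the published class shares; visits without
antibiotics receive a non-antibiotic filler prescription so every visit
carries physician information. Ground truth (per-tier counts and rates,
appropriateness mix, item label counts, the injected interruption
parameters) is written alongside the CSVs and is sufficient to predict
every downstream statistic without re-running the generator.

What it does **not** emulate: correlations between patient attributes
and diagnosis category (margins only), within-patient correlation over
repeat visits, institution-level volume trends, miscoded or free-text diagnoses, and
any joint covariate distribution of the source city. Passing pipeline tests on synthetic data therefore
demonstrate correctness of the estimators and bookkeeping, not
real-world validity of the emulated parameter values.

`simulate_monthly_series` bypasses the visit level and draws monthly
outcomes directly from the segmented line plus an optional seasonal
vector and AR(1) noise (stationary initialization), for fast
estimator-recovery studies. `simulate_logistic_clustered` does the same
for the mixed logistic model.

## Degenerate inputs and numerical conventions

Zero-denominator rates raise; x = 0 / x = n interval bounds are exact 0
and 1; the Goodman computation requires k ≥ 2 and n ≥ 1; rank-deficient
segmented or logistic designs raise; complete separation in the logistic
model raises rather than returning divergent coefficients; all Monte
Carlo in the package and tests runs on seeded `numpy` generators, and
the dataset generator is byte-reproducible for a fixed config.
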