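# Methods

This note records the models, the defaults and the numerical choices, in
the order the pipeline runs. It states no empirical result beyond what
the test suite and `scripts/acceptance.py` themselves compute.

## Synthetic cohort generator

The generator produces person-level tables with the structure the
analysis assumes; it is the ground truth against which every estimator
is validated.

**Model.** Age is uniform on [45, 95] (continuous; surveys bin by year,
which is a display choice only). Treatment (pension receipt) is zero
below the cutoff (60); at and above it the probability is

    P(pension | age) = J + (1 − J)(1 − exp(−λ (age − 60))),

a jump of `first_stage_jump` J (default 0.65) followed by a rise toward 1
with rate `takeup_lambda` λ (default 0.30/year) — the shape produced by
annual or quarterly eligibility reviews that delay first payment.
Optional coefficients (`takeup_covariate_coefs`) shift the above-cutoff
probability with centred covariates to create confounded designs for
testing the matching correction; by default take-up depends on age only.

Latent health is

    H* = s_pre·(age−60)⁻ + s_post·(age−60)⁺ + τ(tercile)·pension
         + Σ_k β_k x_k + γ·z_income + ε,   ε ~ N(0, σ²),

with both age slopes negative and the post-cutoff slope steeper
(defaults −0.05/−0.09 per year), a per-person treatment effect equal to
the value of `late_by_tercile` for the person's income tercile, additive
covariate effects, and an income loading γ = ρ/√(1−ρ²)·σ chosen so that
the non-age health component correlates with standardized log income at
`health_income_corr` ρ. Log household income is normal (defaults 7.55 ±
1.18 log-yuan, matching the emulated survey's descriptive statistics).

**Defaults as study conditions.** `late_by_tercile` defaults to
(2.00, 1.96, 1.32) — the published conventional subgroup estimates for
the low/middle/high income groups — and ρ = 0.30. Together these
reproduce the two first-order facts the cohort must carry: a health
effect that favours the poor, and nonetheless a small *positive*
concentration index (the income–health correlation outweighs the
equalising treatment effect). Covariate marginals (gender 0.49, marriage
0.81, agricultural job 0.68, insurance 0.90, medical-quality mean ≈ 2.5)
follow the survey's descriptive table; their income-rank dependence
coefficients are free parameters — the survey does not report the joint
distribution — set to small values of plausible sign.

**Ordinal ratings.** The two survey ratings are generated by adding an
independent rater error (SD 0.5) to latent health and cutting at
empirical quantiles into 5 (self-rated) and 7 (rated-by-others)
equal-occupancy bins. The scales are given by the survey; the response
model is ours.

**Reproducibility.** One PCG64 generator seeded by `seed`; draw order is
fixed (age, log income, covariates in declaration order, pension, health
noise, two rater noises), so cohorts are bit-reproducible.

**What the generator does not emulate.** Survey sampling design,
household clustering, attrition, survey weights, measurement error
correlated with income, and any discreteness of reported age. Passing
tests therefore show correctness of the estimators under clean
assumptions, not robustness to those real-data features.

## Composite health index

Each ordinal rating is z-standardized with the population convention
(divisor n) and the two z-scores are summed. Standardization always uses
the full input sample, so subgroup analyses stay on one scale; the
composite has mean 0 on that sample by construction. The index is
invariant to positive affine transforms of either raw rating. A constant
rating is rejected (zero variance carries no information).

## Fuzzy RD estimation

**Conventions.** An observation exactly at the cutoff belongs to the
right (eligible) side in every operation. Kernels: triangular 1−|u|,
Epanechnikov 0.75(1−u²), uniform 0.5, all on |u| ≤ 1; triangular is the
default.

**Estimators.** Each boundary value is a kernel-weighted local-linear
fit on its own side; variances are HC0 sandwiches with the kernel
weights. The conventional fuzzy estimate is the Wald ratio of the
outcome and treatment jumps with a delta-method SE that includes the
per-side outcome–treatment intercept covariance. The bias-corrected
estimate subtracts the leading kernel bias (ν/2)h²(m″₊ − m″₋) from both
jumps, with curvatures m″ from one-sided local-quadratic pilot fits at
bandwidth b; ν is the second moment of the equivalent boundary kernel
(−0.1 for triangular). The robust SE adds the sandwich (co)variance of
the estimated bias terms to the conventional one (cross-covariance
between the linear and quadratic fits is neglected; the coverage of the
resulting intervals is verified by Monte Carlo in the test suite). If
bias-correcting the first stage itself would push the treatment jump
below the weak-identification threshold, the uncorrected first stage is
kept — curvature correction of a probability jump near the threshold is
noise-dominated.

**Bandwidths.** The main bandwidth is the IK plug-in: Silverman pilot
h₁ = 1.84·sd(x)·n^(−1/5); boundary variances and density at the cutoff
from the ±h₁ window; third derivative from a global cubic with a level
shift; second-stage bandwidths 3.56·(σ²/(f·m‴²))^(1/7)·N^(−1/7);
one-sided quadratic curvatures with regularization terms
2160·σ²/(N₂h₂⁴); and the final constant C_K = (V/ν²)^(1/5) computed from
the kernel's equivalent boundary kernel (3.4375 for triangular). The
selector is deterministic, exactly scale-equivariant, and falls back to
the Silverman rule with a logged warning on degenerate inputs. The pilot
bandwidth for the bias quadratics defaults to b = h·n^(2/35), which
restores the optimal n^(−1/7) rate for curvature estimation from an h of
order n^(−1/5); a second full plug-in for the quadratic order would add
constants the data cannot distinguish. Robustness grids scale h by 0.5/2.

**Identification guard.** A first-stage jump of 0.05 or less raises an
explicit weak-identification error rather than returning an exploding
ratio (this matters in small subgroups).

**Covariate adjustment.** Default is residualize-then-estimate: outcome
and treatment are regressed on the covariates globally and the RD runs
on the residuals (means added back). Including the covariates directly
in the one-sided weighted fits is available via
`controls_method="local"`.

**Validity battery.** (i) Density test: 40 equal-width bins in a
symmetric window around the cutoff, a GLS line per side on bin
log-counts with Poisson variance 1/count, and a normal test of the
fitted log-density jump. (ii) Covariate smoothness: the sharp-RD jump of
every covariate, with raw and Holm-adjusted p-values (several covariates
are tested at once). (iii) Placebo cutoffs: outcome jumps at counterfeit
thresholds, estimated only on the true cutoff's same side so the genuine
discontinuity cannot enter the window; a guard window of ±2 years around
the true cutoff is enforced.

**Heterogeneity.** Income groups split at the 30th/70th percentiles of
per-capita income (exp of log income); the bandwidth is re-selected per
group; failing groups are flagged while the others are returned.

## Concentration index and decomposition

Fractional ranks are (rank − 0.5)/n in ascending income order with mean
positional ranks for ties, which keeps the rank mean exactly 0.5 and
makes CI ≡ 2·cov_n(health, R)/H̄ an algebraic identity. The curve is the
cumulative health share against the cumulative population share; twice
the area between diagonal and curve equals the index up to O(1/n).

The index is scale-invariant but **not** translation-invariant, and the
composite health index is mean-zero with negative values, which makes
the raw index ill-defined. Default policy: shift health by 1 − min(health)
(minimum becomes 1) before computing the index; the shift is recorded in
every result and can be disabled (`shift="none"`). Consequently reported
CI magnitudes depend on that convention — the sign and the decomposition
shares are the interpretable quantities.

Decomposition: with regression coefficients α_k, each factor contributes
α_k·2cov(X_k, R)/H̄ (equal to e_k·CI_k whenever X̄_k ≠ 0; a zero-mean
factor reports elasticity 0 with a note and contributes via the rank
covariance directly). The residual term is the generalized concentration
index of the residuals divided by mean health, which closes the identity
Σ contributions + residual = total CI exactly — to 1e-10 in the tests —
for any coefficient vector, in particular OLS on the estimation sample.
Contribution rates divide by a denominator D: by default the total CI of
the (shifted) health variable used in the regression; alternatively D is
calibrated from a reference row with a known rate
(`calibrated_contribution_rates`), which is how a published table's
elasticity/CI columns can be checked for internal consistency without
access to the underlying microdata. Rates are reported signed; a
negative rate marks an inequality-reducing factor.

## Propensity-score matching

Logit propensity of pension receipt on age plus the five survey
covariates; matching on the logit of the score, 1:1 nearest neighbour
without replacement, caliper 0.2·SD(logit score), treated units
processed in descending propensity order (deterministic; the thin end of
the control distribution picks first), equidistant ties broken by a
seeded draw recorded in the configuration. Balance is reported as
standardized mean differences (mean difference over the pooled SD)
before and after matching. Matching never sees the outcome — the
function signature takes only propensities and treatment. The matched
OLS uses HC1 robust standard errors.

## Pipeline

The composite health index is built on the full input table; the RD
stage uses all ages. The inequality and decomposition stage runs on the
pension-eligible elderly (age ≥ 60) — the emulated survey's descriptive
sample is ages 60–95, and below the cutoff nobody is treated, so age
would perfectly separate the propensity model there. If the eligible
sample has a single treatment class (e.g. a sharp design), matching is
skipped with a warning and the decomposition regression runs unmatched.

Generator-truth columns (`latent_health`, `true_late`) are stripped on
load; estimation cannot read them (tested by corrupting them on disk and
asserting an identical report). Reports carry a config hash, seed and
library versions; reruns with the same config and seed are byte-identical
up to timestamps. Significance stars follow the emulated tables'
convention: *** p < 0.01, ** p < 0.05, * p < 0.1.

## Problem sizes in the test suite

Monte-Carlo checks use cohorts of n = 2,000–20,000 and 100–500
replicates per criterion (500 for LATE unbiasedness/coverage, 400 for
test size, 200 for the income gradient and density power, 100 for
bandwidth rate and matching), and one n = 10⁶ sample for the analytic
CI limit — sizes at which the Monte-Carlo error is well below each
criterion's tolerance.

## Known limitations

* The bias-corrected/robust construction neglects the covariance between
  the main and pilot fits; coverage is validated empirically, not
  derived.
* The density test uses a normal approximation on binned log-counts; for
  very sparse bins (< ~5 expected per bin) its size degrades.
* Matching assumes overlap; with near-saturated take-up the control pool
  is thin and many treated units go unmatched (reported, not repaired).
* The decomposition attributes inequality through a linear model; it is
  an accounting identity, not a causal decomposition, except insofar as
  the matched design justifies the pension coefficient.
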