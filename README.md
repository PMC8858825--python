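# rdineq

Does a rural pension benefit improve the health of the elderly, and does it
narrow the health gap between poor and rich? `rdineq` implements the two
statistical instruments used to answer those questions from household-survey
data, wired into one reproducible pipeline and driven by a synthetic cohort
generator so that every estimator can be validated against known ground
truth:

1. **Fuzzy regression-discontinuity (RD) estimation** of the local average
   treatment effect (LATE) of pension receipt on health at the
   eligibility age of 60. Eligibility reviews delay first payment, so the
   probability of receiving the benefit jumps at 60 by less than one; the
   LATE is the Wald ratio of boundary discontinuities,

   LATE = [lim(a↓60) E(Health|a) − lim(a↑60) E(Health|a)] /
          [lim(a↓60) P(Pension|a) − lim(a↑60) P(Pension|a)],

   estimated by one-sided kernel-weighted local-linear regressions with the
   Imbens–Kalyanaraman (IK) plug-in bandwidth, reported as the conventional /
   bias-corrected / robust trio, and accompanied by the standard validity
   battery (McCrary-style density-manipulation test, covariate smoothness
   tests, placebo cutoffs) and income-group heterogeneity.

2. **Concentration index (CI) and its decomposition.** With R_i the
   fractional income rank, CI = (1/n) Σ_i Health_i/H̄ · (2R_i − 1)
   (equivalently twice the covariance of health with the income rank over
   mean health; twice the area between the concentration curve and the
   diagonal). A regression of health on factors X_k with coefficients α_k
   splits the index into factor contributions e_k·CI(X_k), with elasticity
   e_k = α_k X̄_k/H̄, plus a residual term — each factor's contribution rate
   is its share of the total in percent. The decomposition regression is run
   on a propensity-score-matched sample (logit propensity, 1:1 nearest
   neighbour without replacement, caliper 0.2 SD of the logit score) so the
   coefficients come from a covariate-balanced comparison.

The package is aimed at applied health-economics and epidemiology work with
person-level survey tables (age, treatment indicator, two ordinal health
ratings, demographics, log household income).

## Worked example

```bash
rdineq demo --out results/demo --n 10000 --seed 0
```

simulates a cohort of 10,000 (ages 45–95, treatment-probability jump 0.65
at age 60, income-correlated health, income-graded treatment effects),
builds the composite health index (sum of the z-scores of the two ordinal
ratings), and prints

```
robust LATE 2.3273*** (SE 0.1439); first stage 0.734; CI 0.0085
pension contribution rate -4.48% (denominator 0.0301)
```

Read: at the age-60 threshold the probability of receiving the pension
jumps by 0.734; scaling the health discontinuity by that jump gives a
robust (bias-corrected, variance-inflated) LATE of 2.33 composite-health
points for compliers (*** = p < 0.01). The concentration index of health
over income among the 60+ sample is 0.0085 — slightly pro-rich health
inequality — and the pension factor's contribution rate is negative, i.e.
the benefit reduces measured inequality because its health effect is
positive while its own income gradient is not pro-rich.

`results/demo/` then contains the full estimator grid
(`table2_grid.csv`: three estimator rows × bandwidth multipliers 0.5/1/2 ×
triangular/Epanechnikov/uniform kernels × with/without controls), the
income-tercile group estimates (`table3_groups.csv`: in this run
conventional LATEs 2.47/2.68/1.78 for low/middle/high income), the
decomposition table (`decomposition.csv`), the concentration-curve points,
and `report.json` with the validity battery and provenance (config hash,
seed, versions).

The same stages are available as library functions
(`rdineq.fuzzy_late`, `rdineq.ik_bandwidth`, `rdineq.concentration_index`,
`rdineq.decompose_ci`, `rdineq.estimate_propensity`, ...) and as further
CLI verbs (`simulate`, `analyze`, `decompose`, `report`).

## Layout

```
src/rdineq/
  synthetic.py   cohort generator (the testing ground; documented draw order)
  health.py      composite health index from the two ordinal ratings
  frdd.py        kernels, IK bandwidth, sharp/fuzzy RD, validity battery
  inequality.py  fractional ranks, CI, concentration curve, decomposition
  psm.py         propensity model, matching, matched OLS
  pipeline.py    end-to-end orchestration and table rendering
  cli.py         typer CLI (console script `rdineq`)
docs/methods.md  modelling and numerical choices in detail
```
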