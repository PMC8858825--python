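"""Synthetic survey-cohort generator.

Produces person-level cohorts of rural elderly with the statistical
structure the downstream analysis assumes: a jump in the probability of
receiving a pension benefit at the eligibility age (60), age-declining
latent health with a level shift at the cutoff, income-correlated health
(yielding a small positive concentration index), treatment effects that
vary by income tercile, and covariate marginals resembling a national
household survey.

The generator is the testing ground for the whole pipeline: the latent
health scale and the per-person treatment effect are retained (columns
``latent_health`` and ``true_late``) so that estimators can be validated
against ground truth. Estimation code must never read those columns.

Draw order is fixed and documented (age, log income, covariates in
declaration order, pension, health noise, two rater noises), so a given
seed reproduces a cohort bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CovariateSpec",
    "SyntheticConfig",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
    "TRUTH_COLUMNS",
]

#: CSV schema, in column order. Truth columns are optional on disk.
COHORT_COLUMNS = [
    "age",
    "pension",
    "self_health",
    "other_health",
    "gender",
    "marriage",
    "job_type",
    "insured",
    "log_income",
    "med_quality",
]
TRUTH_COLUMNS = ["latent_health", "true_late"]

_COLUMN_DTYPES = {
    "age": float,
    "pension": int,
    "self_health": int,
    "other_health": int,
    "gender": int,
    "marriage": int,
    "job_type": int,
    "insured": int,
    "log_income": float,
    "med_quality": int,
    "latent_health": float,
    "true_late": float,
}


@dataclass(frozen=True)
class CovariateSpec:
    """One background covariate of the cohort.

    Parameters
    ----------
    kind:
        ``"bernoulli"`` for 0/1 covariates, ``"ordinal"`` for an ordered
        categorical coded 1..len(probs).
    p:
        Success probability (bernoulli only).
    probs:
        Category probabilities (ordinal only), summing to 1.
    rank_coef:
        Linear dependence of the covariate on the person's income
        fractional rank, centred at 0.5. For bernoulli covariates the
        success probability becomes ``p + rank_coef * (rank - 0.5)``
        (clipped to [0, 1]); for ordinal covariates the latent category
        propensity is shifted analogously.
    health_beta:
        Additive effect of the covariate on latent health (per unit for
        bernoulli, per category step above the midpoint for ordinal).
    """

    kind: str = "bernoulli"
    p: float = 0.5
    probs: tuple[float, ...] = ()
    rank_coef: float = 0.0
    health_beta: float = 0.0


def _default_covariates() -> dict[str, CovariateSpec]:
    # Marginals follow the descriptive statistics of the emulated survey:
    # gender 0.49, marriage 0.81, agricultural job 0.68, medical-insurance
    # enrollment 0.90, medical-quality rating mean ~2.5 on a 1-5 scale.
    return {
        "gender": CovariateSpec("bernoulli", p=0.49, rank_coef=0.02, health_beta=-0.10),
        "marriage": CovariateSpec("bernoulli", p=0.81, rank_coef=-0.10, health_beta=0.20),
        "job_type": CovariateSpec("bernoulli", p=0.68, rank_coef=-0.08, health_beta=-0.20),
        "insured": CovariateSpec("bernoulli", p=0.90, rank_coef=-0.05, health_beta=0.10),
        "med_quality": CovariateSpec(
            "ordinal",
            probs=(0.12, 0.42, 0.32, 0.10, 0.04),
            rank_coef=0.10,
            health_beta=0.05,
        ),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """All parameters of the cohort generator.

    Attributes
    ----------
    n:
        Number of individuals.
    age_range:
        Support of the (continuous, uniform) age distribution in years.
    cutoff:
        Pension-eligibility age. Below it the treatment probability is 0.
    first_stage_jump:
        Jump in P(pension) at the cutoff, in (0, 1].
    takeup_lambda:
        Rate of the delayed take-up above the cutoff:
        ``P = jump + (1 - jump) * (1 - exp(-lambda * (age - cutoff)))``,
        emulating periodic eligibility reviews that postpone first payment.
    late_by_tercile:
        Treatment effect on the latent health scale for the low-, middle-
        and high-income tercile.
    age_slopes:
        (pre, post) latent-health slopes per year of age; both must be
        <= 0 and the post-cutoff slope must be at least as steep.
    income_log_mean, income_log_sd:
        Normal parameters of log household income.
    health_income_corr:
        Correlation between the non-age component of latent health and
        log income, in (-1, 1). Implemented by mixing the standardized
        log income into the health error at the corresponding loading.
    covariates:
        Mapping of covariate name to :class:`CovariateSpec`. The five
        default covariates match the cohort CSV schema.
    takeup_covariate_coefs:
        Optional additive shifts of the above-cutoff take-up probability
        per (centred) covariate unit; nonzero values create confounding
        between treatment and covariates, useful for testing matching
        corrections. Defaults to none (take-up driven by age only).
    noise_sd:
        Scale of the idiosyncratic latent-health error.
    rater_noise_sd:
        Scale of the independent rater errors added before the latent
        health is discretized into the two ordinal ratings.
    seed:
        Seed of the single PCG64 generator governing all draws.
    """

    n: int = 10_000
    age_range: tuple[float, float] = (45.0, 95.0)
    cutoff: float = 60.0
    first_stage_jump: float = 0.65
    takeup_lambda: float = 0.30
    late_by_tercile: tuple[float, float, float] = (2.00, 1.96, 1.32)
    age_slopes: tuple[float, float] = (-0.05, -0.09)
    income_log_mean: float = 7.55
    income_log_sd: float = 1.18
    health_income_corr: float = 0.30
    covariates: Mapping[str, CovariateSpec] = field(default_factory=_default_covariates)
    takeup_covariate_coefs: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    rater_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError(f"n must be positive, got n={self.n}")
        lo, hi = self.age_range
        if not lo < self.cutoff < hi:
            raise ValueError(
                f"cutoff must lie inside age_range, got cutoff={self.cutoff}, "
                f"age_range={self.age_range}"
            )
        if not 0.0 < self.first_stage_jump <= 1.0:
            raise ValueError(
                f"first_stage_jump must be in (0, 1], got {self.first_stage_jump}"
            )
        if self.takeup_lambda < 0:
            raise ValueError(f"takeup_lambda must be >= 0, got {self.takeup_lambda}")
        pre, post = self.age_slopes
        if pre > 0 or post > 0:
            raise ValueError(f"age_slopes must both be <= 0, got {self.age_slopes}")
        if post > pre:
            raise ValueError(
                "post-cutoff age slope must be at least as steep as the "
                f"pre-cutoff slope, got age_slopes={self.age_slopes}"
            )
        if not -1.0 < self.health_income_corr < 1.0:
            raise ValueError(
                f"health_income_corr must be in (-1, 1), got {self.health_income_corr}"
            )
        if self.income_log_sd <= 0:
            raise ValueError(f"income_log_sd must be > 0, got {self.income_log_sd}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.rater_noise_sd < 0:
            raise ValueError(f"rater_noise_sd must be >= 0, got {self.rater_noise_sd}")
        if len(self.late_by_tercile) != 3:
            raise ValueError("late_by_tercile must have exactly three entries")
        for name, spec in self.covariates.items():
            if spec.kind == "bernoulli":
                if not 0.0 <= spec.p <= 1.0:
                    raise ValueError(
                        f"covariate {name!r}: probability p={spec.p} outside [0, 1]"
                    )
            elif spec.kind == "ordinal":
                probs = np.asarray(spec.probs, dtype=float)
                if probs.size < 2 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
                    raise ValueError(
                        f"covariate {name!r}: probs must be >= 0 and sum to 1, "
                        f"got {spec.probs}"
                    )
            else:
                raise ValueError(f"covariate {name!r}: unknown kind {spec.kind!r}")
        for name in self.takeup_covariate_coefs:
            if name not in self.covariates:
                raise ValueError(
                    f"takeup_covariate_coefs references unknown covariate {name!r}"
                )

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SyntheticConfig":
        raw = dict(raw)
        if "covariates" in raw:
            raw["covariates"] = {
                name: CovariateSpec(**{**spec, "probs": tuple(spec.get("probs", ()))})
                if isinstance(spec, Mapping)
                else spec
                for name, spec in raw["covariates"].items()
            }
        for key in ("age_range", "late_by_tercile", "age_slopes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["covariates"] = {
            name: dataclasses.asdict(spec) for name, spec in self.covariates.items()
        }
        return out


def _fractional_rank_of(values: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return (rankdata(values, method="average") - 0.5) / values.size


def _equal_probability_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize into 1..n_bins bins with (near-)equal occupancy.

    Thresholds are the empirical quantiles of the supplied vector, which
    calibrates the response scale on the generated population itself.
    """
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return 1 + np.searchsorted(edges, values, side="left").astype(int)


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Draw one cohort under ``config``.

    Returns a DataFrame with the cohort CSV schema plus the two truth
    columns ``latent_health`` (the continuous health index before
    discretization) and ``true_late`` (the person's treatment effect).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    lo, hi = config.age_range
    cutoff = config.cutoff

    # Draw order is fixed: age, log income, covariates, pension, noises.
    age = rng.uniform(lo, hi, size=n)
    log_income = rng.normal(config.income_log_mean, config.income_log_sd, size=n)
    income_rank = _fractional_rank_of(log_income)

    covariate_values: dict[str, np.ndarray] = {}
    covariate_effect = np.zeros(n)
    for name, spec in config.covariates.items():
        if spec.kind == "bernoulli":
            p = np.clip(spec.p + spec.rank_coef * (income_rank - 0.5), 0.0, 1.0)
            x = (rng.uniform(size=n) < p).astype(int)
            covariate_effect += spec.health_beta * x
        else:
            probs = np.asarray(spec.probs, dtype=float)
            k = probs.size
            cum = np.cumsum(probs)
            u = np.clip(
                rng.uniform(size=n) + spec.rank_coef * (income_rank - 0.5), 0.0, 1.0
            )
            x = 1 + np.searchsorted(cum[:-1], u, side="right").astype(int)
            covariate_effect += spec.health_beta * (x - (k + 1) / 2.0)
        covariate_values[name] = x

    # Treatment: zero below the cutoff; above it the probability jumps by
    # first_stage_jump and then rises toward 1 with the delayed-review shape.
    above = age >= cutoff
    p_treat = np.zeros(n)
    years_past = np.maximum(age - cutoff, 0.0)
    base = config.first_stage_jump + (1.0 - config.first_stage_jump) * (
        1.0 - np.exp(-config.takeup_lambda * years_past)
    )
    for name, coef in config.takeup_covariate_coefs.items():
        spec = config.covariates[name]
        centre = spec.p if spec.kind == "bernoulli" else float(
            np.dot(np.arange(1, len(spec.probs) + 1), spec.probs)
        )
        base = base + coef * (covariate_values[name] - centre)
    p_treat[above] = np.clip(base[above], 0.0, 1.0)
    pension = (rng.uniform(size=n) < p_treat).astype(int)

    # Per-person effect: the tercile value for the person's income tercile.
    terciles = np.searchsorted(
        np.quantile(log_income, [1 / 3, 2 / 3]), log_income, side="right"
    )
    true_late = np.asarray(config.late_by_tercile, dtype=float)[terciles]

    pre_slope, post_slope = config.age_slopes
    trend = np.where(
        above, post_slope * (age - cutoff), pre_slope * (age - cutoff)
    )
    rho = config.health_income_corr
    z_income = (log_income - config.income_log_mean) / config.income_log_sd
    income_loading = rho / np.sqrt(1.0 - rho**2) * config.noise_sd
    noise = rng.normal(0.0, config.noise_sd, size=n)
    latent = (
        trend
        + true_late * pension
        + covariate_effect
        + income_loading * z_income
        + noise
    )

    rater_self = rng.normal(0.0, config.rater_noise_sd, size=n)
    rater_other = rng.normal(0.0, config.rater_noise_sd, size=n)
    self_health = _equal_probability_bins(latent + rater_self, 5)
    other_health = _equal_probability_bins(latent + rater_other, 7)

    return pd.DataFrame(
        {
            "age": age,
            "pension": pension,
            "self_health": self_health,
            "other_health": other_health,
            "gender": covariate_values["gender"],
            "marriage": covariate_values["marriage"],
            "job_type": covariate_values["job_type"],
            "insured": covariate_values["insured"],
            "log_income": log_income,
            "med_quality": covariate_values["med_quality"],
            "latent_health": latent,
            "true_late": true_late,
        }
    )


def write_cohort(cohort: pd.DataFrame, path, keep_truth: bool = True) -> None:
    """Write a cohort to CSV (UTF-8, header row, full float precision)."""
    cols = list(COHORT_COLUMNS)
    if keep_truth and all(c in cohort.columns for c in TRUTH_COLUMNS):
        cols += TRUTH_COLUMNS
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing required columns: {missing}")
    cohort.to_csv(path, index=False, columns=cols, float_format="%.17g")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema and column types."""
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    extra = [
        c for c in table.columns if c not in COHORT_COLUMNS and c not in TRUTH_COLUMNS
    ]
    if missing or extra:
        raise ValueError(
            f"cohort schema mismatch: missing columns {missing}, "
            f"unexpected columns {extra}"
        )
    for col in table.columns:
        try:
            table[col] = table[col].astype(_COLUMN_DTYPES[col])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"column {col!r} could not be parsed as numeric") from exc
    return table
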