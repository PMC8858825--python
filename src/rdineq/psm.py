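"""Propensity-score matching correction for the decomposition regression.

Pension receipt is not randomly assigned away from the eligibility
cutoff, so the OLS coefficients feeding the concentration-index
decomposition are estimated on a covariate-balanced sample: a logit
propensity model of treatment on the covariates, 1:1 nearest-neighbour
matching without replacement on the logit of the propensity score with
a caliper of 0.2 standard deviations of that logit, and OLS with
heteroskedasticity-robust standard errors on the matched sample.

Matching never sees the outcome: :func:`match` takes only propensities
and treatment status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "PropensityFit",
    "MatchedSample",
    "RegressionFit",
    "SeparationError",
    "estimate_propensity",
    "match",
    "matched_ols",
    "standardized_mean_differences",
]


class SeparationError(ValueError):
    """The logit model separates treatment perfectly."""


@dataclass(frozen=True)
class PropensityFit:
    propensity: np.ndarray  # strictly inside (0, 1)
    coefficients: pd.Series
    covariate_names: tuple[str, ...]
    treatment: np.ndarray


@dataclass(frozen=True)
class MatchedSample:
    pairs: pd.DataFrame  # columns: treated, control, distance
    caliper: float
    smd_before: pd.Series
    smd_after: pd.Series
    n_treated: int
    n_unmatched_treated: int

    @property
    def indices(self) -> np.ndarray:
        """Row indices of the matched sample (treated + their controls)."""
        return np.concatenate(
            [self.pairs["treated"].to_numpy(), self.pairs["control"].to_numpy()]
        )


@dataclass(frozen=True)
class RegressionFit:
    intercept: float
    treatment_coef: float
    treatment_se: float
    coefficients: pd.Series  # covariate coefficients
    robust_se: pd.Series
    residuals: np.ndarray
    nobs: int


def estimate_propensity(
    data: pd.DataFrame, covariates: Sequence[str], treatment: str = "pension"
) -> PropensityFit:
    """Logit model of treatment on the covariates.

    Raises :class:`SeparationError` when the fitted probabilities are
    pinned at 0/1 (perfect separation), which makes matching degenerate.
    """
    t = data[treatment].to_numpy(dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("treatment has a single class; propensity model undefined")
    X = data[list(covariates)].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        bad = [c for c, s in zip(covariates, X.std(axis=0)) if s == 0]
        raise ValueError(f"constant covariates cannot enter the propensity model: {bad}")
    Xc = sm.add_constant(X)
    try:
        fit = sm.Logit(t, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise SeparationError(
            f"propensity model failed ({exc}); review the covariate set for "
            "variables that perfectly predict treatment"
        ) from exc
    p = np.asarray(fit.predict(Xc))
    eps = 1e-10
    if np.any(p <= eps) or np.any(p >= 1 - eps):
        raise SeparationError(
            "fitted propensities pinned at 0 or 1: the covariates separate "
            "treatment perfectly; review the covariate set"
        )
    names = ["const", *covariates]
    return PropensityFit(p, pd.Series(fit.params, index=names), tuple(covariates), t)


def standardized_mean_differences(
    data: pd.DataFrame, covariates: Sequence[str], treated_mask: np.ndarray
) -> pd.Series:
    """Per-covariate SMD = (mean_T - mean_C) / pooled SD."""
    out = {}
    for c in covariates:
        v = data[c].to_numpy(dtype=float)
        vt, vc = v[treated_mask], v[~treated_mask]
        pooled = np.sqrt(0.5 * (vt.var(ddof=1) + vc.var(ddof=1)))
        out[c] = (vt.mean() - vc.mean()) / pooled if pooled > 0 else 0.0
    return pd.Series(out)


def match(
    fit: PropensityFit,
    data: pd.DataFrame,
    caliper: float | None = None,
    ratio: int = 1,
    seed: int = 0,
) -> MatchedSample:
    """1:``ratio`` nearest-neighbour matching on the logit propensity.

    Without replacement; treated units are processed in descending
    propensity order (deterministic and conventional — high-propensity
    treated units face the thinnest control region, so they pick first).
    The default caliper is 0.2 SD of the logit propensity; pairs beyond
    it are dropped and reported as unmatched. Equidistant controls are
    tie-broken by a seeded draw.
    """
    p = np.clip(fit.propensity, 1e-12, 1 - 1e-12)
    logit = np.log(p / (1 - p))
    if caliper is None:
        caliper = 0.2 * logit.std(ddof=1)
    if caliper < 0:
        raise ValueError(f"caliper must be >= 0, got {caliper}")
    treated_idx = np.flatnonzero(fit.treatment == 1)
    control_idx = np.flatnonzero(fit.treatment == 0)
    order = treated_idx[np.argsort(-logit[treated_idx], kind="stable")]
    # sorted pool of available controls
    pool = control_idx[np.argsort(logit[control_idx], kind="stable")]
    pool_vals = logit[pool].copy()
    rng = np.random.default_rng(seed)

    pairs = []
    unmatched = 0
    for ti in order:
        target = logit[ti]
        got = 0
        for _ in range(ratio):
            if pool_vals.size == 0:
                break
            j = np.searchsorted(pool_vals, target)
            candidates = []
            if j < pool_vals.size:
                candidates.append((abs(pool_vals[j] - target), j))
            if j > 0:
                candidates.append((abs(pool_vals[j - 1] - target), j - 1))
            dmin = min(c[0] for c in candidates)
            best = [c[1] for c in candidates if c[0] == dmin]
            pick = best[0] if len(best) == 1 else int(rng.choice(best))
            if dmin > caliper:
                break
            pairs.append((int(ti), int(pool[pick]), float(dmin)))
            pool = np.delete(pool, pick)
            pool_vals = np.delete(pool_vals, pick)
            got += 1
        if got == 0:
            unmatched += 1
    if not pairs:
        raise ValueError(
            f"no matches found under caliper {caliper:.4g}; widen the caliper "
            "or review propensity overlap"
        )
    pairs_df = pd.DataFrame(pairs, columns=["treated", "control", "distance"])

    treated_mask = fit.treatment == 1
    smd_before = standardized_mean_differences(data, fit.covariate_names, treated_mask)
    m_idx = np.concatenate([pairs_df["treated"].to_numpy(), pairs_df["control"].to_numpy()])
    m_data = data.iloc[m_idx].reset_index(drop=True)
    m_treated = np.concatenate(
        [np.ones(len(pairs_df), dtype=bool), np.zeros(len(pairs_df), dtype=bool)]
    )
    smd_after = standardized_mean_differences(m_data, fit.covariate_names, m_treated)
    if unmatched:
        logger.info("%d treated units unmatched under caliper %.4g", unmatched, caliper)
    return MatchedSample(
        pairs_df, float(caliper), smd_before, smd_after,
        n_treated=int(treated_mask.sum()), n_unmatched_treated=int(unmatched),
    )


def matched_ols(
    sample: MatchedSample,
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    treatment: str = "pension",
) -> RegressionFit:
    """OLS of the outcome on treatment and covariates, matched rows only.

    Heteroskedasticity-robust (HC1) standard errors; the coefficients
    feed the concentration-index decomposition.
    """
    rows = data.iloc[sample.indices]
    y = rows[outcome].to_numpy(dtype=float)
    names = [treatment, *covariates]
    X = rows[names].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # identify a minimal set of columns beyond a full-rank prefix
        bad = []
        r = 1
        for k, name in enumerate(names, start=1):
            if np.linalg.matrix_rank(Xc[:, : k + 1]) == r:
                bad.append(name)
            else:
                r += 1
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(y, Xc).fit(cov_type="HC1")
    params = pd.Series(fit.params, index=["const", *names])
    ses = pd.Series(fit.bse, index=["const", *names])
    return RegressionFit(
        intercept=float(params["const"]),
        treatment_coef=float(params[treatment]),
        treatment_se=float(ses[treatment]),
        coefficients=params.drop("const"),
        robust_se=ses.drop("const"),
        residuals=np.asarray(fit.resid),
        nobs=int(fit.nobs),
    )
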