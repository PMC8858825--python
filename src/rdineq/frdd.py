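"""Fuzzy regression-discontinuity estimation at an eligibility cutoff.

Pension receipt jumps in probability — but not from 0 to 1 — when age
crosses the eligibility threshold (60), because periodic eligibility
reviews delay first payment. The causal effect of the benefit on health
for compliers at the cutoff (the LATE) is therefore identified by the
Wald ratio of two boundary discontinuities:

    LATE = [lim_{a↓60} E(Health|a) − lim_{a↑60} E(Health|a)]
         / [lim_{a↓60} P(Pension|a) − lim_{a↑60} P(Pension|a)]

Each boundary value is estimated by kernel-weighted local-linear
regression on its own side of the cutoff. The module provides

* the conventional point estimate with heteroskedasticity-robust
  (sandwich) standard errors,
* a bias-corrected estimate that subtracts the leading smoothing bias
  estimated from a local-quadratic pilot fit at a wider bandwidth, and
* robust inference that inflates the variance for the estimated bias —
  the conventional / bias-corrected / robust trio reported in applied
  RD tables,
* the Imbens–Kalyanaraman (IK) plug-in bandwidth selector,
* the validity battery: a McCrary-style density-manipulation test of
  the running variable, covariate smoothness tests, and placebo-cutoff
  tests,
* income-group heterogeneity (subgroup LATEs with per-group bandwidth).

Cutoff membership convention: the policy grants eligibility at 60, so
age >= cutoff belongs to the right (treated-eligible) side everywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

logger = logging.getLogger(__name__)

__all__ = [
    "KERNELS",
    "kernel_weight",
    "BandwidthSpec",
    "RDDataset",
    "RDDEstimate",
    "SharpRDResult",
    "DensityTestResult",
    "InsufficientDataError",
    "WeakFirstStageError",
    "local_linear_boundary_fit",
    "ik_bandwidth",
    "sharp_rd",
    "fuzzy_late",
    "heterogeneous_late",
    "density_manipulation_test",
    "covariate_smoothness_tests",
    "placebo_cutoff_tests",
    "rd_dataset_from_cohort",
]

# Weak-identification guard on the first-stage probability jump.
WEAK_FIRST_STAGE_THRESHOLD = 0.05


class InsufficientDataError(ValueError):
    """Too few usable observations for a local fit."""


class WeakFirstStageError(ValueError):
    """First-stage jump too close to zero for a Wald ratio."""


# ---------------------------------------------------------------------------
# Kernels and their boundary constants
# ---------------------------------------------------------------------------

KERNELS = {
    "triangular": lambda u: np.maximum(1.0 - np.abs(u), 0.0),
    "epanechnikov": lambda u: 0.75 * np.maximum(1.0 - u**2, 0.0) * (np.abs(u) <= 1),
    "uniform": lambda u: 0.5 * (np.abs(u) <= 1.0),
}


def kernel_weight(u, kernel: str = "triangular"):
    """Kernel weight at scaled distance ``u``; zero outside |u| <= 1."""
    try:
        k = KERNELS[kernel]
    except KeyError:
        raise ValueError(
            f"unknown kernel {kernel!r}; choose one of {sorted(KERNELS)}"
        ) from None
    return k(np.asarray(u, dtype=float))


@lru_cache(maxsize=None)
def _boundary_constants(kernel: str) -> tuple[float, float, float]:
    """(nu, V, C_K) for local-linear estimation at a boundary.

    With one-sided moments mu_j = ∫_0^1 u^j K(u) du, the equivalent
    boundary kernel is K*(u) = (mu_2 − mu_1 u) K(u) / (mu_0 mu_2 − mu_1²).
    ``nu`` is its second moment (the bias constant: leading bias of the
    intercept is (nu/2) h² m''), ``V`` its squared L2 norm (variance
    constant), and ``C_K = (V / nu²)^{1/5}`` the MSE-optimal bandwidth
    constant (3.4375 for the triangular kernel).
    """
    k = KERNELS[kernel]
    mu = [integrate.quad(lambda u, j=j: u**j * k(u), 0, 1)[0] for j in range(3)]
    den = mu[0] * mu[2] - mu[1] ** 2

    def kstar(u):
        return (mu[2] - mu[1] * u) * k(u) / den

    nu = integrate.quad(lambda u: u**2 * kstar(u), 0, 1)[0]
    V = integrate.quad(lambda u: kstar(u) ** 2, 0, 1)[0]
    ck = (V / nu**2) ** 0.2
    return nu, V, ck


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandwidthSpec:
    """Bandwidth choice for the local fits.

    ``method="ik"`` selects the main bandwidth by the IK plug-in rule
    (scaled by ``multiplier`` for robustness grids); ``method="manual"``
    uses ``h`` (and ``b``) as given. The pilot bandwidth ``b`` used for
    the bias-correction quadratic defaults to ``h * n^(2/35)``, which
    restores the slower optimal rate (n^(-1/7)) for curvature estimation
    from an h of order n^(-1/5).
    """

    method: str = "ik"
    h: float | None = None
    b: float | None = None
    multiplier: float = 1.0

    def __post_init__(self):
        if self.method not in ("ik", "manual"):
            raise ValueError(f"bandwidth method must be 'ik' or 'manual', got {self.method!r}")
        if self.method == "manual" and (self.h is None or self.h <= 0):
            raise ValueError("manual bandwidth requires h > 0")
        if self.h is not None and self.b is not None and self.b < self.h:
            raise ValueError(f"pilot bandwidth b={self.b} must be >= h={self.h}")
        if self.multiplier <= 0:
            raise ValueError(f"multiplier must be > 0, got {self.multiplier}")

    def resolve(self, y, x, cutoff, kernel) -> tuple[float, float]:
        if self.method == "manual":
            h = float(self.h) * self.multiplier
        else:
            h = ik_bandwidth(y, x, cutoff, kernel) * self.multiplier
        b = float(self.b) if self.b is not None else h * len(np.asarray(x)) ** (2.0 / 35.0)
        return h, max(b, h)


@dataclass
class RDDataset:
    """Inputs of one RD estimation problem."""

    running: np.ndarray
    outcome: np.ndarray
    treatment: np.ndarray
    cutoff: float
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.running = np.asarray(self.running, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.treatment = np.asarray(self.treatment, dtype=float)
        uniq = np.unique(self.treatment)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError("treatment must be binary 0/1")
        if not (self.running.min() < self.cutoff < self.running.max()):
            raise ValueError(
                "running variable must have support on both sides of the cutoff"
            )

    def subset(self, mask) -> "RDDataset":
        cov = self.covariates.loc[mask].reset_index(drop=True) if self.covariates is not None else None
        return RDDataset(
            self.running[mask], self.outcome[mask], self.treatment[mask], self.cutoff, cov
        )


def rd_dataset_from_cohort(
    cohort: pd.DataFrame,
    outcome: str,
    cutoff: float = 60.0,
    covariate_names: Sequence[str] = ("gender", "marriage", "job_type", "insured", "med_quality"),
) -> RDDataset:
    """Build an :class:`RDDataset` from a cohort table."""
    cov = cohort[list(covariate_names)].reset_index(drop=True) if covariate_names else None
    return RDDataset(
        cohort["age"].to_numpy(float),
        cohort[outcome].to_numpy(float),
        cohort["pension"].to_numpy(float),
        cutoff,
        cov,
    )


@dataclass(frozen=True)
class SharpRDResult:
    jump: float
    se: float
    p_value: float
    h: float
    n_effective: int


@dataclass(frozen=True)
class RDDEstimate:
    """Conventional / bias-corrected / robust trio for one fuzzy-RD fit."""

    conventional: tuple[float, float]  # (estimate, sandwich SE)
    bias_corrected: tuple[float, float]  # (estimate, conventional SE)
    robust: tuple[float, float]  # (bias-corrected estimate, robust SE)
    first_stage: tuple[float, float]
    h: float
    b: float
    kernel: str
    n_effective: int
    controls: bool = False

    def p_values(self) -> dict[str, float]:
        out = {}
        for name in ("conventional", "bias_corrected", "robust"):
            est, se = getattr(self, name)
            z = est / se if se > 0 else np.inf
            out[name] = 2 * stats.norm.sf(abs(z))
        return out


# ---------------------------------------------------------------------------
# Local polynomial boundary fits
# ---------------------------------------------------------------------------


def _side_mask(x: np.ndarray, cutoff: float, side: str) -> np.ndarray:
    if side == "right":
        return x >= cutoff  # eligibility starts at the cutoff itself
    if side == "left":
        return x < cutoff
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def _boundary_wls(Y, x, cutoff, side, h, kernel, order):
    """Kernel-weighted polynomial fit of each column of Y on one side.

    Returns (coefs[k, order+1], rowcov, n_eff) where rowcov[r] is the
    k-by-k sandwich covariance of the r-th coefficient across responses
    (diagonal = HC0 variances, off-diagonal = cross-response covariance).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))  # shape (k, n)
    mask = _side_mask(np.asarray(x, float), cutoff, side)
    d = np.asarray(x, float)[mask] - cutoff
    w = kernel_weight(d / h, kernel)
    keep = w > 0
    d, w = d[keep], w[keep]
    Ys = Y[:, mask][:, keep]
    n_eff = d.size
    if n_eff < order + 2:
        raise InsufficientDataError(
            f"only {n_eff} weighted observations on the {side} side at h={h:.4g}; "
            f"need at least {order + 2}"
        )
    X = np.vander(d, order + 1, increasing=True)
    XW = X.T * w
    A = XW @ X
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise InsufficientDataError(
            f"singular local design on the {side} side at h={h:.4g}"
        ) from exc
    B = Ainv @ XW  # (order+1, n_eff): coef = B @ y
    coefs = Ys @ B.T  # (k, order+1)
    resid = Ys - coefs @ X.T  # (k, n_eff)
    # rowcov[r][j, l] = sum_i B[r,i]^2 e_ji e_li  (HC0 sandwich, shared weights)
    B2 = B**2
    rowcov = np.einsum("ri,ji,li->rjl", B2, resid, resid)
    return coefs, rowcov, n_eff


def local_linear_boundary_fit(y, x, cutoff, side, h, kernel="triangular"):
    """Local-linear boundary value on one side of the cutoff.

    Returns ``(intercept, slope, var_intercept)`` where the intercept is
    the estimated conditional mean at the cutoff approached from
    ``side`` and the variance is the HC0 sandwich variance.
    """
    coefs, rowcov, _ = _boundary_wls(y, x, cutoff, side, h, kernel, order=1)
    return float(coefs[0, 0]), float(coefs[0, 1]), float(rowcov[0][0, 0])


# ---------------------------------------------------------------------------
# IK plug-in bandwidth
# ---------------------------------------------------------------------------


def ik_bandwidth(y, x, cutoff, kernel: str = "triangular") -> float:
    """Imbens–Kalyanaraman MSE-optimal bandwidth for the boundary jump.

    Plug-in steps (all constants named):

    1. Silverman pilot ``h1 = 1.84 sd(x) n^(-1/5)``; within ±h1 of the
       cutoff estimate the boundary conditional variances (s2 left/right)
       and the density ``f(c)``.
    2. Global cubic (with a level shift at the cutoff) estimates the
       third derivative; second-stage bandwidths
       ``h2± = 3.56 (s2 / (f(c) m3²))^(1/7) N±^(-1/7)``.
    3. One-sided quadratics within h2 give the curvatures m2±, with
       regularization terms ``r± = 2160 s2± / (N2± h2±⁴)`` guarding
       against noisy curvature estimates.
    4. ``h = C_K [ (s2l + s2r) / (f(c) ((m2r − m2l)² + rl + rr)) ]^(1/5)
       n^(-1/5)`` with the kernel-specific boundary constant C_K.

    Deterministic given the data; exactly equivariant under rescaling of
    the running variable. Degenerate pilot estimates trigger a fall-back
    to the Silverman rule with a logged warning.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = x.size
    n_left = int(np.sum(x < cutoff))
    n_right = n - n_left
    if min(n_left, n_right) < 50:
        raise InsufficientDataError(
            f"IK bandwidth needs >= 50 observations per side, got "
            f"left={n_left}, right={n_right}"
        )
    sd_x = x.std(ddof=1)
    h1 = 1.84 * sd_x * n ** (-0.2)

    def _fallback(reason: str) -> float:
        logger.warning("IK bandwidth degenerate (%s); using Silverman rule", reason)
        warnings.warn(f"IK bandwidth degenerate ({reason}); using Silverman rule")
        return h1

    left1 = (x >= cutoff - h1) & (x < cutoff)
    right1 = (x >= cutoff) & (x <= cutoff + h1)
    if left1.sum() < 2 or right1.sum() < 2:
        return _fallback("empty pilot window")
    s2l = y[left1].var(ddof=1)
    s2r = y[right1].var(ddof=1)
    if not np.isfinite(s2l + s2r) or s2l + s2r <= 0:
        return _fallback("zero pilot variance")
    f_c = (left1.sum() + right1.sum()) / (2.0 * n * h1)

    d = x - cutoff
    D = (d >= 0).astype(float)
    X3 = np.column_stack([np.ones(n), D, d, d**2, d**3])
    beta3, *_ = np.linalg.lstsq(X3, y, rcond=None)
    m3 = 6.0 * beta3[4]
    if m3 == 0 or not np.isfinite(m3):
        return _fallback("zero third-derivative estimate")
    s2_mid = 0.5 * (s2l + s2r)
    h2l = 3.56 * (s2_mid / (f_c * m3**2)) ** (1.0 / 7.0) * n_left ** (-1.0 / 7.0)
    h2r = 3.56 * (s2_mid / (f_c * m3**2)) ** (1.0 / 7.0) * n_right ** (-1.0 / 7.0)
    h2l = min(h2l, cutoff - x.min())
    h2r = min(h2r, x.max() - cutoff)

    def _curvature(side_mask, h2):
        dd = d[side_mask & (np.abs(d) <= h2)]
        yy = y[side_mask & (np.abs(d) <= h2)]
        if dd.size < 4:
            return None, dd.size
        Xq = np.column_stack([np.ones(dd.size), dd, dd**2])
        bq, *_ = np.linalg.lstsq(Xq, yy, rcond=None)
        return 2.0 * bq[2], dd.size

    m2l, n2l = _curvature(d < 0, h2l)
    m2r, n2r = _curvature(d >= 0, h2r)
    if m2l is None or m2r is None:
        return _fallback("too few points for curvature fits")
    rl = 2160.0 * s2l / (n2l * h2l**4)
    rr = 2160.0 * s2r / (n2r * h2r**4)
    _, _, ck = _boundary_constants(kernel)
    denom = f_c * ((m2r - m2l) ** 2 + rl + rr)
    if denom <= 0 or not np.isfinite(denom):
        return _fallback("degenerate regularized curvature")
    return float(ck * ((s2l + s2r) / denom) ** 0.2 * n ** (-0.2))


# ---------------------------------------------------------------------------
# Sharp and fuzzy estimators
# ---------------------------------------------------------------------------


def sharp_rd(y, x, cutoff, h=None, kernel: str = "triangular") -> SharpRDResult:
    """Boundary jump (right minus left intercept) of ``y`` at the cutoff.

    Used directly for the first stage and for covariate smoothness; the
    variance is the sum of the two one-sided HC0 intercept variances.
    ``h=None`` selects the IK bandwidth on ``y``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if h is None:
        h = ik_bandwidth(y, x, cutoff, kernel)
    al, _, vl = local_linear_boundary_fit(y, x, cutoff, "left", h, kernel)
    ar, _, vr = local_linear_boundary_fit(y, x, cutoff, "right", h, kernel)
    jump = ar - al
    se = np.sqrt(vl + vr)
    z = jump / se if se > 0 else np.inf
    n_eff = int(np.sum(np.abs((x - cutoff) / h) <= 1))
    return SharpRDResult(float(jump), float(se), float(2 * stats.norm.sf(abs(z))), float(h), n_eff)


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    Z1 = np.column_stack([np.ones(len(v)), Z])
    beta, *_ = np.linalg.lstsq(Z1, v, rcond=None)
    return v - Z1 @ beta + v.mean()


def _wald(jy, jt, vy, vt, cyt):
    tau = jy / jt
    var = (vy + tau**2 * vt - 2.0 * tau * cyt) / jt**2
    return tau, np.sqrt(max(var, 0.0))


def fuzzy_late(
    data: RDDataset,
    bw: BandwidthSpec | None = None,
    kernel: str = "triangular",
    controls: bool = False,
    controls_method: str = "residualize",
) -> RDDEstimate:
    """Fuzzy-RD LATE of treatment on outcome at the cutoff.

    Conventional: local-linear Wald ratio at bandwidth h with
    delta-method sandwich SE (including the outcome/treatment intercept
    covariance per side). Bias-corrected: both discontinuities are
    corrected by the leading kernel bias term ``(nu/2) h² (m2r − m2l)``
    with curvatures from local-quadratic pilot fits at bandwidth b.
    Robust: the bias-corrected point estimate with a variance that adds
    the (co)variance of the estimated bias terms.

    ``controls=True`` adjusts linearly for the dataset's covariates; the
    default residualizes outcome and treatment on them globally before
    the local fits, ``controls_method="local"`` instead includes them in
    each one-sided weighted fit.
    """
    bw = bw or BandwidthSpec()
    x, c = data.running, data.cutoff
    y, t = data.outcome, data.treatment

    extra = None
    if controls:
        if data.covariates is None or data.covariates.shape[1] == 0:
            raise ValueError("controls=True but the dataset has no covariates")
        Z = data.covariates.to_numpy(dtype=float)
        if controls_method == "residualize":
            y = _residualize(y, Z)
            t = _residualize(t, Z)
        elif controls_method == "local":
            extra = Z
        else:
            raise ValueError(f"unknown controls_method {controls_method!r}")

    h, b = bw.resolve(y, x, c, kernel)
    nu, _, _ = _boundary_constants(kernel)

    Y = np.vstack([y, t])
    if extra is None:
        fits = {
            side: _boundary_wls(Y, x, c, side, h, kernel, order=1)
            for side in ("left", "right")
        }
        jumps = fits["right"][0][:, 0] - fits["left"][0][:, 0]
        cov_int = fits["right"][1][0] + fits["left"][1][0]
    else:
        # covariates entered in the local fit: design [1, d, d^2.., Z]
        jumps = np.zeros(2)
        cov_int = np.zeros((2, 2))
        for sgn, side in ((1.0, "right"), (-1.0, "left")):
            mask = _side_mask(x, c, side)
            d = x[mask] - c
            w = kernel_weight(d / h, kernel)
            keep = w > 0
            d, w = d[keep], w[keep]
            Xd = np.column_stack([np.ones(d.size), d, extra[mask][keep]])
            XW = Xd.T * w
            Ainv = np.linalg.inv(XW @ Xd)
            B = Ainv @ XW
            Ys = Y[:, mask][:, keep]
            co = Ys @ B.T
            resid = Ys - co @ Xd.T
            jumps += sgn * co[:, 0]
            cov_int += np.einsum("i,ji,li->jl", B[0] ** 2, resid, resid)

    jy, jt = jumps
    if abs(jt) <= WEAK_FIRST_STAGE_THRESHOLD:
        raise WeakFirstStageError(
            f"first-stage jump {jt:.4f} is below the identification "
            f"threshold {WEAK_FIRST_STAGE_THRESHOLD}; the Wald ratio is unreliable"
        )
    vy, vt, cyt = cov_int[0, 0], cov_int[1, 1], cov_int[0, 1]
    tau_c, se_c = _wald(jy, jt, vy, vt, cyt)

    # Pilot quadratics at b for the bias terms.
    pfits = {
        side: _boundary_wls(Y, x, c, side, b, kernel, order=2)
        for side in ("left", "right")
    }
    m2 = {s: 2.0 * pfits[s][0][:, 2] for s in pfits}  # curvature per response
    bias = 0.5 * nu * h**2 * (m2["right"] - m2["left"])
    jy_bc, jt_bc = jumps - bias
    if abs(jt_bc) <= WEAK_FIRST_STAGE_THRESHOLD:
        jt_bc = jt  # curvature correction of the first stage is noise-dominated
    tau_bc = jy_bc / jt_bc

    # Robust variance: conventional sandwich plus variance of the bias
    # estimates (covariance of the quadratic coefficients, factor 4 for
    # the curvature m2 = 2 * coef2), evaluated at the corrected jumps.
    cov_bias = (0.5 * nu * h**2) ** 2 * 4.0 * (pfits["right"][1][2] + pfits["left"][1][2])
    cov_rob = cov_int + cov_bias
    _, se_rob = _wald(jy_bc, jt_bc, cov_rob[0, 0], cov_rob[1, 1], cov_rob[0, 1])

    se_first = float(np.sqrt(vt))
    n_eff = int(np.sum(np.abs((x - c) / h) <= 1))
    return RDDEstimate(
        conventional=(float(tau_c), float(se_c)),
        bias_corrected=(float(tau_bc), float(se_c)),
        robust=(float(tau_bc), float(se_rob)),
        first_stage=(float(jt), se_first),
        h=float(h),
        b=float(b),
        kernel=kernel,
        n_effective=n_eff,
        controls=bool(controls),
    )


def heterogeneous_late(
    data: RDDataset,
    income: np.ndarray,
    income_breaks: tuple[float, float] = (0.30, 0.70),
    kernel: str = "triangular",
    controls: bool = False,
) -> dict[str, dict]:
    """Per-income-group fuzzy LATEs (low / middle / high).

    Groups are formed at the given quantiles of per-capita income (30th
    and 70th percentiles by default); the bandwidth is re-selected
    within each group. A group whose estimation fails (too small, weak
    first stage) is flagged with the error message while the remaining
    groups are still returned.
    """
    income = np.asarray(income, dtype=float)
    q_lo, q_hi = np.quantile(income, income_breaks)
    masks = {
        "low": income <= q_lo,
        "middle": (income > q_lo) & (income <= q_hi),
        "high": income > q_hi,
    }
    out: dict[str, dict] = {}
    for name, mask in masks.items():
        entry: dict = {"n": int(mask.sum()), "estimate": None, "error": None}
        try:
            entry["estimate"] = fuzzy_late(
                data.subset(mask), BandwidthSpec(), kernel, controls=controls
            )
        except (InsufficientDataError, WeakFirstStageError, ValueError) as exc:
            entry["error"] = str(exc)
            logger.warning("income group %s skipped: %s", name, exc)
        out[name] = entry
    return out


# ---------------------------------------------------------------------------
# Validity battery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DensityTestResult:
    statistic: float
    p_value: float
    log_density_jump: float
    n_bins: int
    window: float


def density_manipulation_test(
    running, cutoff, n_bins: int = 40, window: float | None = None
) -> DensityTestResult:
    """McCrary-style manipulation test of the running-variable density.

    The running variable is binned into ``n_bins`` equal-width bins in a
    symmetric window around the cutoff; a line is fitted to the bin
    log-counts on each side (generalized least squares with the Poisson
    variance 1/count), and the jump of the fitted log-density at the
    cutoff is tested with a normal approximation. A significant jump
    indicates sorting of individuals across the eligibility threshold.
    """
    x = np.asarray(running, dtype=float)
    if x.size < 100:
        raise InsufficientDataError(
            f"density test needs at least 100 observations, got {x.size}"
        )
    if window is None:
        window = min(cutoff - x.min(), x.max() - cutoff)
    if window <= 0:
        raise ValueError("cutoff must be interior to the support of the running variable")
    half = n_bins // 2
    if half < 3:
        raise ValueError("n_bins must be at least 6")

    def _side_intercept(lo, hi, at):
        counts, edges = np.histogram(x, bins=half, range=(lo, hi))
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        if keep.sum() < 3:
            raise InsufficientDataError(
                "fewer than 3 populated bins on one side; increase the sample "
                "(>= 100 observations per side recommended) or reduce n_bins"
            )
        cc, cn = centers[keep], counts[keep].astype(float)
        X = np.column_stack([np.ones(cc.size), cc - at])
        W = cn  # inverse of Var(log N) ~ 1/N
        A = np.linalg.inv((X.T * W) @ X)
        beta = A @ (X.T * W) @ np.log(cn)
        return beta[0], A[0, 0]

    al, vl = _side_intercept(cutoff - window, cutoff, cutoff)
    ar, vr = _side_intercept(cutoff, cutoff + window, cutoff)
    jump = ar - al
    z = jump / np.sqrt(vl + vr)
    return DensityTestResult(
        float(z), float(2 * stats.norm.sf(abs(z))), float(jump), n_bins, float(window)
    )


def covariate_smoothness_tests(
    data: RDDataset, kernel: str = "triangular", h: float | None = None
) -> pd.DataFrame:
    """Sharp-RD jump of every covariate at the cutoff.

    Predetermined covariates must be smooth through the threshold; a
    discontinuity would indicate that something other than the benefit
    changes at the cutoff. Returns one row per covariate with the jump,
    its SE, the raw p-value and a Holm-adjusted p-value (the battery
    tests several covariates at once, so raw p-values overstate joint
    significance).
    """
    if data.covariates is None or data.covariates.shape[1] == 0:
        return pd.DataFrame(
            columns=["covariate", "jump", "se", "p_value", "p_holm", "h", "error"]
        )
    rows = []
    for name in data.covariates.columns:
        v = data.covariates[name].to_numpy(dtype=float)
        try:
            res = sharp_rd(v, data.running, data.cutoff, h=h, kernel=kernel)
            rows.append(
                dict(covariate=name, jump=res.jump, se=res.se, p_value=res.p_value,
                     h=res.h, error=None)
            )
        except (InsufficientDataError, ValueError) as exc:
            rows.append(
                dict(covariate=name, jump=np.nan, se=np.nan, p_value=np.nan,
                     h=np.nan, error=str(exc))
            )
    table = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests

    ok = table["p_value"].notna()
    table["p_holm"] = np.nan
    if ok.any():
        table.loc[ok, "p_holm"] = multipletests(
            table.loc[ok, "p_value"].to_numpy(), method="holm"
        )[1]
    return table[["covariate", "jump", "se", "p_value", "p_holm", "h", "error"]]


def placebo_cutoff_tests(
    data: RDDataset,
    placebo_cutoffs: Sequence[float],
    guard: float = 2.0,
    kernel: str = "triangular",
) -> pd.DataFrame:
    """Outcome-jump estimates at counterfeit cutoffs.

    Each placebo cutoff must lie inside the running-variable support and
    outside a guard window around the true cutoff. Estimation is
    restricted to the observations on the true cutoff's same side as the
    placebo point, so the genuine discontinuity cannot leak into the
    local window. If the treatment probability also jumps at the placebo
    point (it should not) a fuzzy ratio is reported, otherwise the sharp
    outcome jump.
    """
    x = data.running
    rows = []
    for c_star in placebo_cutoffs:
        if not (x.min() < c_star < x.max()):
            raise ValueError(
                f"placebo cutoff {c_star} outside the running-variable support "
                f"[{x.min():.3g}, {x.max():.3g}]"
            )
        if abs(c_star - data.cutoff) <= guard:
            raise ValueError(
                f"placebo cutoff {c_star} inside the guard window "
                f"±{guard} around the true cutoff {data.cutoff}"
            )
        side = x < data.cutoff if c_star < data.cutoff else x >= data.cutoff
        xs, ys, ts = x[side], data.outcome[side], data.treatment[side]
        cov = (data.covariates.loc[side].reset_index(drop=True)
               if data.covariates is not None else None)
        try:
            fs = sharp_rd(ts, xs, c_star, kernel=kernel)
            if abs(fs.jump) > WEAK_FIRST_STAGE_THRESHOLD:
                est = fuzzy_late(
                    RDDataset(xs, ys, ts, c_star, cov), BandwidthSpec(), kernel
                )
                jump, se = est.conventional
                design = "fuzzy"
                p = est.p_values()["conventional"]
                h = est.h
            else:
                res = sharp_rd(ys, xs, c_star, kernel=kernel)
                jump, se, p, h = res.jump, res.se, res.p_value, res.h
                design = "sharp"
            rows.append(dict(cutoff=c_star, design=design, estimate=jump, se=se,
                             p_value=p, h=h, error=None))
        except (InsufficientDataError, WeakFirstStageError) as exc:
            rows.append(dict(cutoff=c_star, design=None, estimate=np.nan, se=np.nan,
                             p_value=np.nan, h=np.nan, error=str(exc)))
    return pd.DataFrame(rows)
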