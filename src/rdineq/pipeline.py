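"""End-to-end analysis pipeline.

Orchestrates: simulate-or-load cohort → composite health index → fuzzy-RD
estimator grid and validity battery → income-group heterogeneity →
concentration index → PSM-corrected decomposition, producing a
machine-readable report whose sections mirror the applied tables
(estimator grid, income groups, decomposition) plus provenance.

Generator-truth columns (``latent_health``, ``true_late``) are stripped
from the cohort before any estimation; the pipeline can never peek at
the simulated ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import frdd, inequality, psm
from .health import composite_health
from .synthetic import (
    COHORT_COLUMNS,
    TRUTH_COLUMNS,
    SyntheticConfig,
    generate_cohort,
    read_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "render_tables", "significance_stars"]

COVARIATE_NAMES = ("gender", "marriage", "job_type", "insured", "med_quality")
# age joins the propensity model and the decomposition regression (it drives
# both pension receipt and health) but not the RD smoothness battery, where
# it is the running variable itself
PSM_COVARIATE_NAMES = ("age", *COVARIATE_NAMES)


def significance_stars(p: float) -> str:
    """Star convention of the emulated tables: ***p<0.01, **p<0.05, *p<0.1."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run.

    ``input_path`` loads a cohort CSV; otherwise a cohort is simulated
    from ``synthetic`` (defaulting to the generator's defaults with the
    run's seed). The estimator grid mirrors the applied robustness
    table: triangular kernel without/with controls at the selected
    bandwidth, halved and doubled bandwidths, then the alternative
    kernels with controls.
    """

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    cutoff: float = 60.0
    kernels: tuple[str, ...] = ("triangular", "epanechnikov", "uniform")
    bandwidth_multipliers: tuple[float, ...] = (0.5, 1.0, 2.0)
    income_breaks: tuple[float, float] = (0.30, 0.70)
    ci_shift: str = "auto"
    denominator_policy: str = "total"
    placebo_cutoffs: tuple[float, ...] = (55.0, 65.0)
    psm_caliper: float | None = None
    psm_ratio: int = 1
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        for k in self.kernels:
            if k not in frdd.KERNELS:
                raise ValueError(f"unknown kernel {k!r}")
        if any(m <= 0 for m in self.bandwidth_multipliers):
            raise ValueError("bandwidth multipliers must be > 0")
        lo, hi = self.income_breaks
        if not 0 < lo < hi < 1:
            raise ValueError(f"income_breaks must satisfy 0 < lo < hi < 1, got {self.income_breaks}")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        if self.synthetic is not None:
            payload["synthetic"] = self.synthetic.to_dict()
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig.from_dict(raw["synthetic"])
        for key in ("kernels", "bandwidth_multipliers", "income_breaks", "placebo_cutoffs"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown run-config fields: {sorted(unknown)}")
        return cls(**raw)


def _load_cohort(config: RunConfig) -> pd.DataFrame:
    if config.input_path is not None:
        cohort = read_cohort(config.input_path)
    else:
        syn = config.synthetic or SyntheticConfig(seed=config.seed)
        if config.synthetic is None:
            logger.info("no input path given; simulating the default cohort")
        cohort = generate_cohort(syn)
    # the analysis must never see generator truth
    return cohort[[c for c in COHORT_COLUMNS if c in cohort.columns]].copy()


def _estimate_to_dict(est: frdd.RDDEstimate) -> dict:
    p = est.p_values()
    return {
        "conventional": {"estimate": est.conventional[0], "se": est.conventional[1],
                         "p": p["conventional"], "stars": significance_stars(p["conventional"])},
        "bias_corrected": {"estimate": est.bias_corrected[0], "se": est.bias_corrected[1],
                           "p": p["bias_corrected"], "stars": significance_stars(p["bias_corrected"])},
        "robust": {"estimate": est.robust[0], "se": est.robust[1],
                   "p": p["robust"], "stars": significance_stars(p["robust"])},
        "first_stage": {"estimate": est.first_stage[0], "se": est.first_stage[1]},
        "h": est.h, "b": est.b, "kernel": est.kernel,
        "n_effective": est.n_effective, "controls": est.controls,
    }


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole pipeline and return the report as a nested dict.

    Deterministic given the config and seed (the provenance block's
    timestamp and elapsed times are the only non-reproducible fields).
    Validity-battery failures are recorded as warnings in the report;
    estimation failures abort.
    """
    config.validate()
    t0 = time.time()
    warnings_log: list[str] = []

    cohort = _load_cohort(config)
    cohort["health"] = composite_health(cohort["self_health"], cohort["other_health"])
    data = frdd.rd_dataset_from_cohort(cohort, "health", config.cutoff, COVARIATE_NAMES)
    income = np.exp(cohort["log_income"].to_numpy())

    # --- estimator grid (robustness table) -------------------------------
    grid: list[dict] = []
    base_kernel = config.kernels[0]
    for controls in (False, True):
        est = frdd.fuzzy_late(data, frdd.BandwidthSpec(), base_kernel, controls=controls)
        grid.append({"column": f"{base_kernel}/x1.0/controls={'YES' if controls else 'NO'}",
                     **_estimate_to_dict(est)})
    for mult in config.bandwidth_multipliers:
        if mult == 1.0:
            continue
        est = frdd.fuzzy_late(data, frdd.BandwidthSpec(multiplier=mult), base_kernel, controls=True)
        grid.append({"column": f"{base_kernel}/x{mult}/controls=YES", **_estimate_to_dict(est)})
    for kernel in config.kernels[1:]:
        est = frdd.fuzzy_late(data, frdd.BandwidthSpec(), kernel, controls=True)
        grid.append({"column": f"{kernel}/x1.0/controls=YES", **_estimate_to_dict(est)})

    # --- validity battery (failures warn, never abort) -------------------
    battery: dict = {}
    try:
        dens = frdd.density_manipulation_test(data.running, config.cutoff)
        battery["density_test"] = dataclasses.asdict(dens)
    except (frdd.InsufficientDataError, ValueError) as exc:
        warnings_log.append(f"density test failed: {exc}")
    try:
        battery["covariate_smoothness"] = frdd.covariate_smoothness_tests(
            data, base_kernel
        ).to_dict(orient="records")
    except Exception as exc:  # battery must not abort the run
        warnings_log.append(f"covariate smoothness battery failed: {exc}")
    try:
        battery["placebo_cutoffs"] = frdd.placebo_cutoff_tests(
            data, config.placebo_cutoffs, kernel=base_kernel
        ).to_dict(orient="records")
    except (frdd.InsufficientDataError, ValueError) as exc:
        warnings_log.append(f"placebo tests failed: {exc}")

    # --- heterogeneity by income group -----------------------------------
    groups = frdd.heterogeneous_late(data, income, config.income_breaks, base_kernel,
                                     controls=True)
    table3 = {
        name: {"n": g["n"],
               **({"error": g["error"]} if g["estimate"] is None
                  else _estimate_to_dict(g["estimate"]))}
        for name, g in groups.items()
    }
    for name, g in groups.items():
        if g["error"]:
            warnings_log.append(f"income group {name}: {g['error']}")

    # --- concentration index ---------------------------------------------
    # the inequality stage runs on the pension-eligible elderly (age >=
    # cutoff), the survey's descriptive sample; below the cutoff nobody is
    # treated, so age would also separate the propensity model there
    elderly = cohort[cohort["age"] >= config.cutoff].reset_index(drop=True)
    eld_income = np.exp(elderly["log_income"].to_numpy())
    ci_res = inequality.concentration_index(elderly["health"], eld_income, config.ci_shift)
    curve = inequality.concentration_curve(elderly["health"], eld_income, config.ci_shift)
    # curve points for export, thinned to at most 500 rows
    step = max(1, len(curve) // 500)
    curve_points = curve[::step].tolist()
    if not np.allclose(curve[-1], [1.0, 1.0]):
        curve_points.append(curve[-1].tolist())

    # --- PSM-corrected decomposition -------------------------------------
    flat = elderly
    reg_factors = ["pension", *PSM_COVARIATE_NAMES, "log_income"]
    psm_info: dict
    try:
        pfit = psm.estimate_propensity(flat, PSM_COVARIATE_NAMES)
        matched = psm.match(pfit, flat, caliper=config.psm_caliper,
                            ratio=config.psm_ratio, seed=config.seed)
        ols = psm.matched_ols(matched, flat, "health",
                              [*PSM_COVARIATE_NAMES, "log_income"])
        m_rows = flat.iloc[matched.indices].reset_index(drop=True)
        psm_info = {
            "caliper": matched.caliper,
            "n_pairs": len(matched.pairs),
            "n_unmatched_treated": matched.n_unmatched_treated,
            "smd_before": matched.smd_before.to_dict(),
            "smd_after": matched.smd_after.to_dict(),
        }
    except (ValueError, psm.SeparationError) as exc:
        # e.g. a sharp design leaves no untreated elderly to match against
        warnings_log.append(f"PSM skipped, decomposition on the unmatched sample: {exc}")
        import statsmodels.api as sm

        names = [*PSM_COVARIATE_NAMES, "log_income"]
        X = sm.add_constant(flat[["pension", *names]].to_numpy(dtype=float))
        can_estimate_pension = flat["pension"].nunique() > 1
        if not can_estimate_pension:
            X = sm.add_constant(flat[names].to_numpy(dtype=float))
        fit = sm.OLS(flat["health"].to_numpy(), X).fit(cov_type="HC1")
        cols = (["pension", *names] if can_estimate_pension else names)
        params = pd.Series(fit.params[1:], index=cols)
        ols = psm.RegressionFit(
            intercept=float(fit.params[0]),
            treatment_coef=float(params.get("pension", np.nan)),
            treatment_se=float("nan"),
            coefficients=params,
            robust_se=pd.Series(fit.bse[1:], index=cols),
            residuals=np.asarray(fit.resid),
            nobs=int(fit.nobs),
        )
        m_rows = flat
        reg_factors = ["pension", *names] if can_estimate_pension else list(names)
        psm_info = {"skipped": str(exc)}
    decomp = inequality.decompose_ci(
        m_rows[reg_factors], ols.coefficients.to_dict(),
        np.exp(m_rows["log_income"].to_numpy()), m_rows["health"].to_numpy(),
        intercept=ols.intercept, shift=config.ci_shift,
        denominator_policy=config.denominator_policy,
    )

    report = {
        "table2_grid": grid,
        "table3_groups": table3,
        "validity_battery": battery,
        "ci_result": {
            "ci": ci_res.ci, "health_mean": ci_res.health_mean,
            "shift": ci_res.shift, "note": ci_res.health_sign_note,
            "curve_points": curve_points,
        },
        "decomposition": {
            "table": decomp.to_dict(orient="records"),
            "denominator": decomp.attrs["denominator"],
            "total_ci": decomp.attrs["total_ci"],
            "health_mean": decomp.attrs["health_mean"],
            "shift": decomp.attrs["shift"],
            "psm": psm_info,
        },
        "warnings": warnings_log,
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n": int(len(cohort)),
            "versions": _versions(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "elapsed_s": round(time.time() - t0, 3),
        },
    }
    return report


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "rdineq": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


_NONDETERMINISTIC = ("timestamp", "elapsed_s")


def report_fingerprint(report: Mapping) -> str:
    """Hash of the report excluding timestamps, for reproducibility checks."""
    clean = json.loads(json.dumps(report))
    for key in _NONDETERMINISTIC:
        clean.get("provenance", {}).pop(key, None)
    return hashlib.sha256(json.dumps(clean, sort_keys=True).encode()).hexdigest()


def render_tables(report: Mapping, output_dir, formats: Sequence[str] = ("csv", "json")) -> list[Path]:
    """Write CSV/JSON renderings of a report's sections.

    Refuses malformed reports, listing the missing sections.
    """
    required = ["table2_grid", "table3_groups", "ci_result", "decomposition"]
    missing = [k for k in required if k not in report]
    if missing:
        raise ValueError(f"report is missing sections: {missing}")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "json" in formats:
        path = out / "report.json"
        path.write_text(json.dumps(report, indent=2, default=_json_default))
        written.append(path)
    if "csv" in formats:
        grid_rows = []
        for col in report["table2_grid"]:
            for row_name in ("conventional", "bias_corrected", "robust"):
                r = col[row_name]
                grid_rows.append(
                    dict(column=col["column"], estimator=row_name,
                         estimate=r["estimate"], se=r["se"], p=r["p"],
                         stars=r["stars"], h=col["h"], kernel=col["kernel"],
                         n_effective=col["n_effective"]))
        p = out / "table2_grid.csv"
        pd.DataFrame(grid_rows).to_csv(p, index=False)
        written.append(p)

        g_rows = []
        for name, g in report["table3_groups"].items():
            if "error" in g and "conventional" not in g:
                g_rows.append(dict(group=name, n=g["n"], error=g["error"]))
            else:
                for row_name in ("conventional", "bias_corrected", "robust"):
                    r = g[row_name]
                    g_rows.append(dict(group=name, n=g["n"], estimator=row_name,
                                       estimate=r["estimate"], se=r["se"],
                                       p=r["p"], stars=r["stars"]))
        p = out / "table3_groups.csv"
        pd.DataFrame(g_rows).to_csv(p, index=False)
        written.append(p)

        p = out / "decomposition.csv"
        pd.DataFrame(report["decomposition"]["table"]).to_csv(p, index=False)
        written.append(p)

        p = out / "concentration_curve.csv"
        pd.DataFrame(report["ci_result"]["curve_points"],
                     columns=["cum_population_share", "cum_health_share"]).to_csv(p, index=False)
        written.append(p)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
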