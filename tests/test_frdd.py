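"""Fuzzy-RDD estimator, IK bandwidth, and the validity battery."""

import numpy as np
import pytest

from rdineq.frdd import (
    BandwidthSpec,
    InsufficientDataError,
    RDDataset,
    WeakFirstStageError,
    covariate_smoothness_tests,
    density_manipulation_test,
    fuzzy_late,
    heterogeneous_late,
    ik_bandwidth,
    kernel_weight,
    local_linear_boundary_fit,
    placebo_cutoff_tests,
    rd_dataset_from_cohort,
    sharp_rd,
)
from rdineq.synthetic import SyntheticConfig, generate_cohort

ALL_KERNELS = ["triangular", "epanechnikov", "uniform"]


# --- kernels ---------------------------------------------------------------


@pytest.mark.parametrize(
    "u, kernel, expected",
    [
        (0.0, "triangular", 1.0),
        (0.0, "epanechnikov", 0.75),
        (0.0, "uniform", 0.5),
        (0.5, "triangular", 0.5),
        (1.5, "triangular", 0.0),
        (1.5, "epanechnikov", 0.0),
        (1.5, "uniform", 0.0),
        (-0.5, "uniform", 0.5),
    ],
)
def test_kernel_weights(u, kernel, expected):
    assert kernel_weight(u, kernel) == pytest.approx(expected)


def test_unknown_kernel_rejected():
    with pytest.raises(ValueError, match="unknown kernel"):
        kernel_weight(0.0, "gaussian")


# --- local linear boundary fits -------------------------------------------


@pytest.mark.parametrize("kernel", ALL_KERNELS)
@pytest.mark.parametrize("h", [0.5, 2.0, 10.0])
def test_exact_on_linear_data(kernel, h, rng):
    x = rng.uniform(-5, 5, 300)
    y = 2.0 + 0.7 * x
    a, s, _ = local_linear_boundary_fit(y, x, 0.0, "left", h, kernel)
    assert a == pytest.approx(2.0, abs=1e-9)
    assert s == pytest.approx(0.7, abs=1e-9)


def test_constant_outcome(rng):
    x = rng.uniform(0, 3, 100)
    a, s, v = local_linear_boundary_fit(np.full(100, 4.2), x, 0.0, "right", 1.0)
    assert a == pytest.approx(4.2)
    assert s == pytest.approx(0.0, abs=1e-10)


def test_quadratic_bias_vanishes_with_h(rng):
    x = rng.uniform(0, 5, 200_000)
    y = x**2  # true boundary value 0
    errs = [
        abs(local_linear_boundary_fit(y, x, 0.0, "right", h)[0]) for h in (2.0, 0.5)
    ]
    assert errs[1] < errs[0] / 4  # O(h^2) bias


def test_insufficient_data_error_names_side():
    x = np.array([-1.0, -2.0, 1.0, 2.0, 3.0])
    with pytest.raises(InsufficientDataError, match="left"):
        local_linear_boundary_fit(np.ones(5), x, 0.0, "left", 0.1)


# --- IK bandwidth ----------------------------------------------------------


def _curved_dgp(r, n):
    x = r.uniform(-1, 1, n)
    y = (
        0.4 * (x >= 0)
        + np.where(x >= 0, 1.5 * x**2, -1.0 * x**2)
        + 0.5 * x
        + r.normal(0, 0.3, n)
    )
    return y, x


def test_scale_equivariance_exact(rng):
    y, x = _curved_dgp(rng, 2000)
    h = ik_bandwidth(y, x, 0.0)
    for c in (0.1, 7.3, 250.0):
        assert ik_bandwidth(y, c * x, 0.0) == pytest.approx(c * h, rel=1e-7)


def test_rate_n_to_the_minus_fifth():
    ratios = []
    for i in range(60):
        r = np.random.default_rng(500 + i)
        h_small = ik_bandwidth(*_curved_dgp(r, 400), 0.0)
        h_big = ik_bandwidth(*_curved_dgp(r, 12_800), 0.0)
        ratios.append(h_small / h_big)
    assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)


def test_close_to_mse_oracle():
    """IK h within a factor 1.5 of the brute-force MSE minimizer."""
    n = 2000
    grid = np.geomspace(0.05, 1.0, 12)
    reps = 60
    jumps = np.zeros((len(grid), reps))
    hs = []
    for rep in range(reps):
        r = np.random.default_rng(900 + rep)
        y, x = _curved_dgp(r, n)
        hs.append(ik_bandwidth(y, x, 0.0))
        for gi, h in enumerate(grid):
            jumps[gi, rep] = sharp_rd(y, x, 0.0, h=h).jump
    mse = ((jumps - 0.4) ** 2).mean(axis=1)
    h_oracle = grid[np.argmin(mse)]
    h_ik = np.mean(hs)
    assert h_oracle / 1.5 <= h_ik <= h_oracle * 1.5


def test_too_few_observations_per_side():
    r = np.random.default_rng(0)
    x = np.concatenate([r.uniform(-1, 0, 30), r.uniform(0, 1, 200)])
    with pytest.raises(InsufficientDataError, match="50"):
        ik_bandwidth(np.zeros(230), x, 0.0)


def test_degenerate_variance_falls_back_with_warning(rng):
    x = rng.uniform(-1, 1, 300)
    with pytest.warns(UserWarning, match="Silverman"):
        h = ik_bandwidth(np.zeros(300), x, 0.0)
    assert h > 0


# --- sharp RD --------------------------------------------------------------


def test_null_jump_on_smooth_outcome(rng):
    x = rng.uniform(-2, 2, 40_000)
    y = np.sin(x) + rng.normal(0, 0.2, 40_000)
    res = sharp_rd(y, x, 0.0)
    assert abs(res.jump) < 3 * res.se


def test_sharp_design_treatment_jump_is_one(rng):
    x = rng.uniform(40, 80, 5000)
    t = (x >= 60).astype(float)
    res = sharp_rd(t, x, 60.0, h=5.0)
    assert res.jump == pytest.approx(1.0, abs=1e-9)


def test_first_stage_jump_matches_config(default_cohort):
    res = sharp_rd(
        default_cohort["pension"].to_numpy(float),
        default_cohort["age"].to_numpy(),
        60.0,
    )
    assert res.jump == pytest.approx(0.65, abs=3 * res.se)


def test_right_side_inclusion_at_the_cutoff():
    """An observation exactly at the cutoff belongs to the right side."""
    x = np.array([-3.0, -2.0, -1.0, -0.5, 0.0, 1.0, 2.0, 3.0])
    y = np.where(x >= 0, 10.0, 0.0)
    res = sharp_rd(y, x, 0.0, h=10.0)
    assert res.jump == pytest.approx(10.0, abs=1e-9)


# --- fuzzy LATE ------------------------------------------------------------


def _piecewise_constant_dataset(rng, n=4000):
    """Outcome jump 0.6 and first-stage jump 0.5 by construction."""
    x = rng.uniform(-1, 1, n)
    right = x >= 0
    t = (rng.uniform(size=n) < np.where(right, 0.75, 0.25)).astype(float)
    y = 0.6 * right + rng.normal(0, 1e-8, n)
    return RDDataset(x, y, t, 0.0)


def test_wald_ratio_definition(rng):
    data = _piecewise_constant_dataset(rng)
    est = fuzzy_late(data, BandwidthSpec(method="manual", h=1.0))
    # outcome jump 0.6 / first-stage jump 0.5 = 1.2, up to first-stage noise
    assert est.conventional[0] == pytest.approx(1.2, abs=0.15)
    fs = sharp_rd(data.treatment, data.running, 0.0, h=1.0)
    jy = sharp_rd(data.outcome, data.running, 0.0, h=1.0)
    assert est.conventional[0] == pytest.approx(jy.jump / fs.jump, rel=1e-9)


def test_sharp_design_reduces_to_sharp_rd():
    cfg = SyntheticConfig(n=8000, first_stage_jump=1.0, takeup_lambda=1e9, seed=6)
    c = generate_cohort(cfg)
    data = rd_dataset_from_cohort(c, "latent_health")
    est = fuzzy_late(data, BandwidthSpec(method="manual", h=4.0))
    out = sharp_rd(data.outcome, data.running, 60.0, h=4.0)
    assert est.conventional[0] == pytest.approx(out.jump, rel=1e-9)
    assert est.first_stage[0] == pytest.approx(1.0, abs=1e-9)


def test_weak_first_stage_error_names_jump(rng):
    x = rng.uniform(-1, 1, 2000)
    t = (rng.uniform(size=2000) < 0.5).astype(float)  # no jump anywhere
    y = rng.normal(size=2000)
    with pytest.raises(WeakFirstStageError, match="first-stage jump"):
        fuzzy_late(RDDataset(x, y, t, 0.0), BandwidthSpec(method="manual", h=1.0))


def test_kernels_agree_within_mc_error(homogeneous_cohort):
    data = rd_dataset_from_cohort(homogeneous_cohort, "latent_health")
    ests = {
        k: fuzzy_late(data, BandwidthSpec(), kernel=k).conventional
        for k in ALL_KERNELS
    }
    vals = [v[0] for v in ests.values()]
    ses = [v[1] for v in ests.values()]
    assert max(vals) - min(vals) < 2 * max(ses)


def test_bandwidth_grid_coherence(homogeneous_cohort):
    """Halved/doubled bandwidths give estimates consistent with the base one."""
    data = rd_dataset_from_cohort(homogeneous_cohort, "latent_health")
    base = fuzzy_late(data, BandwidthSpec(multiplier=1.0))
    half = fuzzy_late(data, BandwidthSpec(multiplier=0.5))
    double = fuzzy_late(data, BandwidthSpec(multiplier=2.0))
    for other in (half, double):
        diff = abs(other.conventional[0] - base.conventional[0])
        joint_se = np.hypot(other.conventional[1], base.conventional[1])
        assert diff < 3 * joint_se
    assert half.h == pytest.approx(base.h / 2)
    assert double.h == pytest.approx(base.h * 2)


def test_controls_leave_estimate_close(homogeneous_cohort):
    data = rd_dataset_from_cohort(homogeneous_cohort, "latent_health")
    plain = fuzzy_late(data, controls=False)
    adj = fuzzy_late(data, controls=True)
    local = fuzzy_late(data, controls=True, controls_method="local")
    for est in (adj, local):
        assert est.conventional[0] == pytest.approx(
            plain.conventional[0], abs=3 * plain.conventional[1]
        )


# --- heterogeneity ---------------------------------------------------------


def test_group_sizes_follow_quantile_split(default_cohort):
    data = rd_dataset_from_cohort(default_cohort, "latent_health")
    groups = heterogeneous_late(data, np.exp(default_cohort["log_income"]))
    sizes = {k: v["n"] for k, v in groups.items()}
    assert sizes == {"low": 3000, "middle": 4000, "high": 3000}


def test_homogeneous_effect_groups_agree(homogeneous_cohort):
    data = rd_dataset_from_cohort(homogeneous_cohort, "latent_health")
    groups = heterogeneous_late(data, np.exp(homogeneous_cohort["log_income"]))
    ests = [g["estimate"].conventional for g in groups.values() if g["estimate"]]
    assert len(ests) == 3
    spread = max(e[0] for e in ests) - min(e[0] for e in ests)
    assert spread < 3 * np.hypot(*sorted(e[1] for e in ests)[-2:])


def test_small_group_flagged_others_returned(default_cohort):
    data = rd_dataset_from_cohort(default_cohort, "latent_health")
    income = np.exp(default_cohort["log_income"].to_numpy())
    groups = heterogeneous_late(data, income, income_breaks=(0.002, 0.5))
    assert groups["low"]["estimate"] is None and groups["low"]["error"]
    assert groups["middle"]["estimate"] is not None
    assert groups["high"]["estimate"] is not None


# --- validity battery ------------------------------------------------------


def test_density_test_contract_small_n():
    with pytest.raises(InsufficientDataError, match="100"):
        density_manipulation_test(np.linspace(0, 1, 10), 0.5)


def test_density_test_detects_mass_jump(rng):
    n_left = rng.binomial(5000, 15 / (15 + 2 * 35))
    x = np.concatenate(
        [rng.uniform(45, 60, n_left), rng.uniform(60, 95, 5000 - n_left)]
    )
    res = density_manipulation_test(x, 60.0)
    assert res.p_value < 0.01
    assert res.log_density_jump == pytest.approx(np.log(2), abs=0.25)


def test_density_test_accepts_smooth_density():
    rejections = 0
    for seed in range(20):
        x = np.random.default_rng(seed).uniform(45, 95, 20_000)
        rejections += density_manipulation_test(x, 60.0).p_value < 0.05
    assert rejections <= 4  # ~5% nominal size


def test_covariate_with_jump_is_flagged(default_cohort, rng):
    data = rd_dataset_from_cohort(default_cohort, "latent_health")
    jumped = data.covariates.copy()
    jumped["constructed"] = (data.running >= 60) * 1.0 + rng.normal(
        0, 0.3, len(data.running)
    )
    data = RDDataset(data.running, data.outcome, data.treatment, 60.0, jumped)
    table = covariate_smoothness_tests(data).set_index("covariate")
    assert table.loc["constructed", "p_holm"] < 0.01
    assert (table.drop(index="constructed")["p_value"] > 0.001).all()


def test_empty_covariate_set_gives_empty_table(default_cohort):
    data = rd_dataset_from_cohort(default_cohort, "latent_health", covariate_names=())
    assert covariate_smoothness_tests(data).empty


def test_placebo_cutoffs_quiet_but_true_cutoff_significant(default_cohort):
    data = rd_dataset_from_cohort(default_cohort, "latent_health")
    table = placebo_cutoff_tests(data, [53.0, 68.0])
    assert (table["error"].isna()).all()
    # sanity inversion: the genuine cutoff shows a strong effect
    true_effect = fuzzy_late(data)
    assert true_effect.p_values()["robust"] < 0.01


def test_placebo_cutoff_outside_support_rejected(default_cohort):
    data = rd_dataset_from_cohort(default_cohort, "latent_health")
    with pytest.raises(ValueError, match="support"):
        placebo_cutoff_tests(data, [120.0])


def test_placebo_cutoff_inside_guard_window_rejected(default_cohort):
    data = rd_dataset_from_cohort(default_cohort, "latent_health")
    with pytest.raises(ValueError, match="guard"):
        placebo_cutoff_tests(data, [60.5])
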