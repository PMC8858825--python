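"""Concentration index, curve, and decomposition: identities and examples."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rdineq.inequality import (
    calibrated_contribution_rates,
    ci_from_curve,
    concentration_curve,
    concentration_index,
    decompose_ci,
    decomposition_recovery_check,
    fractional_rank,
)

# --- fractional ranks ------------------------------------------------------


def test_rank_formula():
    assert fractional_rank([10, 20, 30, 40]) == pytest.approx(
        [0.125, 0.375, 0.625, 0.875]
    )


def test_all_equal_incomes_rank_half():
    assert fractional_rank([7, 7, 7]) == pytest.approx([0.5, 0.5, 0.5])


def test_tied_ranks_get_mean_position():
    # positional ranks 1,2 share mean 1.5 -> (1.5 - 0.5)/3 = 1/3
    assert fractional_rank([5, 5, 9]) == pytest.approx([1 / 3, 1 / 3, 5 / 6])


def test_rank_mean_is_exactly_half(rng):
    v = rng.integers(0, 5, 1000).astype(float)  # heavy ties
    assert fractional_rank(v).mean() == pytest.approx(0.5, abs=1e-14)


# --- concentration index ---------------------------------------------------


def test_constant_health_no_inequality(rng):
    res = concentration_index(np.full(50, 3.0), rng.normal(size=50))
    assert res.ci == pytest.approx(0.0, abs=1e-14)


def test_hand_computed_three_point_example():
    # incomes (1,2,3), health (1,2,3):
    # (1/3)[(1/2)(-2/3) + 0 + (3/2)(2/3)] = 2/9
    res = concentration_index([1, 2, 3], [1, 2, 3], shift="none")
    assert res.ci == pytest.approx(2 / 9, abs=1e-15)


def test_health_equal_rank_limit_one_third(rng):
    y = rng.uniform(0, 1, 10**6)
    r = fractional_rank(y)
    res = concentration_index(r, y, shift="none")
    assert res.ci == pytest.approx(1 / 3, abs=1e-3)


@given(
    h=hnp.arrays(np.float64, 40, elements=st.floats(0.1, 100)),
    y=hnp.arrays(np.float64, 40, elements=st.floats(-50, 50)),
)
def test_covariance_identity_holds_everywhere(h, y):
    res = concentration_index(h, y, shift="none")
    r = fractional_rank(y)
    oracle = 2 * (np.mean(h * r) - h.mean() * r.mean()) / h.mean()
    assert res.ci == pytest.approx(oracle, abs=1e-12)
    assert abs(res.ci) <= 1 + 1e-12  # non-negative health


def test_scale_invariance_translation_sensitivity(rng):
    h = rng.uniform(1, 5, 300)
    y = rng.normal(size=300)
    base = concentration_index(h, y, shift="none").ci
    assert concentration_index(7.7 * h, y, shift="none").ci == pytest.approx(
        base, abs=1e-12
    )
    shifted = concentration_index(h + 10.0, y, shift="none").ci
    assert shifted != pytest.approx(base, abs=1e-6)  # CI is not translation invariant


def test_rank_only_dependence(rng):
    h = rng.uniform(1, 5, 200)
    y = rng.normal(size=200)
    base = concentration_index(h, y, shift="none").ci
    perm = rng.permutation(200)
    joint = concentration_index(h[perm], y[perm], shift="none").ci
    assert joint == pytest.approx(base, abs=1e-12)
    broken = concentration_index(h, y[perm], shift="none").ci
    assert broken != pytest.approx(base, abs=1e-6)


def test_zero_mean_health_is_an_error(rng):
    h = np.array([-1.0, 1.0, -2.0, 2.0])
    with pytest.raises(ValueError, match="mean"):
        concentration_index(h, [1, 2, 3, 4], shift="none")


def test_auto_shift_recorded_and_makes_health_positive():
    res = concentration_index([-2.0, 0.0, 2.0, 4.0], [1, 2, 3, 4], shift="auto")
    assert res.shift == pytest.approx(3.0)  # 1 - min
    assert res.ci > 0


# --- concentration curve ---------------------------------------------------


def test_constant_health_curve_is_diagonal(rng):
    curve = concentration_curve(np.full(100, 2.0), rng.normal(size=100))
    assert np.allclose(curve[:, 0], curve[:, 1], atol=1e-12)


def test_all_health_at_top_income():
    h = np.array([0.0, 0.0, 0.0, 5.0])
    curve = concentration_curve(h, [1, 2, 3, 4], shift="none")
    assert curve[:4, 1] == pytest.approx([0, 0, 0, 0])
    assert curve[-1] == pytest.approx([1.0, 1.0])


def test_curve_endpoints_and_area_consistency(rng):
    h = rng.uniform(0.5, 3.0, 4000)
    y = rng.normal(size=4000) + 0.3 * h
    curve = concentration_curve(h, y, shift="none")
    assert curve[0] == pytest.approx([0.0, 0.0])
    assert curve[-1] == pytest.approx([1.0, 1.0])
    ci = concentration_index(h, y, shift="none").ci
    assert ci_from_curve(curve) == pytest.approx(ci, abs=2 / 4000)
    assert ci > 0  # pro-rich by construction; curve below the diagonal
    assert (curve[1:-1, 1] <= curve[1:-1, 0] + 1e-9).all()


def test_zero_total_health_curve_error():
    with pytest.raises(ValueError, match="undefined"):
        concentration_curve([0.0, 0.0], [1, 2], shift="none")


# --- decomposition ---------------------------------------------------------


def _linear_world(rng, n=2000):
    x1 = rng.uniform(0, 1, n)
    x2 = rng.binomial(1, 0.4, n).astype(float)
    income = np.exp(rng.normal(0, 1, n) + x1)
    health = 2.0 + 1.5 * x1 - 0.8 * x2
    data = pd.DataFrame({"x1": x1, "x2": x2})
    return data, {"x1": 1.5, "x2": -0.8}, income, health


def test_exact_linear_health_rates_sum_to_100(rng):
    data, coefs, income, health = _linear_world(rng)
    table = decompose_ci(data, coefs, income, health, intercept=2.0, shift="none")
    assert table.set_index("factor").loc["residual", "contribution"] == pytest.approx(
        0.0, abs=1e-12
    )
    assert table["rate_pct"].sum() == pytest.approx(100.0, abs=1e-8)


def test_adding_up_identity_for_ols(rng):
    import statsmodels.api as sm

    data, _, income, health = _linear_world(rng)
    noisy = health + rng.normal(0, 0.7, len(health))
    X = sm.add_constant(data.to_numpy())
    fit = sm.OLS(noisy, X).fit()
    coefs = dict(zip(data.columns, fit.params[1:]))
    table = decompose_ci(
        data, coefs, income, noisy, intercept=fit.params[0], shift="none"
    )
    total = concentration_index(noisy, income, shift="none").ci
    assert table["contribution"].sum() == pytest.approx(total, abs=1e-10)


def test_factor_uncorrelated_with_income_contributes_zero(rng):
    n = 500
    data = pd.DataFrame({"x": np.tile([0.0, 1.0], n // 2)})
    income = np.repeat(np.arange(n // 2), 2).astype(float) + 1
    health = 1.0 + 3.0 * data["x"].to_numpy()
    table = decompose_ci(data, {"x": 3.0}, income, health, intercept=1.0, shift="none")
    row = table.set_index("factor").loc["x"]
    assert row["ci"] == pytest.approx(0.0, abs=1e-12)
    assert row["contribution"] == pytest.approx(0.0, abs=1e-12)


def test_doubling_coefficient_doubles_contribution(rng):
    data, coefs, income, health = _linear_world(rng)
    t1 = decompose_ci(data, coefs, income, health, intercept=2.0, shift="none")
    coefs2 = dict(coefs, x1=2 * coefs["x1"])
    t2 = decompose_ci(data, coefs2, income, health, intercept=2.0, shift="none")
    c1 = t1.set_index("factor").loc["x1", "contribution"]
    c2 = t2.set_index("factor").loc["x1", "contribution"]
    assert c2 == pytest.approx(2 * c1, rel=1e-12)


def test_reference_denominator_calibration():
    elas = {"a": 2.0, "b": -1.0}
    cis = {"a": 0.05, "b": -0.1}
    table = calibrated_contribution_rates(elas, cis, "b", 50.0)
    # D = (-1 * -0.1) / 0.5 = 0.2; a's rate = 100 * 0.1 / 0.2 = 50
    assert table.loc["a", "rate_pct"] == pytest.approx(50.0)
    assert table.loc["b", "rate_pct"] == pytest.approx(50.0)


def test_recovery_check_matches_analytic_contributions():
    out = decomposition_recovery_check(n=4000, reps=30, seed=3)
    assert out["mean_abs_rate_error_pp"] < 2.0
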