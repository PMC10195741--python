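"""Mediation engine: OLS oracle checks, bootstrap behavior, Sobel test."""

import numpy as np
import pytest
import statsmodels.api as sm

from emobias import (
    DegenerateInputError,
    DesignError,
    fit_model4,
    ols,
    percentile_ci,
    sobel,
)


def normal_equations_oracle(X, y):
    """Explicit (X'X)^-1 X'y with classical SEs."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    s2 = resid @ resid / (len(y) - X.shape[1])
    return beta, np.sqrt(s2 * np.diag(XtX_inv))


# ---- ols ----

def test_response_equal_to_predictor_column(rng):
    x = rng.normal(size=20)
    X = np.column_stack([np.ones(20), x])
    fit = ols(X, x)
    np.testing.assert_allclose(fit.coef, [0.0, 1.0], atol=1e-12)
    np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)


def test_intercept_only_gives_mean(rng):
    y = rng.normal(3.0, 1.0, size=15)
    fit = ols(np.ones((15, 1)), y)
    assert fit.coef[0] == pytest.approx(y.mean(), abs=1e-12)


def test_six_point_fixture_matches_normal_equations():
    X = np.array([[1, 0.5], [1, 1.0], [1, 1.5], [1, 2.2], [1, 3.0], [1, 4.1]])
    y = np.array([1.1, 1.9, 2.4, 3.6, 4.2, 5.9])
    fit = ols(X, y)
    beta, se = normal_equations_oracle(X, y)
    np.testing.assert_allclose(fit.coef, beta, atol=1e-12)
    np.testing.assert_allclose(fit.se, se, atol=1e-12)


def test_ols_agrees_with_statsmodels(rng):
    """Independent-library cross-check of coefficients and SEs."""
    X = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
    y = rng.normal(size=40)
    fit = ols(X, y)
    ref = sm.OLS(y, X).fit()
    np.testing.assert_allclose(fit.coef, ref.params, atol=1e-10)
    np.testing.assert_allclose(fit.se, ref.bse, atol=1e-10)
    assert fit.resid_var == pytest.approx(ref.mse_resid, abs=1e-10)


def test_rank_deficiency_names_collinear_columns(rng):
    x = rng.normal(size=30)
    X = np.column_stack([np.ones(30), x, 2 * x])
    with pytest.raises(DesignError, match="collinear"):
        ols(X, rng.normal(size=30))


# ---- percentile_ci ----

def test_constant_draws_collapse():
    lo, hi = percentile_ci(np.full(200, 3.5), 0.95)
    assert lo == hi == 3.5


def test_quantile_rule_matches_sort_and_interpolate_oracle():
    draws = np.arange(1.0, 101.0)
    lo, hi = percentile_ci(draws, 0.90)

    def q(sorted_vals, p):  # linear interpolation between order statistics
        h = (len(sorted_vals) - 1) * p
        lo_i = int(np.floor(h))
        return sorted_vals[lo_i] + (h - lo_i) * (sorted_vals[min(lo_i + 1, len(sorted_vals) - 1)] - sorted_vals[lo_i])

    s = np.sort(draws)
    assert lo == pytest.approx(q(s, 0.05), abs=1e-12)
    assert hi == pytest.approx(q(s, 0.95), abs=1e-12)


def test_symmetric_draws_give_antisymmetric_interval(rng):
    x = rng.normal(size=5000)
    draws = np.concatenate([x, -x])
    lo, hi = percentile_ci(draws, 0.95)
    assert lo == pytest.approx(-hi, abs=1e-9)


def test_too_few_draws_rejected():
    with pytest.raises(DegenerateInputError):
        percentile_ci(np.arange(50.0), 0.95)


# ---- sobel ----

def test_sobel_null_a():
    z, p = sobel(0.0, 1.0, 2.0, 0.5)
    assert z == 0.0 and p == 1.0


def test_sobel_closed_form():
    z, p = sobel(1.0, 1.0, 1.0, 1.0)
    assert z == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-12)


def test_sobel_rejects_bad_se():
    with pytest.raises(ValueError):
        sobel(1.0, 0.0, 1.0, 1.0)


# ---- fit_model4 ----

def _toy_data(rng, n=120, a=0.6, b=0.5, cp=0.2):
    x = rng.integers(0, 2, size=n).astype(float)
    m = a * x + rng.normal(size=n)
    y = cp * x + b * m + rng.normal(size=n)
    return x, m, y


def test_ols_identity_c_equals_cprime_plus_ab(rng):
    x, m, y = _toy_data(rng)
    z = rng.normal(size=(len(x), 2))
    res = fit_model4(x, m, y, covariates=z, n_boot=0)
    assert abs(res.c - (res.c_prime + res.ab)) < 1e-10


def test_null_mediator_ci_contains_zero():
    rng = np.random.default_rng(2024)
    n = 150
    x = rng.integers(0, 2, size=n).astype(float)
    m = rng.normal(size=n)          # independent of x and y
    y = 0.3 * x + rng.normal(size=n)
    res = fit_model4(x, m, y, n_boot=2000, seed=77)
    lo, hi = res.ci_ab
    assert lo < 0.0 < hi


def test_eight_row_fixture_matches_per_regression_oracle():
    # printed fixture: x condition, m mediator, y outcome
    x = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
    m = np.array([0.2, -0.1, 0.4, 0.0, 0.9, 1.1, 0.7, 1.3])
    y = np.array([1.0, 0.8, 1.3, 0.9, 2.0, 2.4, 1.9, 2.6])
    res = fit_model4(x, m, y, n_boot=0)
    ones = np.ones(8)
    beta_a, se_a = normal_equations_oracle(np.column_stack([ones, x]), m)
    beta_y, _ = normal_equations_oracle(np.column_stack([ones, m, x]), y)
    beta_c, _ = normal_equations_oracle(np.column_stack([ones, x]), y)
    assert res.a == pytest.approx(beta_a[1], abs=1e-12)
    assert res.se_a == pytest.approx(se_a[1], abs=1e-12)
    assert res.b == pytest.approx(beta_y[1], abs=1e-12)
    assert res.c_prime == pytest.approx(beta_y[2], abs=1e-12)
    assert res.c == pytest.approx(beta_c[1], abs=1e-12)
    assert res.ab == pytest.approx(beta_a[1] * beta_y[1], abs=1e-12)


def test_scale_equivariance_of_mediator(rng):
    x, m, y = _toy_data(rng)
    base = fit_model4(x, m, y, n_boot=0)
    scaled = fit_model4(x, 10.0 * m, y, n_boot=0)
    assert scaled.a == pytest.approx(10.0 * base.a, rel=1e-12)
    assert scaled.b == pytest.approx(base.b / 10.0, rel=1e-12)
    assert scaled.ab == pytest.approx(base.ab, rel=1e-12)
    assert scaled.c == pytest.approx(base.c, rel=1e-12)
    assert scaled.c_prime == pytest.approx(base.c_prime, rel=1e-12)


def test_seeded_determinism_bit_identical(rng):
    x, m, y = _toy_data(rng)
    r1 = fit_model4(x, m, y, n_boot=500, seed=11)
    r2 = fit_model4(x, m, y, n_boot=500, seed=11)
    assert r1.to_dict() == r2.to_dict()


def test_constant_exposure_rejected(rng):
    n = 30
    with pytest.raises(DesignError, match="distinct"):
        fit_model4(np.zeros(n), rng.normal(size=n), rng.normal(size=n), n_boot=0)


def test_unbalanced_exposure_warns_on_many_redraws():
    rng = np.random.default_rng(8)
    n = 12
    x = np.zeros(n)
    x[0] = 1.0  # single treated case: many degenerate resamples
    m = rng.normal(size=n)
    y = rng.normal(size=n)
    with pytest.warns(UserWarning, match="redraws"):
        res = fit_model4(x, m, y, n_boot=500, seed=4)
    assert res.n_redraws > 0
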