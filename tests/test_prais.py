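"""Prais-Winsten and Cochrane-Orcutt feasible GLS.

The independent oracle for the transform is explicit-inverse GLS with the
AR(1) covariance Sigma_ij = phi^|i-j| / (1 - phi^2).
"""

import numpy as np
import pytest

from itsfit import (
    MaScenario,
    build_design,
    estimate_phi1,
    fit_cochrane_orcutt,
    fit_ols,
    fit_prais_winsten,
    pw_transform,
    simulate_its,
)


def ar1_series(n, phi, rng):
    e = np.empty(n)
    e[0] = rng.standard_normal() / np.sqrt(1 - phi**2)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + rng.standard_normal()
    return e


def test_phi1_estimator_consistency():
    rng = np.random.default_rng(8)
    white = rng.standard_normal(100_000)
    assert estimate_phi1(white).phi1 == pytest.approx(0.0, abs=0.01)
    ar = ar1_series(100_000, 0.5, rng)
    assert estimate_phi1(ar).phi1 == pytest.approx(0.5, abs=0.01)


def test_phi1_limit_for_ma_errors_is_lag1_autocorrelation():
    from itsfit.ma_dgp import simulate_ma_errors

    e = simulate_ma_errors((1, 1, 1), 10**6, np.random.default_rng(9))
    assert estimate_phi1(e).phi1 == pytest.approx(0.75, abs=0.01)


def test_phi1_estimator_edge_cases():
    with pytest.raises(ValueError, match="constant"):
        estimate_phi1(np.ones(10))
    # near unit-root residuals: estimate truncated into the open interval
    t = np.arange(200.0)
    est = estimate_phi1(t - t.mean())
    assert abs(est.phi1) < 1


def test_transform_hand_example():
    # phi = 0.5, y = (2, 3): ytilde = (2*sqrt(0.75), 3 - 0.5*2)
    d = build_design(8, 4)
    y = np.arange(2.0, 10.0)
    Xt, yt, names = pw_transform(d, y, 0.5)
    assert yt[0] == pytest.approx(2 * np.sqrt(0.75))
    assert yt[1] == pytest.approx(3 - 0.5 * 2)
    assert names[0] == "z"
    np.testing.assert_allclose(Xt[0, 0], np.sqrt(0.75))
    np.testing.assert_allclose(Xt[1:, 0], 0.5)
    # trend column transformed like everything else
    j = names.index("t")
    np.testing.assert_allclose(Xt[2:, j], d.t[2:] - 0.5 * d.t[1:-1])


def test_phi_zero_transform_is_identity(moderate_series):
    Xt, yt, _ = pw_transform(moderate_series, moderate_series.y, 0.0)
    np.testing.assert_array_equal(yt, moderate_series.y)
    np.testing.assert_array_equal(Xt, moderate_series.matrix())
    pw = fit_prais_winsten(moderate_series, phi1=0.0)
    ols = fit_ols(moderate_series)
    np.testing.assert_allclose(pw.betas, ols.betas, rtol=1e-12)
    np.testing.assert_allclose(pw.vcov, ols.vcov, rtol=1e-12)


def test_fixed_phi_equals_explicit_gls():
    """PW transform with known phi is exactly GLS with the AR(1) covariance."""
    rng = np.random.default_rng(21)
    phi = 0.6
    for n in (10, 30, 50):
        d = build_design(n)
        y = 4 - d.x - d.t / n + ar1_series(n, phi, rng)
        idx = np.arange(n)
        Sigma = phi ** np.abs(idx[:, None] - idx[None, :]) / (1 - phi**2)
        X = d.matrix()
        Si = np.linalg.inv(Sigma)
        beta_gls = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ y)
        pw = fit_prais_winsten(d, y, phi1=phi)
        np.testing.assert_allclose(pw.betas, beta_gls, atol=1e-8)


def test_transform_with_true_phi_removes_lag1_correlation():
    rng = np.random.default_rng(4)
    n, phi = 100_000, 0.7
    d = build_design(n)
    y = 1.0 + 0.5 * d.x + ar1_series(n, phi, rng)
    Xt, yt, _ = pw_transform(d, y, phi)
    beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
    r = yt - Xt @ beta
    assert np.corrcoef(r[1:], r[:-1])[0, 1] == pytest.approx(0.0, abs=0.01)


def test_cochrane_orcutt_drops_first_row(moderate_series):
    co = fit_cochrane_orcutt(moderate_series, phi1=0.0)
    ols_rows_1_on = fit_ols(
        build_design(moderate_series.n - 1, moderate_series.tau - 1),
        moderate_series.y[1:],
    )
    # with phi=0, CO is OLS on rows 1..n-1 (same step/trend shape, shifted)
    assert co.df == moderate_series.n - 1 - 3
    assert co.beta1 == pytest.approx(ols_rows_1_on.beta1)


def test_pw_more_precise_than_co_and_estimates_agree_at_large_n():
    scen = MaScenario.from_thetas((0.7, 0.0, 0.0))
    var_ratio = []
    for i in range(400):
        sim = simulate_its(scen, 20, np.random.default_rng(i))
        pw = fit_prais_winsten(sim)
        co = fit_cochrane_orcutt(sim)
        var_ratio.append(co.se_beta1**2 / pw.se_beta1**2)
    assert np.mean(var_ratio) > 1.0
    big = simulate_its(scen, 1000, np.random.default_rng(77))
    pw, co = fit_prais_winsten(big), fit_cochrane_orcutt(big)
    assert abs(pw.beta1 - co.beta1) < 0.02


def test_iterated_fit_reports_phi_and_convergence(moderate_series):
    fit = fit_prais_winsten(moderate_series)
    assert fit.converged
    assert fit.extras["iterations"] >= 2
    assert abs(fit.extras["phi1"]) < 1
    single = fit_prais_winsten(moderate_series, iterate=False)
    assert single.extras["iterations"] == 1


def test_pw_unbiased_under_ma3_errors():
    """FGLS point estimates stay unbiased when the AR(1) working model is wrong."""
    scen = MaScenario.from_thetas((0.9, 0.6, 0.3))
    est = [
        fit_prais_winsten(simulate_its(scen, 50, np.random.default_rng(i))).beta1
        for i in range(2000)
    ]
    bias = np.mean(est) + 1.0
    mc_se = np.std(est, ddof=1) / np.sqrt(len(est))
    assert abs(bias) < 3 * mc_se
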