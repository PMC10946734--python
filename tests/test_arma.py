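"""Regression with ARMA errors: likelihoods, ML fitting, order selection.

statsmodels' SARIMAX is the independent reference for the exact Gaussian
likelihood; the dense multivariate-normal density with the analytic ARMA
autocovariance is the in-house oracle for the Kalman recursion.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from itsfit import (
    MaScenario,
    build_design,
    conditional_loglik,
    exact_loglik,
    fit_arma_regression,
    fit_ols,
    simulate_its,
    stepwise_select,
)
from itsfit._arma_core import arma_acovf, pacf_to_ar, ar_to_pacf, unconstrained_to_arma
from itsfit.arma import aicc_penalty


@pytest.fixture(scope="module")
def series():
    return simulate_its(MaScenario.from_thetas((0.8, 0.5, 0.2)), 50, np.random.default_rng(3))


BETA = np.array([4.0, -1.0, -0.02])


def test_acovf_matches_statsmodels():
    from statsmodels.tsa.arima_process import arma_acovf as sm_acovf

    phi, theta = np.array([0.5, -0.2]), np.array([0.4, 0.1, 0.05])
    ours = arma_acovf(phi, theta, 12, sigma2=1.7)
    ref = sm_acovf(np.r_[1.0, -phi], np.r_[1.0, theta], nobs=12, sigma2=1.7)
    np.testing.assert_allclose(ours, ref, rtol=1e-10)


def test_pacf_transform_round_trip_and_stationarity():
    rng = np.random.default_rng(0)
    for _ in range(50):
        r = rng.uniform(-0.95, 0.95, size=4)
        a = pacf_to_ar(r)
        np.testing.assert_allclose(ar_to_pacf(a), r, atol=1e-10)
        roots = np.roots(np.r_[1.0, -a][::-1])
        assert np.min(np.abs(roots)) > 1.0


def test_unconstrained_map_gives_invertible_ma():
    u = np.array([2.5, -1.0, 0.7])
    _, theta = unconstrained_to_arma(u, 0, 3)
    roots = np.roots(np.r_[1.0, theta][::-1])
    assert np.min(np.abs(roots)) > 1.0


def test_iid_conditional_equals_iid_exact_equals_normal_density(series):
    ll_c = conditional_loglik(series, series.y, BETA, [], [], 1.3)
    ll_e = exact_loglik(series, series.y, BETA, [], [], 1.3)
    eps = series.y - series.matrix() @ BETA
    ll_ref = stats.norm.logpdf(eps, scale=np.sqrt(1.3)).sum()
    assert ll_c == pytest.approx(ll_ref, abs=1e-10)
    assert ll_e == pytest.approx(ll_ref, abs=1e-10)


def test_conditional_ma1_matches_worked_recursion():
    """First three MA(1) contributions: means beta'x0, beta'x1 + th*e0,
    beta'x2 + th*(e1 - th*e0)."""
    d3 = build_design(3, 2, include_trend=False)
    y = np.array([1.0, 2.0, 1.5])
    b = np.array([1.2, -0.4])
    th, s2 = 0.6, 0.9
    eps = y - d3.matrix() @ b
    eta0 = eps[0]
    eta1 = eps[1] - th * eta0
    eta2 = eps[2] - th * eta1
    by_hand = stats.norm.logpdf([eta0, eta1, eta2], scale=np.sqrt(s2)).sum()
    ll = conditional_loglik(d3, y, b, [], [th], s2)
    assert ll == pytest.approx(by_hand, abs=1e-12)
    # mean of y2 | y1, y0 is beta'x2 + th*(eps1 - th*eps0)
    assert eta2 == pytest.approx(eps[2] - th * eps[1] + th**2 * eps[0])


def test_conditional_explosive_recursion_flagged(series):
    with pytest.raises(ValueError, match="invertible"):
        conditional_loglik(series, series.y, BETA, [], [-1.6], 1.0)


def test_exact_loglik_kalman_equals_dense_oracle(series):
    for phi, theta in [([], [0.8, 0.5, 0.2]), ([0.5], [0.3]), ([0.9], []), ([0.4, 0.3], [0.2, 0.1])]:
        k = exact_loglik(series, series.y, BETA, phi, theta, 1.1, method="kalman")
        dn = exact_loglik(series, series.y, BETA, phi, theta, 1.1, method="dense")
        assert k == pytest.approx(dn, abs=1e-6)


def test_exact_loglik_matches_statsmodels(series):
    phi, theta = np.array([0.3]), np.array([0.4, 0.2])
    ours = exact_loglik(series, series.y, BETA, phi, theta, 1.3)
    mod = sm.tsa.SARIMAX(series.y, exog=series.matrix(), order=(1, 0, 2), trend="n")
    ref = mod.loglike(np.r_[BETA, phi, theta, 1.3])
    assert ours == pytest.approx(ref, abs=1e-8)


def test_exact_loglik_rejects_nonstationary(series):
    with pytest.raises(ValueError, match="non-stationary"):
        exact_loglik(series, series.y, BETA, [1.05], [], 1.0)


def test_conditional_approaches_exact_for_long_series():
    scen = MaScenario.from_thetas((0.6, 0.3, 0.1))
    sim = simulate_its(scen, 10_000, np.random.default_rng(12))
    ll_c = conditional_loglik(sim, sim.y, BETA, [0.2], [0.5], 1.0)
    ll_e = exact_loglik(sim, sim.y, BETA, [0.2], [0.5], 1.0)
    assert abs(ll_c - ll_e) / sim.n < 1e-3


def test_likelihood_peaks_near_truth():
    scen = MaScenario.from_thetas((0.8, 0.5, 0.2))
    wins = 0
    for i in range(100):
        sim = simulate_its(scen, 100, np.random.default_rng(i))
        truth = exact_loglik(sim, sim.y, np.array([4, -1, -0.01]), [], [0.8, 0.5, 0.2], 1.0)
        pert = exact_loglik(sim, sim.y, np.array([4, -1, -0.01]), [], [0.4, 0.1, 0.0], 1.0)
        wins += truth > pert
    assert wins > 80


def test_fit_00_equals_ols_with_ml_variance(series):
    fit = fit_arma_regression(series, p=0, q=0)
    ols = fit_ols(series)
    np.testing.assert_allclose(fit.betas, ols.betas, atol=1e-6)
    rss = float(np.sum((series.y - series.matrix() @ ols.betas) ** 2))
    assert fit.sigma2 == pytest.approx(rss / series.n, rel=1e-8)


def test_ml_matches_statsmodels_maximized_loglik(series):
    ours = fit_arma_regression(series, p=0, q=3)
    ref = sm.tsa.SARIMAX(series.y, exog=series.matrix(), order=(0, 0, 3), trend="n").fit(disp=0)
    assert ours.loglik >= ref.llf - 1e-3  # at least as good an optimum
    np.testing.assert_allclose(ours.betas, ref.params[:3], atol=0.05)


def test_ma3_parameter_recovery():
    scen = MaScenario.from_thetas((0.8, 0.5, 0.2))
    est = []
    for i in range(120):
        sim = simulate_its(scen, 300, np.random.default_rng(i))
        est.append(fit_arma_regression(sim, p=0, q=3).thetas)
    np.testing.assert_allclose(np.mean(est, axis=0), [0.8, 0.5, 0.2], atol=0.05)


def test_aicc_penalty_arithmetic():
    # n=50, k=5: AICc = AIC + 2*5*6/44
    assert aicc_penalty(50, 5) == pytest.approx(2 * 5 * 6 / 44)
    assert np.isinf(aicc_penalty(6, 5))


def test_stepwise_respects_order_caps(series):
    fit = stepwise_select(series, max_p=2, max_q=2)
    assert fit.p <= 2 and fit.q <= 2
    fit5 = stepwise_select(series)
    assert fit5.p <= 5 and fit5.q <= 5


def test_stepwise_prefers_white_noise_on_iid_data():
    scen = MaScenario.from_thetas((0.0, 0.0, 0.0))
    orders = []
    for i in range(60):
        sim = simulate_its(scen, 300, np.random.default_rng(i))
        f = stepwise_select(sim)
        orders.append((f.p, f.q))
    share_00 = np.mean([o == (0, 0) for o in orders])
    assert share_00 > 0.5
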