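"""REML estimation of regression with ARMA errors, Satterthwaite degrees of
freedom, and the Kenward-Roger small-sample correction.

Maximum likelihood underestimates error-model parameters (and hence the
standard error of the intervention effect) because it ignores the loss of
information from estimating the regression mean.  Restricted maximum
likelihood (REML) removes that source of bias by maximising the likelihood
of error contrasts,

    l_R(psi) = -1/2 [ log|V| + log|X' V^-1 X| + r' V^-1 r ] + const,

where V = sigma2 * C(error params) is the dense ARMA covariance of the
series and r the GLS residuals.  The regression coefficients are then
generalized-least-squares estimates at the fitted error parameters.

Because the sampling variability of the estimated variance of beta1-hat
(call it phi-hat) is ignored by a normal-reference interval, the
Satterthwaite approximation matches var(phi-hat) to a scaled chi-square,
giving degrees of freedom d = 2 phi^2 / var(phi-hat); the Kenward-Roger
correction additionally inflates the variance of beta-hat for the
first-order bias induced by plugging in estimated error parameters.  Both
corrections use a t(d) reference distribution.

Dense n-by-n covariances are used throughout; the methods target short
series (n up to a few hundred), where this is both exact and cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy.optimize import minimize

from ._arma_core import arma_acovf, arma_to_unconstrained, unconstrained_to_arma
from .design import ItsDesign
from .results import FitResult

__all__ = ["RemlFit", "SatterthwaiteInfo", "reml_fit", "satterthwaite_df", "kr_fit"]

LOG2PI = float(np.log(2.0 * np.pi))
_UBOUND = 6.0  # |arctanh(pacf)| cap, keeps the ARMA covariance numerically PD
_REL_STEP = 1e-4  # central-difference step factor: h = 1e-4 * (1 + |psi|)


@dataclass
class SatterthwaiteInfo:
    """Satterthwaite matching for the variance of the intervention estimate.

    ``phi`` is the estimated variance of beta1-hat, ``var_phi_hat`` the
    delta-method variance of that estimate under the REML information, and
    ``d = 2 phi^2 / var_phi_hat`` the matched chi-square degrees of freedom.
    """

    phi: float
    var_phi_hat: float
    d: float


@dataclass
class RemlFit:
    """REML fit of the segmented regression with an ARMA error model.

    Carries everything needed for the Satterthwaite/Kenward-Roger
    machinery: the data, the error-model orders and estimates, and the
    restricted-likelihood value.
    """

    design: ItsDesign
    y: np.ndarray
    p: int
    q: int
    phis: np.ndarray
    thetas: np.ndarray
    sigma2: float
    betas: np.ndarray
    vcov_betas: np.ndarray
    loglik_r: float
    converged: bool

    @property
    def psi(self) -> np.ndarray:
        """Variance-parameter vector (phis, thetas, sigma2)."""
        return np.concatenate([self.phis, self.thetas, [self.sigma2]])

    @property
    def beta1_index(self) -> int:
        return self.design.beta1_index

    def to_fit_result(self, method: str = "reml", df: float = np.inf) -> FitResult:
        return FitResult(
            method=method,
            names=self.design.names,
            betas=self.betas,
            vcov=self.vcov_betas,
            df=df,
            beta1_index=self.beta1_index,
            converged=self.converged,
            extras={"p": self.p, "q": self.q, "sigma2": self.sigma2},
        )


def _corr_matrix(phi, theta, n: int) -> np.ndarray:
    """Dense ARMA covariance at unit innovation variance."""
    return sla.toeplitz(arma_acovf(phi, theta, n, sigma2=1.0))


def _whiten(C: np.ndarray, X: np.ndarray, y: np.ndarray):
    L = sla.cholesky(C, lower=True)
    Xw = sla.solve_triangular(L, X, lower=True)
    yw = sla.solve_triangular(L, y, lower=True)
    logdet_c = 2.0 * float(np.sum(np.log(np.diag(L))))
    return Xw, yw, logdet_c


def restricted_loglik(
    design: ItsDesign, y: np.ndarray, phis, thetas, sigma2: float
) -> float:
    """Restricted log-likelihood at fixed error-model parameters."""
    X = design.matrix()
    n, k = X.shape
    C = _corr_matrix(phis, thetas, n)
    Xw, yw, logdet_c = _whiten(C, X, np.asarray(y, dtype=float))
    Q, R = np.linalg.qr(Xw)
    beta = np.linalg.solve(R, Q.T @ yw)
    r = yw - Xw @ beta
    rss = float(r @ r)
    logdet_xwx = 2.0 * float(np.sum(np.log(np.abs(np.diag(R)))))
    return -0.5 * (
        (n - k) * (LOG2PI + np.log(sigma2))
        + logdet_c
        + logdet_xwx
        + rss / sigma2
    )


def _concentrated_negloglik(u, p, q, X, y, n, k):
    phi, theta = unconstrained_to_arma(u, p, q)
    try:
        C = _corr_matrix(phi, theta, n)
        Xw, yw, logdet_c = _whiten(C, X, y)
    except (np.linalg.LinAlgError, ValueError):
        return 1e12
    Q, R = np.linalg.qr(Xw)
    beta = np.linalg.solve(R, Q.T @ yw)
    r = yw - Xw @ beta
    rss = float(r @ r)
    if rss <= 0:
        return 1e12
    s2 = rss / (n - k)
    logdet_xwx = 2.0 * float(np.sum(np.log(np.abs(np.diag(R)))))
    return 0.5 * ((n - k) * (LOG2PI + np.log(s2) + 1.0) + logdet_c + logdet_xwx)


def reml_fit(
    design: ItsDesign,
    y: np.ndarray | None = None,
    error_model: tuple[int, int] = (0, 3),
) -> RemlFit:
    """Fit the segmented regression with ARMA(p,q) errors by REML.

    The error parameters maximise the restricted likelihood (with sigma2
    profiled out as rss_gls / (n - k), the unbiased estimator in the iid
    case); beta-hat is then the GLS estimate at the fitted error
    parameters.  Non-convergence of the optimizer is reported through
    ``converged=False`` — on very short series this is expected to happen
    occasionally and must not crash a simulation.
    """
    y = design.y if y is None else np.asarray(y, dtype=float)
    if y is None:
        raise ValueError("no response attached to the design and none supplied")
    p, q = error_model
    X = design.matrix()
    n, k = X.shape
    if n <= k + p + q:
        raise ValueError(f"series too short (n={n}) for REML with ARMA({p},{q}) errors")

    converged = True
    if p + q == 0:
        u_hat = np.zeros(0)
    else:
        bounds = [(-_UBOUND, _UBOUND)] * (p + q)

        def solve(u0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return minimize(
                    _concentrated_negloglik,
                    u0,
                    args=(p, q, X, y, n, k),
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": 100},
                )

        res = solve(np.zeros(p + q))
        if res.nit <= 2:
            # barely moved: retry from a positive-autocorrelation start
            alt = solve(np.full(p + q, -0.4))
            if np.isfinite(alt.fun) and alt.fun < res.fun:
                res = alt
        u_hat = res.x if np.all(np.isfinite(res.x)) else np.zeros(p + q)
        converged = bool(res.success or res.status == 1) and np.isfinite(res.fun)

    phi, theta = unconstrained_to_arma(u_hat, p, q)
    C = _corr_matrix(phi, theta, n)
    Xw, yw, _ = _whiten(C, X, y)
    Q, R = np.linalg.qr(Xw)
    beta = np.linalg.solve(R, Q.T @ yw)
    r = yw - Xw @ beta
    sigma2 = float(r @ r) / (n - k)
    Rinv = np.linalg.inv(R)
    vcov = sigma2 * (Rinv @ Rinv.T)
    llr = restricted_loglik(design, y, phi, theta, sigma2)
    return RemlFit(
        design=design,
        y=y,
        p=p,
        q=q,
        phis=phi,
        thetas=theta,
        sigma2=sigma2,
        betas=beta,
        vcov_betas=vcov,
        loglik_r=llr,
        converged=converged,
    )


def _split_psi(psi: np.ndarray, p: int, q: int):
    return psi[:p], psi[p : p + q], float(psi[p + q])


def _steps(psi: np.ndarray) -> np.ndarray:
    return _REL_STEP * (1.0 + np.abs(psi))


def _kr_machinery(fit: RemlFit) -> dict:
    """Shared ingredients for Satterthwaite and Kenward-Roger.

    Builds V and its derivatives with respect to the variance parameters
    psi = (phis, thetas, sigma2), the GLS variance Phi = (X'V^-1 X)^-1, the
    REML projection P = V^-1 - V^-1 X Phi X' V^-1, and the *expected* REML
    information I_ij = tr(P dV_i P dV_j) / 2.  The expected information is
    positive semi-definite by construction, which keeps the downstream
    variance of var(beta1-hat) non-negative even when the error-model
    estimate sits on the invertibility boundary (where a numeric observed
    Hessian is unreliable).
    """
    n = fit.design.n
    X = fit.design.matrix()
    psi = fit.psi
    npar = len(psi)
    C = _corr_matrix(fit.phis, fit.thetas, n)
    V = fit.sigma2 * C
    L = sla.cholesky(V, lower=True)
    Vinv = sla.cho_solve((L, True), np.eye(n))
    Vinv_X = Vinv @ X
    Phi = np.linalg.inv(X.T @ Vinv_X)
    Proj = Vinv - Vinv_X @ Phi @ Vinv_X.T
    dVs = [_dV(fit, i) for i in range(npar)]
    PdV = [Proj @ dV for dV in dVs]
    info = np.empty((npar, npar))
    for i in range(npar):
        for j in range(i + 1):
            info[i, j] = info[j, i] = 0.5 * float(np.sum(PdV[i].T * PdV[j]))
    return {
        "V": V,
        "L": L,
        "Vinv_X": Vinv_X,
        "Phi": Phi,
        "info": info,
        "dVs": dVs,
    }


def _var_beta1(fit: RemlFit, psi: np.ndarray) -> float:
    """var(beta1-hat) = sigma2 [ (X' C^-1 X)^-1 ]_11 as a function of psi."""
    ph, th, s2 = _split_psi(psi, fit.p, fit.q)
    X = fit.design.matrix()
    C = _corr_matrix(ph, th, fit.design.n)
    Xw = sla.solve_triangular(sla.cholesky(C, lower=True), X, lower=True)
    M = np.linalg.inv(Xw.T @ Xw)
    j = fit.beta1_index
    return s2 * float(M[j, j])


def _satterthwaite_from_machinery(fit: RemlFit, mach: dict) -> SatterthwaiteInfo:
    psi0 = fit.psi
    h = _steps(psi0)
    npar = len(psi0)
    g = np.empty(npar)
    for i in range(npar):
        ei = np.zeros(npar)
        ei[i] = h[i]
        g[i] = (_var_beta1(fit, psi0 + ei) - _var_beta1(fit, psi0 - ei)) / (2.0 * h[i])
    info = mach["info"]
    try:
        cov_psi = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_psi = np.linalg.pinv(info)
    var_phi = float(g @ cov_psi @ g)
    phi_hat = _var_beta1(fit, psi0)
    if var_phi <= 0:
        # degenerate propagation: no measurable variance-parameter
        # uncertainty, so the residual df bound applies
        d = float(fit.design.n - fit.design.k)
    else:
        d = 2.0 * phi_hat ** 2 / var_phi
        d = min(d, float(fit.design.n - fit.design.k))
    return SatterthwaiteInfo(phi=phi_hat, var_phi_hat=var_phi, d=float(d))


def satterthwaite_df(fit: RemlFit) -> SatterthwaiteInfo:
    """Satterthwaite degrees of freedom for the intervention coefficient.

    The gradient of var(beta1-hat) with respect to the variance parameters
    is taken by central differences; its quadratic form in the inverse
    expected REML information gives var(phi-hat), and
    d = 2 phi^2 / var(phi-hat), capped at the residual degrees of freedom
    n - k.  Under an iid error model this reproduces d = n - k exactly (up
    to numeric differencing error).
    """
    return _satterthwaite_from_machinery(fit, _kr_machinery(fit))


def _dV(fit: RemlFit, i: int) -> np.ndarray:
    """Central-difference derivative of V = sigma2 C w.r.t. psi_i."""
    psi0 = fit.psi
    h = _steps(psi0)
    n = fit.design.n

    def V(psi):
        ph, th, s2 = _split_psi(psi, fit.p, fit.q)
        return s2 * _corr_matrix(ph, th, n)

    ei = np.zeros(len(psi0))
    ei[i] = h[i]
    return (V(psi0 + ei) - V(psi0 - ei)) / (2.0 * h[i])


def _d2V(fit: RemlFit, i: int, j: int) -> np.ndarray:
    psi0 = fit.psi
    h = _steps(psi0)
    n = fit.design.n

    def V(psi):
        ph, th, s2 = _split_psi(psi, fit.p, fit.q)
        return s2 * _corr_matrix(ph, th, n)

    ei = np.zeros(len(psi0))
    ej = np.zeros(len(psi0))
    ei[i] = h[i]
    ej[j] = h[j]
    if i == j:
        return (V(psi0 + ei) + V(psi0 - ei) - 2.0 * V(psi0)) / h[i] ** 2
    return (
        V(psi0 + ei + ej) - V(psi0 + ei - ej) - V(psi0 - ei + ej) + V(psi0 - ei - ej)
    ) / (4.0 * h[i] * h[j])


def kr_fit(
    design: ItsDesign,
    y: np.ndarray | None = None,
    error_model: tuple[int, int] = (0, 3),
) -> FitResult:
    """REML fit with the Kenward-Roger variance adjustment and t(d) intervals.

    The first-order Kenward-Roger adjustment inflates the GLS variance of
    beta-hat,

        Phi_A = Phi + 2 Phi [ sum_ij W_ij (Q_ij - P_i Phi P_j - R_ij / 4) ] Phi,

    where Phi = (X'V^-1 X)^-1, the P/Q/R arrays involve first and second
    derivatives of V with respect to the variance parameters, and W is the
    inverse REML information.  Degrees of freedom come from the
    Satterthwaite matching.  Under an iid error model the adjustment
    vanishes and the interval reduces to the classical OLS t(n-k) interval.
    """
    fit = reml_fit(design, y, error_model=error_model)
    psi = fit.psi
    npar = len(psi)

    mach = _kr_machinery(fit)
    L = mach["L"]
    Vinv_X = mach["Vinv_X"]
    Phi = mach["Phi"]
    dVs = mach["dVs"]
    sat = _satterthwaite_from_machinery(fit, mach)
    try:
        W = np.linalg.inv(mach["info"])
    except np.linalg.LinAlgError:
        W = np.linalg.pinv(mach["info"])

    P = [Vinv_X.T @ dVi @ Vinv_X for dVi in dVs]
    Lam = np.zeros_like(Phi)
    for i in range(npar):
        Ai = dVs[i] @ Vinv_X
        ViAi = sla.cho_solve((L, True), Ai)
        for j in range(npar):
            Qij = ViAi.T @ dVs[j] @ Vinv_X  # X'V^-1 Vi V^-1 Vj V^-1 X
            Rij = Vinv_X.T @ _d2V(fit, i, j) @ Vinv_X
            Lam += W[i, j] * (Qij - P[i] @ Phi @ P[j] - 0.25 * Rij)
    Phi_adj = Phi + 2.0 * Phi @ Lam @ Phi
    Phi_adj = 0.5 * (Phi_adj + Phi_adj.T)
    # guard: the adjustment must not produce a negative variance
    jj = fit.beta1_index
    if Phi_adj[jj, jj] <= 0:
        Phi_adj = Phi

    return FitResult(
        method="reml_kr",
        names=fit.design.names,
        betas=fit.betas,
        vcov=Phi_adj,
        df=sat.d,
        beta1_index=jj,
        converged=fit.converged,
        extras={
            "p": fit.p,
            "q": fit.q,
            "sigma2": fit.sigma2,
            "satterthwaite_d": sat.d,
            "phi_var_beta1": sat.phi,
            "var_phi_hat": sat.var_phi_hat,
            "se_unadjusted": float(np.sqrt(Phi[jj, jj])),
        },
    )
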