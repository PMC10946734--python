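"""Regression with ARMA(p,q) errors by maximum likelihood, with stepwise
AICc order selection.

The model is y = X beta + eps where eps follows a stationary, invertible
ARMA(p,q) process with iid Gaussian innovations.  Two likelihoods are
available: the exact Gaussian likelihood, evaluated by a Kalman filter on
the state-space form (equivalently, for moderate n, the dense
multivariate-normal density with the analytic ARMA autocovariance), and
the conditional likelihood that fixes pre-sample innovations at zero and
conditions on the first p observations.  Because both whitening operators
are linear, beta and the innovation variance are profiled out and the
optimizer only searches the (p+q)-dimensional error-parameter space, in
partial-autocorrelation coordinates that enforce stationarity and
invertibility.

Order selection follows the stepwise search popularised by the
Hyndman-Khandakar auto-ARIMA algorithm, driven by the bias-corrected AIC
(AICc) with p and q capped at 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.optimize import minimize

from ._arma_core import (
    _HAVE_NUMBA,
    _fg_cond_jit,
    _fg_exact_jit,
    arma_acovf,
    arma_to_unconstrained,
    conditional_whiten,
    is_invertible,
    is_stationary,
    kalman_whiten,
    unconstrained_to_arma,
)
from .design import ItsDesign
from .results import FitResult

__all__ = [
    "ArmaFit",
    "conditional_loglik",
    "exact_loglik",
    "fit_arma_regression",
    "stepwise_select",
    "aicc_penalty",
]

LOG2PI = float(np.log(2.0 * np.pi))
_UBOUND = 6.0  # |arctanh(pacf)| cap; tanh(6) ~ 1 - 1e-5 keeps the state space solvable


@dataclass
class ArmaFit:
    """Maximum-likelihood fit of the regression-with-ARMA-errors model."""

    p: int
    q: int
    phis: np.ndarray
    thetas: np.ndarray
    sigma2: float
    betas: np.ndarray
    vcov_betas: np.ndarray
    loglik: float
    aicc: float
    converged: bool
    likelihood_kind: str
    names: list[str] = field(default_factory=list)
    beta1_index: int = 1
    n: int = 0

    @property
    def k(self) -> int:
        """Total free parameters: betas + phis + thetas + sigma2."""
        return len(self.betas) + self.p + self.q + 1

    def to_fit_result(self, method: str = "arma", use_t: bool = False) -> FitResult:
        df = float(self.n - len(self.betas)) if use_t else np.inf
        return FitResult(
            method=method,
            names=self.names,
            betas=self.betas,
            vcov=self.vcov_betas,
            df=df,
            beta1_index=self.beta1_index,
            converged=self.converged,
            extras={
                "p": self.p,
                "q": self.q,
                "order": f"{self.p},{self.q}",
                "aicc": self.aicc,
                "sigma2": self.sigma2,
                "loglik": self.loglik,
            },
        )


def aicc_penalty(n: int, k: int) -> float:
    """Small-sample AICc correction term 2k(k+1)/(n-k-1); inf when n <= k+1."""
    if n - k - 1 <= 0:
        return np.inf
    return 2.0 * k * (k + 1) / (n - k - 1)


def conditional_loglik(
    design: ItsDesign,
    y: np.ndarray,
    betas: np.ndarray,
    phis,
    thetas,
    sigma2: float,
) -> float:
    """Conditional Gaussian log-likelihood at fixed parameter values.

    Innovations are recovered by the recursion
    eta_t = eps_t - sum_i phi_i eps_{t-i} - sum_j theta_j eta_{t-j}
    with pre-sample innovations fixed at zero, conditioning on the first p
    residuals; n - p Gaussian terms are summed.  A non-invertible MA
    polynomial makes the recursion explosive; this is detected and raised.
    """
    phis = np.asarray(phis, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    eps = np.asarray(y, dtype=float) - design.matrix() @ np.asarray(betas, dtype=float)
    eta = conditional_whiten(phis, thetas, eps[:, None])[:, 0]
    scale = max(1.0, float(np.max(np.abs(eps))))
    if not np.all(np.isfinite(eta)) or np.max(np.abs(eta)) > 1e8 * scale:
        raise ValueError(
            "explosive innovation recursion: the MA polynomial is not invertible"
        )
    m = len(eta)
    return float(-0.5 * m * (LOG2PI + np.log(sigma2)) - 0.5 * (eta @ eta) / sigma2)


def exact_loglik(
    design: ItsDesign,
    y: np.ndarray,
    betas: np.ndarray,
    phis,
    thetas,
    sigma2: float,
    method: str = "kalman",
) -> float:
    """Exact Gaussian log-likelihood at fixed parameter values.

    ``method="kalman"`` runs the state-space innovations recursion;
    ``method="dense"`` evaluates the multivariate-normal density with the
    analytic ARMA autocovariance matrix (intended for moderate n as a
    cross-check; the two agree to numerical precision).
    """
    phis = np.asarray(phis, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    if not is_stationary(phis):
        raise ValueError("AR polynomial is non-stationary")
    if not is_invertible(thetas):
        raise ValueError("MA polynomial is non-invertible")
    eps = np.asarray(y, dtype=float) - design.matrix() @ np.asarray(betas, dtype=float)
    n = len(eps)
    if method == "kalman":
        W, sumlogF, _ = kalman_whiten(phis, thetas, eps[:, None])
        w = W[:, 0]
        return float(
            -0.5 * n * (LOG2PI + np.log(sigma2)) - 0.5 * sumlogF - 0.5 * (w @ w) / sigma2
        )
    if method == "dense":
        gamma = arma_acovf(phis, thetas, n, sigma2=sigma2)
        V = sla.toeplitz(gamma)
        L = sla.cholesky(V, lower=True)
        z = sla.solve_triangular(L, eps, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        return float(-0.5 * n * LOG2PI - 0.5 * logdet - 0.5 * (z @ z))
    raise ValueError(f"unknown method {method!r}")


def _profile_rss(Wy: np.ndarray, Wx: np.ndarray) -> float:
    """Residual sum of squares after profiling beta out by least squares."""
    G = Wx.T @ Wx
    b = np.linalg.solve(G, Wx.T @ Wy)
    r = Wy - Wx @ b
    return float(r @ r)


def _profiled_negloglik_exact(u, p, q, YX, n):
    phi, theta = unconstrained_to_arma(u, p, q)
    try:
        W, sumlogF, ok = kalman_whiten(phi, theta, YX)
        rss = _profile_rss(W[:, 0], W[:, 1:])
    except np.linalg.LinAlgError:
        return 1e12
    if rss <= 0 or not ok:
        return 1e12
    s2 = rss / n
    return 0.5 * n * (LOG2PI + np.log(s2) + 1.0) + 0.5 * sumlogF


def _profiled_negloglik_cond(u, p, q, YX, n):
    phi, theta = unconstrained_to_arma(u, p, q)
    H = conditional_whiten(phi, theta, YX)
    m = H.shape[0]
    if m == 0:
        return 1e12
    try:
        rss = _profile_rss(H[:, 0], H[:, 1:])
    except np.linalg.LinAlgError:
        return 1e12
    if rss <= 0:
        return 1e12
    s2 = rss / m
    return 0.5 * m * (LOG2PI + np.log(s2) + 1.0)


_FD_STEP = 1e-6  # forward-difference step for the jitted gradient


def _minimize_profiled(
    kind: str, u0: np.ndarray, p: int, q: int, YX: np.ndarray, n: int, maxiter: int, ftol: float
):
    """L-BFGS-B on the concentrated likelihood, jitted (f, grad) when available."""
    bounds = [(-_UBOUND, _UBOUND)] * len(u0)
    if _HAVE_NUMBA:
        fg = _fg_cond_jit if kind == "cond" else _fg_exact_jit
        YXc = np.ascontiguousarray(YX)
        zero_g = np.zeros_like(u0)

        def fun(u):
            try:
                return fg(u, p, q, YXc, _FD_STEP)
            except np.linalg.LinAlgError:
                return 1e12, zero_g

        jac = True
    else:
        obj = _profiled_negloglik_cond if kind == "cond" else _profiled_negloglik_exact

        def fun(u):
            return obj(u, p, q, YX, n)

        jac = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return minimize(
            fun,
            u0,
            jac=jac,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": ftol},
        )


def fit_arma_regression(
    design: ItsDesign,
    y: np.ndarray | None = None,
    p: int = 0,
    q: int = 0,
    start: str = "conditional",
    use_t: bool = False,
    start_u: np.ndarray | None = None,
) -> ArmaFit:
    """Fit the segmented regression with ARMA(p,q) errors by exact ML.

    The error parameters are optimized in partial-autocorrelation
    coordinates (stationary/invertible by construction); beta and sigma2
    are profiled out at every step.  ``start="conditional"`` first runs a
    cheap conditional-likelihood fit and polishes on the exact likelihood;
    ``start="zeros"`` optimizes the exact likelihood directly from white
    noise.  The variance matrix of beta-hat is the GLS expression at the
    estimated error parameters (the inverse observed-information block for
    beta); confidence intervals use normal quantiles by default.
    """
    y = design.y if y is None else np.asarray(y, dtype=float)
    if y is None:
        raise ValueError("no response attached to the design and none supplied")
    X = design.matrix()
    n, kb = X.shape
    if n <= p + q + kb + 2:
        raise ValueError(f"series too short (n={n}) to fit ARMA({p},{q}) with {kb} regressors")
    YX = np.column_stack([y, X])

    converged = True
    if p + q == 0:
        u_hat = np.zeros(0)
    else:
        u0 = np.zeros(p + q)
        if start == "conditional":
            pre = _minimize_profiled("cond", u0, p, q, YX, n, maxiter=60, ftol=1e-9)
            if np.all(np.isfinite(pre.x)):
                u0 = pre.x
        starts = [u0]
        if start_u is not None and len(start_u) == p + q:
            starts.append(np.clip(np.asarray(start_u, dtype=float), -_UBOUND, _UBOUND))
        best_res = None
        for s0 in starts:
            res = _minimize_profiled("exact", s0, p, q, YX, n, maxiter=100, ftol=1e-10)
            if np.all(np.isfinite(res.x)) and (best_res is None or res.fun < best_res.fun):
                best_res = res
        if best_res is None:
            u_hat = u0
            converged = False
        else:
            u_hat = best_res.x
            converged = bool(np.isfinite(best_res.fun))

    phi, theta = unconstrained_to_arma(u_hat, p, q)
    W, sumlogF, _ = kalman_whiten(phi, theta, YX)
    wy, Wx = W[:, 0], W[:, 1:]
    G, Rq = np.linalg.qr(Wx)
    beta = np.linalg.solve(Rq, G.T @ wy)
    r = wy - Wx @ beta
    sigma2 = float(r @ r) / n  # ML scale, not n-k
    loglik = float(-0.5 * n * (LOG2PI + np.log(sigma2) + 1.0) - 0.5 * sumlogF)
    Rinv = np.linalg.inv(Rq)
    vcov = sigma2 * (Rinv @ Rinv.T)
    k = kb + p + q + 1
    aicc = -2.0 * loglik + 2.0 * k + aicc_penalty(n, k)
    return ArmaFit(
        p=p,
        q=q,
        phis=phi,
        thetas=theta,
        sigma2=sigma2,
        betas=beta,
        vcov_betas=vcov,
        loglik=loglik,
        aicc=aicc,
        converged=converged,
        likelihood_kind="exact",
        names=design.names,
        beta1_index=design.beta1_index,
        n=n,
    )


_START_ORDERS = ((0, 0), (1, 0), (0, 1), (2, 2))
_ROOT_REJECT = 1.001  # candidate models with a root this close to the unit circle are rejected


def _has_near_unit_root(phi: np.ndarray, theta: np.ndarray) -> bool:
    """Fitted AR or MA polynomial has a root with modulus below 1.001.

    Order selection rejects such candidates: they indicate boundary fits or
    spurious near-cancelling AR/MA pairs whose apparent likelihood gain is
    not trustworthy.
    """
    for coefs in (np.r_[1.0, -np.asarray(phi)], np.r_[1.0, np.asarray(theta)]):
        if len(coefs) > 1 and np.any(coefs[1:] != 0.0):
            roots = np.roots(coefs[::-1])
            if len(roots) and np.min(np.abs(roots)) < _ROOT_REJECT:
                return True
    return False


def stepwise_select(
    design: ItsDesign,
    y: np.ndarray | None = None,
    max_p: int = 5,
    max_q: int = 5,
    use_t: bool = False,
    approximation: bool = False,
) -> ArmaFit:
    """Stepwise AICc search over ARMA error orders (p, q <= 5).

    Starts from the candidate set {(0,0), (1,0), (0,1), (2,2)} and
    repeatedly moves to the best-AICc neighbour (single steps in p and/or
    q, clipped to the order caps) until no neighbour improves.  Ties break
    toward fewer total parameters, then fewer MA parameters.  The winning
    order is refit by exact maximum likelihood and returned.

    Candidates are scored on the exact likelihood by default.
    ``approximation=True`` scores them on the cheaper conditional
    likelihood instead; note that conditional log-likelihoods of models
    with different AR orders sum over different numbers of innovations and
    can reward spurious near-cancelling AR/MA pairs, so this mode trades
    selection fidelity for speed.  Candidate fits that fail are skipped;
    if every candidate fails an error is raised.
    """
    y = design.y if y is None else np.asarray(y, dtype=float)
    if y is None:
        raise ValueError("no response attached to the design and none supplied")
    n, kb = design.n, design.k
    YX = np.column_stack([y, design.matrix()])
    # cache: (p, q) -> ((aicc, p+q, q) sort key, optimal coordinates) or None
    cache: dict[tuple[int, int], tuple[tuple[float, int, int], np.ndarray] | None] = {}
    objective = _profiled_negloglik_cond if approximation else _profiled_negloglik_exact

    def feasible(p: int, q: int) -> bool:
        return 0 <= p <= max_p and 0 <= q <= max_q and n > p + q + kb + 2

    def embed(u_from: np.ndarray, p_from: int, q_from: int, p: int, q: int) -> np.ndarray:
        """Warm start: carry over AR/MA coordinates block-wise, pad with zeros."""
        u0 = np.zeros(p + q)
        np_ar = min(p, p_from)
        u0[:np_ar] = u_from[:np_ar]
        nq = min(q, q_from)
        u0[p : p + nq] = u_from[p_from : p_from + nq]
        return u0

    def score(p: int, q: int, u0: np.ndarray | None = None):
        key = (p, q)
        if key in cache:
            return cache[key]
        out = None
        if feasible(p, q):
            k = kb + p + q + 1
            try:
                if p + q == 0:
                    f = objective(np.zeros(0), 0, 0, YX, n)
                    u_hat = np.zeros(0)
                else:
                    start = np.zeros(p + q) if u0 is None else np.clip(u0, -_UBOUND, _UBOUND)
                    res = _minimize_profiled(
                        "cond" if approximation else "exact",
                        start, p, q, YX, n, maxiter=40, ftol=1e-8,
                    )
                    f = res.fun
                    u_hat = res.x
                    phi_c, theta_c = unconstrained_to_arma(u_hat, p, q)
                    if _has_near_unit_root(phi_c, theta_c):
                        f = np.inf
                aicc = 2.0 * f + 2.0 * k + aicc_penalty(n, k)
                if np.isfinite(aicc):
                    out = ((aicc, p + q, q), u_hat)
            except (ValueError, np.linalg.LinAlgError):
                out = None
        cache[key] = out
        return out

    best: tuple[int, int] | None = None
    best_entry = None
    for p0, q0 in _START_ORDERS:
        entry = score(p0, q0)
        if entry is not None and (best_entry is None or entry[0] < best_entry[0]):
            best, best_entry = (p0, q0), entry
    if best is None:
        raise RuntimeError(
            f"no ARMA candidate model could be fitted (n={n}, {kb} regressors)"
        )

    moves = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1))
    improved = True
    while improved:
        improved = False
        for dp, dq in moves:
            cand = (best[0] + dp, best[1] + dq)
            if not feasible(*cand):
                continue
            u0 = embed(best_entry[1], best[0], best[1], *cand)
            entry = score(*cand, u0=u0)
            if entry is not None and entry[0] < best_entry[0]:
                best, best_entry = cand, entry
                improved = True
                break
    # refit the winner by exact ML, warm-started from the search optimum so the
    # returned fit corresponds to the mode that won the AICc comparison
    return fit_arma_regression(
        design, y, p=best[0], q=best[1], use_t=use_t, start_u=best_entry[1]
    )
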