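"""Numerical kernels for regression with ARMA errors.

Contains the state-space representation of a stationary ARMA(p,q) process
(Harvey form), its stationary autocovariance, a Kalman-filter whitening
pass that evaluates the exact Gaussian likelihood, the conditional
(innovations-recursion) whitening pass, and the partial-autocorrelation
reparameterisation used to keep optimizers inside the
stationary/invertible region.

Both whitening passes are linear operators on the input series, so they are
applied simultaneously to the response and to every design column; the
regression coefficients can then be profiled out by ordinary least squares
on the whitened variables.  The hot loops are numba-jitted, with a pure
NumPy fallback if JIT compilation is unavailable.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# ---------------------------------------------------------------------------
# stationarity / invertibility reparameterisation
# ---------------------------------------------------------------------------

def pacf_to_ar(r: np.ndarray) -> np.ndarray:
    """Durbin-Levinson map from partial autocorrelations to AR coefficients.

    For |r_i| < 1 the returned coefficients a satisfy: 1 - a1 z - ... - ap z^p
    has all roots outside the unit circle (stationarity).
    """
    r = np.asarray(r, dtype=float)
    p = len(r)
    a = np.zeros(p)
    for k in range(p):
        new = a.copy()
        new[k] = r[k]
        for j in range(k):
            new[j] = a[j] - r[k] * a[k - 1 - j]
        a = new
    return a


def ar_to_pacf(a: np.ndarray) -> np.ndarray:
    """Inverse Durbin-Levinson (reverse Levinson recursion)."""
    a = np.asarray(a, dtype=float).copy()
    p = len(a)
    r = np.zeros(p)
    for k in range(p - 1, -1, -1):
        r[k] = a[k]
        if abs(r[k]) >= 1.0:
            r[k] = np.sign(r[k]) * 0.9999
        if k > 0:
            denom = 1.0 - r[k] ** 2
            prev = np.zeros(k)
            for j in range(k):
                prev[j] = (a[j] + r[k] * a[k - 1 - j]) / denom
            a = prev
    return r


def unconstrained_to_arma(u: np.ndarray, p: int, q: int):
    """Map unconstrained coordinates to (phi, theta) in the valid region.

    tanh maps each coordinate to a partial autocorrelation in (-1, 1);
    Durbin-Levinson then yields a stationary AR polynomial.  For the MA
    side the same construction with a sign flip yields an invertible
    1 + theta1 z + ... + thetaq z^q.
    """
    u = np.asarray(u, dtype=float)
    phi = pacf_to_ar(np.tanh(u[:p])) if p else np.zeros(0)
    theta = -pacf_to_ar(np.tanh(u[p : p + q])) if q else np.zeros(0)
    return phi, theta


def arma_to_unconstrained(phi: np.ndarray, theta: np.ndarray) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    parts = []
    if len(phi):
        parts.append(np.arctanh(np.clip(ar_to_pacf(phi), -0.9999, 0.9999)))
    if len(theta):
        parts.append(np.arctanh(np.clip(ar_to_pacf(-theta), -0.9999, 0.9999)))
    if not parts:
        return np.zeros(0)
    return np.concatenate(parts)


def is_stationary(phi: np.ndarray) -> bool:
    phi = np.asarray(phi, dtype=float)
    if len(phi) == 0:
        return True
    roots = np.roots(np.concatenate(([1.0], -phi))[::-1])
    return bool(len(roots) == 0 or np.min(np.abs(roots)) > 1.0)


def is_invertible(theta: np.ndarray) -> bool:
    theta = np.asarray(theta, dtype=float)
    if len(theta) == 0:
        return True
    roots = np.roots(np.concatenate(([1.0], theta))[::-1])
    return bool(len(roots) == 0 or np.min(np.abs(roots)) > 1.0)


# ---------------------------------------------------------------------------
# state space form and autocovariance
# ---------------------------------------------------------------------------

def state_space(phi: np.ndarray, theta: np.ndarray):
    """Harvey companion form: alpha_{t+1} = T alpha_t + R eta_{t+1}, eps_t = alpha_t[0]."""
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    p, q = len(phi), len(theta)
    m = max(p, q + 1)
    T = np.zeros((m, m))
    T[: p, 0] = phi
    T[:-1, 1:] = np.eye(m - 1)
    R = np.zeros(m)
    R[0] = 1.0
    R[1 : q + 1] = theta
    return T, R


def stationary_state_cov(T: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Solve P = T P T' + R R' (unit innovation variance).

    The state dimension is max(p, q+1) <= 6 for the orders this package
    fits, so the Kronecker linear system is solved directly.
    """
    m = T.shape[0]
    A = np.eye(m * m) - np.kron(T, T)
    b = np.outer(R, R).ravel()
    try:
        vec = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        # AR parameters numerically on the unit circle: least-squares fallback
        vec = np.linalg.lstsq(A, b, rcond=None)[0]
    P = vec.reshape(m, m)
    return 0.5 * (P + P.T)


def arma_acovf(phi, theta, nlags: int, sigma2: float = 1.0) -> np.ndarray:
    """Autocovariance gamma_0..gamma_{nlags-1} of a stationary ARMA process.

    Computed from the stationary state covariance: gamma_k = (T^k P)[0, 0].
    """
    T, R = state_space(phi, theta)
    P = stationary_state_cov(T, R)
    v = P[:, 0].copy()
    gamma = np.empty(nlags)
    for k in range(nlags):
        gamma[k] = v[0]
        v = T @ v
    return sigma2 * gamma


# ---------------------------------------------------------------------------
# whitening kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _kalman_whiten_jit(T, R, P0, Y):  # pragma: no cover - jitted
    n, c = Y.shape
    m = T.shape[0]
    a = np.zeros((m, c))
    P = P0.copy()
    W = np.empty((n, c))
    sumlogF = 0.0
    RR = np.outer(R, R)
    ok = True
    steady = False
    F = 1.0
    sqrtF = 1.0
    logF = 0.0
    K = np.zeros(m)
    for t in range(n):
        if not steady:
            F = P[0, 0]
            if F <= 1e-13:
                ok = False
                F = 1e-13
            sqrtF = np.sqrt(F)
            logF = np.log(F)
            TP = T @ P
            K = TP[:, 0] / F
            Pn = TP @ T.T - F * np.outer(K, K) + RR
            Pn = 0.5 * (Pn + Pn.T)
            # filter reaches steady state geometrically; freeze K and F then
            if np.max(np.abs(Pn - P)) < 1e-13:
                steady = True
            P = Pn
        sumlogF += logF
        v = Y[t] - a[0]
        W[t] = v / sqrtF
        a = T @ a + np.outer(K, v)
    return W, sumlogF, ok


def _kalman_whiten_py(T, R, P0, Y):
    n, c = Y.shape
    m = T.shape[0]
    a = np.zeros((m, c))
    P = P0.copy()
    W = np.empty((n, c))
    sumlogF = 0.0
    RR = np.outer(R, R)
    ok = True
    for t in range(n):
        F = P[0, 0]
        if F <= 1e-13:
            ok = False
            F = 1e-13
        sumlogF += np.log(F)
        v = Y[t] - a[0]
        W[t] = v / np.sqrt(F)
        TP = T @ P
        K = TP[:, 0] / F
        a = T @ a + np.outer(K, v)
        P = TP @ T.T - F * np.outer(K, K) + RR
        P = 0.5 * (P + P.T)
    return W, sumlogF, ok


def kalman_whiten(phi, theta, Y: np.ndarray):
    """Exact-likelihood whitening of the columns of Y under ARMA(p,q) errors.

    Returns (W, sumlogF, ok) with W the innovation-standardised columns
    (unit innovation variance) and sumlogF the sum of log innovation
    variance ratios; the exact Gaussian log-likelihood of a series y with
    innovation variance s2 is

        -n/2 log(2 pi s2) - sumlogF/2 - ||W_y||^2 / (2 s2).
    """
    T, R = state_space(phi, theta)
    P0 = stationary_state_cov(T, R)
    fn = _kalman_whiten_jit if _HAVE_NUMBA else _kalman_whiten_py
    return fn(T, R, P0, np.ascontiguousarray(Y, dtype=np.float64))


@njit(cache=True)
def _conditional_whiten_jit(phi, theta, Y):  # pragma: no cover - jitted
    n, c = Y.shape
    p = phi.shape[0]
    q = theta.shape[0]
    H = np.zeros((n, c))  # innovations eta_t per column; zero for t < p
    for t in range(p, n):
        for j in range(c):
            acc = Y[t, j]
            for i in range(p):
                acc -= phi[i] * Y[t - 1 - i, j]
            for i in range(q):
                if t - 1 - i >= p:
                    acc -= theta[i] * H[t - 1 - i, j]
            H[t, j] = acc
    return H[p:]


def _conditional_whiten_py(phi, theta, Y):
    n, c = Y.shape
    p, q = len(phi), len(theta)
    H = np.zeros((n, c))
    for t in range(p, n):
        acc = Y[t].copy()
        for i in range(p):
            acc -= phi[i] * Y[t - 1 - i]
        for i in range(q):
            if t - 1 - i >= p:
                acc -= theta[i] * H[t - 1 - i]
        H[t] = acc
    return H[p:]


LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def _dl_transform_jit(u, p, q):  # pragma: no cover - jitted
    """tanh + Durbin-Levinson map from unconstrained u to (phi, theta)."""
    phi = np.zeros(p)
    theta = np.zeros(q)
    for k in range(p):
        rk = np.tanh(u[k])
        new = phi.copy()
        new[k] = rk
        for j in range(k):
            new[j] = phi[j] - rk * phi[k - 1 - j]
        phi = new
    a = np.zeros(q)
    for k in range(q):
        rk = np.tanh(u[p + k])
        new = a.copy()
        new[k] = rk
        for j in range(k):
            new[j] = a[j] - rk * a[k - 1 - j]
        a = new
    for k in range(q):
        theta[k] = -a[k]
    return phi, theta


@njit(cache=True)
def _neg_exact_jit(u, p, q, YX):  # pragma: no cover - jitted
    """Concentrated (beta, sigma2 profiled out) negative exact log-likelihood."""
    n, c1 = YX.shape
    phi, theta = _dl_transform_jit(u, p, q)
    m = max(p, q + 1)
    T = np.zeros((m, m))
    for i in range(p):
        T[i, 0] = phi[i]
    for i in range(m - 1):
        T[i, i + 1] = 1.0
    R = np.zeros(m)
    R[0] = 1.0
    for i in range(q):
        R[i + 1] = theta[i]
    # stationary state covariance: (I - T (x) T) vec(P) = vec(R R')
    mm = m * m
    A = np.zeros((mm, mm))
    for i in range(m):
        for j in range(m):
            for a_ in range(m):
                for b_ in range(m):
                    A[i * m + a_, j * m + b_] = -T[i, j] * T[a_, b_]
    for i in range(mm):
        A[i, i] += 1.0
    bvec = np.outer(R, R).ravel()
    P = np.linalg.solve(A, bvec).reshape((m, m)).copy()
    P = 0.5 * (P + P.T)
    RR = np.outer(R, R)
    a = np.zeros((m, c1))
    W = np.empty((n, c1))
    sumlogF = 0.0
    steady = False
    F = 1.0
    sqrtF = 1.0
    logF = 0.0
    K = np.zeros(m)
    for t in range(n):
        if not steady:
            F = P[0, 0]
            if F <= 1e-13:
                F = 1e-13
            sqrtF = np.sqrt(F)
            logF = np.log(F)
            TP = T @ P
            K = TP[:, 0] / F
            Pn = TP @ T.T - F * np.outer(K, K) + RR
            Pn = 0.5 * (Pn + Pn.T)
            if np.max(np.abs(Pn - P)) < 1e-13:
                steady = True
            P = Pn
        sumlogF += logF
        v = YX[t] - a[0]
        W[t] = v / sqrtF
        a = T @ a + np.outer(K, v)
    wy = W[:, 0].copy()
    Wx = W[:, 1:].copy()
    G = Wx.T @ Wx
    beta = np.linalg.solve(G, Wx.T @ wy)
    r = wy - Wx @ beta
    rss = r @ r
    if rss <= 0.0 or not np.isfinite(rss):
        return 1e12
    s2 = rss / n
    return 0.5 * n * (LOG2PI + np.log(s2) + 1.0) + 0.5 * sumlogF


@njit(cache=True)
def _neg_cond_jit(u, p, q, YX):  # pragma: no cover - jitted
    """Concentrated negative conditional log-likelihood."""
    n, c1 = YX.shape
    phi, theta = _dl_transform_jit(u, p, q)
    H = np.zeros((n, c1))
    for t in range(p, n):
        for j in range(c1):
            acc = YX[t, j]
            for i in range(p):
                acc -= phi[i] * YX[t - 1 - i, j]
            for i in range(q):
                if t - 1 - i >= p:
                    acc -= theta[i] * H[t - 1 - i, j]
            H[t, j] = acc
    mobs = n - p
    if mobs <= c1:
        return 1e12
    hy = H[p:, 0].copy()
    Hx = H[p:, 1:].copy()
    G = Hx.T @ Hx
    beta = np.linalg.solve(G, Hx.T @ hy)
    r = hy - Hx @ beta
    rss = r @ r
    if rss <= 0.0 or not np.isfinite(rss):
        return 1e12
    s2 = rss / mobs
    return 0.5 * mobs * (LOG2PI + np.log(s2) + 1.0)


@njit(cache=True)
def _fg_exact_jit(u, p, q, YX, h):  # pragma: no cover - jitted
    f0 = _neg_exact_jit(u, p, q, YX)
    g = np.empty(len(u))
    for i in range(len(u)):
        up = u.copy()
        up[i] += h
        g[i] = (_neg_exact_jit(up, p, q, YX) - f0) / h
    return f0, g


@njit(cache=True)
def _fg_cond_jit(u, p, q, YX, h):  # pragma: no cover - jitted
    f0 = _neg_cond_jit(u, p, q, YX)
    g = np.empty(len(u))
    for i in range(len(u)):
        up = u.copy()
        up[i] += h
        g[i] = (_neg_cond_jit(up, p, q, YX) - f0) / h
    return f0, g


def conditional_whiten(phi, theta, Y: np.ndarray) -> np.ndarray:
    """Conditional-likelihood innovations of the columns of Y.

    Pre-sample innovations (t < p) are fixed at zero and the first p values
    of the series are conditioned on, so n - p innovations are returned.
    The recursion is linear in Y, which lets the regression coefficients be
    profiled out exactly as in the exact-likelihood case.
    """
    phi = np.asarray(phi, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    fn = _conditional_whiten_jit if _HAVE_NUMBA else _conditional_whiten_py
    return fn(phi, theta, np.ascontiguousarray(Y, dtype=np.float64))
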