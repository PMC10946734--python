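"""OLS fitting of the segmented model and Newey-West HAC inference.

OLS point estimates of the intervention effect are unbiased even under
autocorrelated errors; what breaks is the classical variance.  The
Newey-West approach keeps the OLS point estimates and replaces the
classical variance with a heteroskedasticity-and-autocorrelation-consistent
(HAC) sandwich built from Bartlett-weighted residual autocovariances up to
a truncation lag m.  Several rules for choosing m are provided, including
the data-dependent plug-in rule of Newey & West (1994), which is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import ItsDesign
from .results import FitResult

__all__ = [
    "HacConfig",
    "fit_ols",
    "select_lag",
    "auto_lag_1994",
    "hac_vcov",
    "fit_newey_west",
]

_LAG_RULES = ("fixed", "n_quarter", "nw_simple", "fixed_b", "auto1994")


@dataclass
class HacConfig:
    """HAC variance configuration: lag rule, fixed lag, prewhitening flag."""

    rule: str = "auto1994"
    m: int | None = None
    prewhiten: bool = False
    use_t: bool = False  # standard-normal reference by default, t(n-k) if True

    def __post_init__(self) -> None:
        if self.rule not in _LAG_RULES:
            raise ValueError(f"unknown lag rule {self.rule!r}; expected one of {_LAG_RULES}")
        if self.rule == "fixed":
            if self.m is None or self.m < 0 or int(self.m) != self.m:
                raise ValueError("rule='fixed' requires a non-negative integer m")


def _ols_core(X: np.ndarray, y: np.ndarray):
    """Coefficients, residuals and (X'X)^{-1} via QR."""
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    Rinv = np.linalg.inv(R)
    xtx_inv = Rinv @ Rinv.T
    return beta, resid, xtx_inv


def fit_ols(design: ItsDesign, y: np.ndarray | None = None) -> FitResult:
    """Classical OLS: vcov = s^2 (X'X)^{-1}, t(n-k) reference distribution.

    A numerically perfect fit (zero residual variance) is flagged
    ``degenerate`` since the standard error is then undefined.
    """
    y = design.y if y is None else np.asarray(y, dtype=float)
    if y is None:
        raise ValueError("no response attached to the design and none supplied")
    X = design.matrix()
    n, k = X.shape
    beta, resid, xtx_inv = _ols_core(X, y)
    dof = n - k
    rss = float(resid @ resid)
    sigma2 = rss / dof
    degenerate = rss <= max(1e-12 * float(y @ y), 1e-300)
    return FitResult(
        method="ols",
        names=design.names,
        betas=beta,
        vcov=sigma2 * xtx_inv,
        df=float(dof),
        beta1_index=design.beta1_index,
        degenerate=degenerate,
        extras={"sigma2": sigma2, "resid": resid},
    )


def select_lag(n: int, rule: str, m: int | None = None) -> int:
    """Deterministic lag-truncation rules for the HAC variance.

    ``n_quarter``: floor(n^{1/4}) — the rate condition from the original
    consistency proof.  ``nw_simple``: floor(0.75 n^{1/3}) — a plug-in rule
    simplified under AR(1) correlation 0.25.  ``fixed_b``: floor(1.3 n^{1/2})
    — intended for use with fixed-b critical values (only the bandwidth rule
    is implemented here; standard quantiles are used).
    """
    if n < 4:
        raise ValueError("need n >= 4 to select a lag")
    if rule == "fixed":
        if m is None:
            raise ValueError("rule='fixed' requires m")
        out = int(m)
    elif rule == "n_quarter":
        out = int(np.floor(n ** 0.25))
    elif rule == "nw_simple":
        out = int(np.floor(0.75 * n ** (1.0 / 3.0)))
    elif rule == "fixed_b":
        out = int(np.floor(1.3 * np.sqrt(n)))
    else:
        raise ValueError(f"unknown lag rule {rule!r}")
    return int(np.clip(out, 0, n - 1))


def auto_lag_1994(design: ItsDesign, residuals: np.ndarray) -> int:
    """Newey & West (1994) automatic lag selection for the Bartlett kernel.

    Uses the score series of the intervention coefficient,
    v_t = x_t * resid_t.  With initial window l = floor(4 (n/100)^{2/9}),
    weighted autocovariance sums s0 = sigma0 + 2 sum_{j<=l} sigma_j and
    s1 = 2 sum_{j<=l} j sigma_j give

        m = floor( 1.1447 * (s1/s0)^{2/3} * n^{1/3} ),

    clipped to [0, n-1].  Degenerate scores (s0 = 0) yield m = 0.
    """
    resid = np.asarray(residuals, dtype=float)
    n = design.n
    v = design.x * resid
    l = int(np.floor(4.0 * (n / 100.0) ** (2.0 / 9.0)))
    sig = np.empty(l + 1)
    for j in range(l + 1):
        sig[j] = float(v[j:] @ v[: n - j]) / n
    s0 = sig[0] + 2.0 * sig[1:].sum()
    s1 = 2.0 * float(np.arange(1, l + 1) @ sig[1:])
    if s0 <= 0:
        return 0
    gamma = 1.1447 * np.abs(s1 / s0) ** (2.0 / 3.0)
    m = int(np.floor(gamma * n ** (1.0 / 3.0)))
    return int(np.clip(m, 0, n - 1))


def _prewhiten(U: np.ndarray):
    """Fit a VAR(1) to the score columns; return filtered scores and (I-A)^{-1}."""
    k = U.shape[1]
    U0, U1 = U[:-1], U[1:]
    A, *_ = np.linalg.lstsq(U0, U1, rcond=None)
    # guard against explosive coefficient matrices
    eig = np.max(np.abs(np.linalg.eigvals(A.T)))
    if eig >= 0.97:
        A = A * (0.97 / eig)
    V = U1 - U0 @ A
    D = np.linalg.inv(np.eye(k) - A.T)
    return V, D


def hac_vcov(design: ItsDesign, residuals: np.ndarray, config: HacConfig) -> np.ndarray:
    """Bartlett-kernel HAC sandwich variance of the OLS coefficients.

    vcov = (X'X)^{-1} S (X'X)^{-1} with
    S = sum_{j=-m}^{m} w_{|j|} sum_t u_t u_{t-j}',  u_t = x_t * resid_t,
    Bartlett weights w_j = 1 - j/(m+1).  The Bartlett kernel guarantees a
    positive semi-definite S.
    """
    resid = np.asarray(residuals, dtype=float)
    X = design.matrix()
    n = X.shape[0]
    if config.rule == "auto1994":
        m = auto_lag_1994(design, resid)
    else:
        m = select_lag(n, config.rule, config.m)
    if m >= n:
        raise ValueError(f"lag m={m} must be smaller than n={n}")
    U = X * resid[:, None]
    D = None
    if config.prewhiten:
        U, D = _prewhiten(U)
    S = U.T @ U
    for j in range(1, min(m, len(U) - 1) + 1):
        w = 1.0 - j / (m + 1.0)
        G = U[j:].T @ U[:-j]
        S += w * (G + G.T)
    if D is not None:
        S = D.T @ S @ D
    xtx_inv = np.linalg.inv(X.T @ X)
    V = xtx_inv @ S @ xtx_inv
    return 0.5 * (V + V.T)


def fit_newey_west(
    design: ItsDesign, y: np.ndarray | None = None, config: HacConfig | None = None
) -> FitResult:
    """OLS point estimates with Newey-West HAC standard errors."""
    config = config or HacConfig()
    base = fit_ols(design, y)
    resid = base.extras["resid"]
    if config.rule == "auto1994":
        m = auto_lag_1994(design, resid)
        cfg = HacConfig(rule="fixed", m=m, prewhiten=config.prewhiten, use_t=config.use_t)
    else:
        m = select_lag(design.n, config.rule, config.m)
        cfg = config
    vcov = hac_vcov(design, resid, cfg)
    return FitResult(
        method="nw",
        names=design.names,
        betas=base.betas,
        vcov=vcov,
        df=float(design.n - design.k) if config.use_t else np.inf,
        beta1_index=design.beta1_index,
        degenerate=base.degenerate,
        extras={"m": m, "rule": config.rule},
    )
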