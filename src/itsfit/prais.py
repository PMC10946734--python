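"""Prais-Winsten and Cochrane-Orcutt feasible GLS under AR(1) errors.

Both methods assume the regression error follows a first-order
autoregressive process eps_t = phi1 * eps_{t-1} + eta_t with |phi1| < 1 and
decorrelate it by quasi-differencing: every variable v is replaced by
v_t - phi1 * v_{t-1}.  Cochrane-Orcutt drops the first observation;
Prais-Winsten keeps it, rescaled by sqrt(1 - phi1^2) so its error variance
matches the rest of the series, which buys precision on short series.  The
intercept becomes a constructed regressor z (z_t = 1 - phi1 for t >= 1,
z_0 = sqrt(1 - phi1^2)), and the transformed regression is fitted without
an intercept.  phi1 is estimated from the lag-1 regression of OLS
residuals on themselves and, by default, re-estimated iteratively until it
stabilises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import ItsDesign
from .ols_hac import _ols_core, fit_ols
from .results import FitResult

__all__ = [
    "Ar1Estimate",
    "estimate_phi1",
    "pw_transform",
    "fit_prais_winsten",
    "fit_cochrane_orcutt",
]

PHI_CAP = 0.999


@dataclass
class Ar1Estimate:
    phi1: float
    iterations: int = 1
    converged: bool = True
    truncated: bool = False


def estimate_phi1(residuals: np.ndarray, include_intercept: bool = False) -> Ar1Estimate:
    """Slope from regressing resid_t on resid_{t-1}.

    The residuals are mean-zero by construction when they come from a model
    with an intercept, so the lag regression omits its own intercept by
    default; either variant is a consistent estimator of phi1.  Estimates
    outside (-1, 1) are truncated to +/-0.999 and flagged.
    """
    e = np.asarray(residuals, dtype=float)
    if len(e) < 3:
        raise ValueError("need at least 3 residuals to estimate phi1")
    if np.allclose(e, e[0]):
        raise ValueError("constant residuals: no variation to estimate phi1 from")
    e0, e1 = e[:-1], e[1:]
    if include_intercept:
        Z = np.column_stack([np.ones_like(e0), e0])
        coef, *_ = np.linalg.lstsq(Z, e1, rcond=None)
        phi = float(coef[1])
    else:
        denom = float(e0 @ e0)
        if denom == 0.0:
            raise ValueError("lagged residuals are all zero")
        phi = float(e0 @ e1) / denom
    truncated = abs(phi) >= 1.0
    if truncated:
        phi = float(np.sign(phi)) * PHI_CAP
    return Ar1Estimate(phi1=phi, truncated=truncated)


def pw_transform(
    design: ItsDesign, y: np.ndarray, phi1: float, drop_first: bool = False
):
    """Quasi-difference the response and every design column.

    Returns (Xt, yt, names) where the intercept has become the constructed
    column z (z_0 = sqrt(1-phi1^2), z_t = 1-phi1 for t >= 1).  With
    ``drop_first`` the t=0 row is removed instead of rescaled
    (Cochrane-Orcutt).
    """
    if not abs(phi1) < 1.0:
        raise ValueError(f"|phi1| must be < 1, got {phi1}")
    y = np.asarray(y, dtype=float)
    X = design.matrix()
    n = design.n
    scale0 = np.sqrt(1.0 - phi1 ** 2)
    Xt = np.empty_like(X)
    yt = np.empty_like(y)
    Xt[1:] = X[1:] - phi1 * X[:-1]
    yt[1:] = y[1:] - phi1 * y[:-1]
    Xt[0] = scale0 * X[0]
    yt[0] = scale0 * y[0]
    # the intercept column turns into the constructed regressor z
    Xt[0, 0] = scale0
    Xt[1:, 0] = 1.0 - phi1
    names = ["z"] + design.names[1:]
    if drop_first:
        return Xt[1:], yt[1:], names
    return Xt, yt, names


def _fit_fgls(
    design: ItsDesign,
    y: np.ndarray | None,
    drop_first: bool,
    iterate: bool,
    tol: float,
    max_iter: int,
    phi1: float | None,
    method: str,
) -> FitResult:
    y = design.y if y is None else np.asarray(y, dtype=float)
    if y is None:
        raise ValueError("no response attached to the design and none supplied")
    X = design.matrix()
    n, k = X.shape

    fixed_phi = phi1 is not None
    if fixed_phi:
        phi = float(phi1)
        iterations = 0
        converged = True
        truncated = False
    else:
        ols = fit_ols(design, y)
        est = estimate_phi1(ols.extras["resid"])
        phi = est.phi1
        truncated = est.truncated
        iterations = 1
        converged = not iterate

    while True:
        Xt, yt, names = pw_transform(design, y, phi, drop_first=drop_first)
        beta, resid_t, xtx_inv = _ols_core(Xt, yt)
        if fixed_phi or not iterate:
            if fixed_phi:
                converged = True
            break
        # re-estimate phi1 from residuals on the original scale
        resid_raw = y - X @ beta
        est = estimate_phi1(resid_raw)
        truncated = truncated or est.truncated
        delta = abs(est.phi1 - phi)
        phi = est.phi1
        iterations += 1
        if delta < tol:
            converged = True
            break
        if iterations >= max_iter:
            converged = False
            break

    dof = len(yt) - k if drop_first else n - k
    sigma2 = float(resid_t @ resid_t) / dof
    return FitResult(
        method=method,
        names=names,
        betas=beta,
        vcov=sigma2 * xtx_inv,
        df=float(dof),
        beta1_index=design.beta1_index,
        converged=converged,
        extras={"phi1": phi, "iterations": iterations, "phi1_truncated": truncated},
    )


def fit_prais_winsten(
    design: ItsDesign,
    y: np.ndarray | None = None,
    iterate: bool = True,
    tol: float = 1e-6,
    max_iter: int = 50,
    phi1: float | None = None,
) -> FitResult:
    """Prais-Winsten feasible GLS (first observation retained and rescaled).

    ``phi1`` fixes the AR coefficient instead of estimating it (useful for
    oracle comparisons: with the true phi1 this is exact GLS).  With
    ``iterate`` (default) the residual/phi1 update is repeated until
    |delta phi1| < tol or ``max_iter`` is reached; non-convergence is
    reported via ``converged=False``, never raised.  Confidence intervals
    use t with n-k degrees of freedom.
    """
    return _fit_fgls(design, y, False, iterate, tol, max_iter, phi1, "pw")


def fit_cochrane_orcutt(
    design: ItsDesign,
    y: np.ndarray | None = None,
    iterate: bool = True,
    tol: float = 1e-6,
    max_iter: int = 50,
    phi1: float | None = None,
) -> FitResult:
    """Cochrane-Orcutt feasible GLS (first observation dropped)."""
    return _fit_fgls(design, y, True, iterate, tol, max_iter, phi1, "co")
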