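"""Common result container for all interrupted-time-series estimators.

Every fitting routine in this package returns a :class:`FitResult` so that
downstream code (the simulation engine, the CLI report writer) can treat
OLS, Prais-Winsten, Newey-West, ARMA-ML and REML fits uniformly.  The
quantity of scientific interest is always the intervention (level-change)
coefficient, so the container carries its standard error, reference
distribution and 95% confidence interval explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats


@dataclass
class FitResult:
    """Method-tagged regression fit of the segmented model.

    Parameters
    ----------
    method:
        Tag identifying the estimator, e.g. ``"ols"``, ``"nw"``, ``"pw"``,
        ``"co"``, ``"arma"``, ``"ma3"``, ``"reml_kr"``.
    names:
        Column names of the design matrix, in estimation order.
    betas:
        Point estimates of the regression coefficients.
    vcov:
        Estimated variance matrix of ``betas`` (symmetric PSD).
    df:
        Degrees of freedom of the reference t distribution for the
        intervention-effect test statistic; ``numpy.inf`` means a standard
        normal reference.
    beta1_index:
        Position of the intervention coefficient in ``betas``.
    converged:
        False when an iterative component hit its limit or an optimizer
        reported failure; estimates are still the best available.
    extras:
        Method-specific diagnostics (AR coefficient, ARMA order, HAC lag,
        Satterthwaite df, ...).
    """

    method: str
    names: list[str]
    betas: np.ndarray
    vcov: np.ndarray
    df: float
    beta1_index: int = 1
    converged: bool = True
    degenerate: bool = False
    extras: dict[str, Any] = field(default_factory=dict)

    @property
    def beta1(self) -> float:
        return float(self.betas[self.beta1_index])

    @property
    def se_beta1(self) -> float:
        return float(np.sqrt(self.vcov[self.beta1_index, self.beta1_index]))

    @property
    def crit(self) -> float:
        """97.5% point of the reference distribution (t with ``df``, or normal)."""
        if np.isinf(self.df):
            return float(stats.norm.ppf(0.975))
        return float(stats.t.ppf(0.975, self.df))

    @property
    def ci_beta1(self) -> tuple[float, float]:
        half = self.crit * self.se_beta1
        return (self.beta1 - half, self.beta1 + half)

    def se(self, j: int) -> float:
        return float(np.sqrt(self.vcov[j, j]))

    def ci(self, j: int) -> tuple[float, float]:
        half = self.crit * self.se(j)
        return (float(self.betas[j]) - half, float(self.betas[j]) + half)

    def to_row(self) -> dict[str, Any]:
        """Flatten to a CSV-friendly record."""
        lo, hi = self.ci_beta1
        row: dict[str, Any] = {
            "method": self.method,
            "beta1": self.beta1,
            "se_beta1": self.se_beta1,
            "df": self.df,
            "ci_lo": lo,
            "ci_hi": hi,
            "converged": self.converged,
        }
        for name, b in zip(self.names, self.betas):
            row[f"coef_{name}"] = float(b)
        for key, val in self.extras.items():
            row[f"extra_{key}"] = val
        return row
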