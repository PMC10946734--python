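"""Segmented-regression design for interrupted time series.

An interrupted time series (ITS) consists of n equally spaced observations
y_0..y_{n-1} of a population-level outcome, with an intervention starting at
time index tau.  The segmented regression model is

    y_t = beta0 + beta1 * x_t + beta2 * t + (covariates) + eps_t,

where x_t is the step indicator (0 before tau, 1 from tau on) and t the
linear trend.  beta1 is the level change attributable to the intervention.
This module builds the design matrix used both to simulate from the model
and to fit it, so simulation and estimation share one definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ItsDesign",
    "RegressionParams",
    "RankDeficientDesignError",
    "build_design",
    "read_its_csv",
]


class RankDeficientDesignError(ValueError):
    """Design matrix does not have full column rank."""


@dataclass
class RegressionParams:
    """True coefficients of the segmented model, used by the simulator.

    ``beta2 = None`` means "use -1/n at simulation time", the convention
    that keeps the total trend reduction over the series constant as n
    varies.  ``sigma2_eta`` is the innovation variance of the error process.
    """

    beta0: float = 4.0
    beta1: float = -1.0
    beta2: float | None = None
    extra_betas: dict[str, float] = field(default_factory=dict)
    sigma2_eta: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2_eta <= 0:
            raise ValueError("sigma2_eta must be positive")

    def trend_slope(self, n: int) -> float:
        return -1.0 / n if self.beta2 is None else self.beta2

    def mean(self, design: "ItsDesign") -> np.ndarray:
        """E[y] under the model, on the design's time grid."""
        mu = self.beta0 + self.beta1 * design.x
        if design.include_trend:
            mu = mu + self.trend_slope(design.n) * design.t
        for name, b in self.extra_betas.items():
            mu = mu + b * design.covariates[name]
        return mu


@dataclass
class ItsDesign:
    """Regression design for an ITS: step indicator, trend, covariates.

    ``y`` is optionally attached (by the simulator or the CSV reader); the
    design itself is identical whether used for simulation or fitting.
    """

    n: int
    tau: int
    include_trend: bool = True
    include_interaction: bool = False
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 < self.tau < self.n):
            raise ValueError(f"tau must lie strictly inside (0, n); got tau={self.tau}, n={self.n}")
        for name, col in self.covariates.items():
            col = np.asarray(col, dtype=float)
            if col.shape != (self.n,):
                raise ValueError(f"covariate {name!r} has length {len(col)}, expected n={self.n}")
            self.covariates[name] = col
        self._check_rank()

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n, dtype=float)

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.n) >= self.tau).astype(float)

    @property
    def names(self) -> list[str]:
        out = ["intercept", "x"]
        if self.include_trend:
            out.append("t")
        if self.include_interaction:
            out.append("x:t")
        out.extend(self.covariates)
        return out

    @property
    def beta1_index(self) -> int:
        return 1  # intervention column always follows the intercept

    @property
    def k(self) -> int:
        return 2 + int(self.include_trend) + int(self.include_interaction) + len(self.covariates)

    def matrix(self) -> np.ndarray:
        cols = [np.ones(self.n), self.x]
        if self.include_trend:
            cols.append(self.t)
        if self.include_interaction:
            cols.append(self.x * self.t)
        cols.extend(self.covariates.values())
        return np.column_stack(cols)

    def _check_rank(self) -> None:
        X = self.matrix()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            # identify a column whose removal restores full rank; scan from the
            # end so user-supplied covariates are blamed before core columns
            names = self.names
            for j, name in zip(range(len(names) - 1, -1, -1), reversed(names)):
                sub = np.delete(X, j, axis=1)
                if np.linalg.matrix_rank(sub) == sub.shape[1]:
                    raise RankDeficientDesignError(
                        f"design is rank deficient: column {name!r} is collinear "
                        "with the remaining columns"
                    )
            raise RankDeficientDesignError("design is rank deficient")

    def with_y(self, y: np.ndarray) -> "ItsDesign":
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError(f"y has length {len(y)}, expected {self.n}")
        return ItsDesign(
            n=self.n,
            tau=self.tau,
            include_trend=self.include_trend,
            include_interaction=self.include_interaction,
            covariates=dict(self.covariates),
            y=y,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": np.arange(self.n), "x": self.x})
        if self.include_trend:
            df["t"] = self.t
        for name, col in self.covariates.items():
            df[name] = col
        if self.y is not None:
            df.insert(1, "y", self.y)
        return df


def default_tau(n: int) -> int:
    """Balanced 1:1 pre/post split; odd n puts the extra point pre-intervention."""
    return (n + 1) // 2


def build_design(
    n: int,
    tau: int | None = None,
    include_trend: bool = True,
    covariates: dict[str, np.ndarray] | None = None,
    include_interaction: bool = False,
) -> ItsDesign:
    """Build the segmented-regression design.

    Parameters
    ----------
    n:
        Number of equally spaced observations (time index 0..n-1).
    tau:
        First post-intervention index; default ``(n+1)//2`` gives the
        balanced split (exactly 1:1 for even n).
    include_trend:
        Include the linear trend column t = 0..n-1.
    covariates:
        Named extra columns of length n (season dummies, strike flags, ...).
    include_interaction:
        Include the x*t interaction (changing intervention effect); off by
        default.
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    if tau is None:
        tau = default_tau(n)
    return ItsDesign(
        n=int(n),
        tau=int(tau),
        include_trend=include_trend,
        include_interaction=include_interaction,
        covariates=dict(covariates or {}),
    )


_REQUIRED_COLUMNS = ("time", "y", "x")


def read_its_csv(path, include_trend: bool = True) -> ItsDesign:
    """Read a user ITS from a delimited table.

    Requires a header with columns ``time``, ``y``, ``x``; any further
    columns are treated as named covariates.  Time points must be equally
    spaced and the intervention indicator must be a 0/1 step.  Missing
    values anywhere are rejected.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"input table is missing required column {col!r}")
    if df.isna().any().any():
        bad = [c for c in df.columns if df[c].isna().any()]
        raise ValueError(f"missing values in column(s) {bad}; impute or drop before analysis")
    df = df.sort_values("time").reset_index(drop=True)
    time = df["time"].to_numpy(dtype=float)
    steps = np.diff(time)
    if len(steps) and not np.allclose(steps, steps[0]):
        raise ValueError("time points must be equally spaced")
    x = df["x"].to_numpy(dtype=float)
    if not set(np.unique(x)) <= {0.0, 1.0}:
        raise ValueError("intervention column 'x' must be a 0/1 indicator")
    post = np.nonzero(x == 1.0)[0]
    if len(post) == 0 or len(post) == len(x):
        raise ValueError("intervention indicator must switch from 0 to 1 inside the series")
    tau = int(post[0])
    if not np.all(x[tau:] == 1.0) or not np.all(x[:tau] == 0.0):
        raise ValueError("intervention column 'x' must be a single upward step")
    covars = {
        c: df[c].to_numpy(dtype=float)
        for c in df.columns
        if c not in _REQUIRED_COLUMNS and c != "t"
    }
    design = build_design(
        n=len(df), tau=tau, include_trend=include_trend, covariates=covars
    )
    return design.with_y(df["y"].to_numpy(dtype=float))
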