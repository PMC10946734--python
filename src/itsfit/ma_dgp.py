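"""Synthetic-data generator: MA(3) error scenarios and the ITS simulator.

The study conditions emulated here are monthly surveillance-style series of
length 20-300 with a mid-series step intervention, a linear trend, and
positive autocorrelation that decreases over the first three lags and is
zero beyond lag 3.  Errors follow a moving-average process of order 3,

    eps_t = eta_t + theta1*eta_{t-1} + theta2*eta_{t-2} + theta3*eta_{t-3},

with iid standard-normal innovations eta_t.  Autocorrelation scenarios are
drawn from nested uniforms — theta1 ~ U(0,1), theta2 ~ U(0,theta1),
theta3 ~ U(0,theta2) — which constrains the implied lag-1..3
autocorrelations to be positive and decreasing (lag-1 below ~0.775).

Default regression coefficients are beta0 = 4, beta1 = -1, beta2 = -1/n
with unit innovation variance, i.e. an intervention-level drop and a total
trend drop of comparable size to the error scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ItsDesign, RegressionParams, build_design, default_tau

__all__ = ["MaScenario", "ma_acf", "sample_scenario", "sample_scenarios", "simulate_its"]

#: lag-1 autocorrelation strata used to label scenarios
LOW_RHO1 = 0.3
HIGH_RHO1 = 0.6


def ma_acf(thetas, max_lag: int = 3) -> np.ndarray:
    """Autocorrelation function of an MA(q) process at lags 1..max_lag.

    rho_k = (sum_{i=0}^{q-k} theta_i theta_{i+k}) / (sum_i theta_i^2) with
    theta_0 = 1, and rho_k = 0 exactly for k > q.
    """
    th = np.concatenate(([1.0], np.asarray(thetas, dtype=float)))
    q = len(th) - 1
    denom = float(th @ th)
    rho = np.zeros(max_lag)
    for k in range(1, max_lag + 1):
        if k <= q:
            rho[k - 1] = float(th[: q - k + 1] @ th[k:]) / denom
    return rho


def _label(rho1: float) -> str:
    if rho1 < LOW_RHO1:
        return "low"
    if rho1 < HIGH_RHO1:
        return "moderate"
    return "high"


@dataclass(frozen=True)
class MaScenario:
    """An MA(3) autocorrelation scenario.

    ``thetas`` are the moving-average coefficients, ``acf`` the implied
    lag-1..3 autocorrelations, and ``label`` the lag-1 stratum
    (low < 0.3 <= moderate < 0.6 <= high).
    """

    thetas: tuple[float, float, float]
    acf: tuple[float, float, float]
    label: str
    id: int = 0

    @staticmethod
    def from_thetas(thetas, id: int = 0) -> "MaScenario":
        t1, t2, t3 = (float(v) for v in thetas)
        rho = ma_acf((t1, t2, t3))
        return MaScenario(
            thetas=(t1, t2, t3),
            acf=(float(rho[0]), float(rho[1]), float(rho[2])),
            label=_label(rho[0]),
            id=id,
        )


def sample_scenario(rng: np.random.Generator, id: int = 0) -> MaScenario:
    """Draw one scenario: theta1 ~ U(0,1), theta2 ~ U(0,theta1), theta3 ~ U(0,theta2)."""
    t1 = rng.uniform(0.0, 1.0)
    t2 = rng.uniform(0.0, t1)
    t3 = rng.uniform(0.0, t2)
    return MaScenario.from_thetas((t1, t2, t3), id=id)


def sample_scenarios(n_scenarios: int, rng: np.random.Generator) -> list[MaScenario]:
    """Draw a scenario set, ordered by lag-1 autocorrelation (weakest first)."""
    raw = [sample_scenario(rng) for _ in range(n_scenarios)]
    raw.sort(key=lambda s: s.acf[0])
    return [
        MaScenario(thetas=s.thetas, acf=s.acf, label=s.label, id=i)
        for i, s in enumerate(raw)
    ]


def simulate_ma_errors(
    thetas, n: int, rng: np.random.Generator, sigma2_eta: float = 1.0
) -> np.ndarray:
    """Simulate n values of the MA error process, exactly stationary from t=0.

    Draws q pre-sample innovations so no burn-in transient remains.
    """
    th = np.concatenate(([1.0], np.asarray(thetas, dtype=float)))
    q = len(th) - 1
    eta = rng.standard_normal(n + q) * np.sqrt(sigma2_eta)
    if q == 0:
        return eta
    # eps_t = sum_j th[j] * eta_{t-j}; full convolution then trim edges
    return np.convolve(eta, th, mode="full")[q : q + n]


def simulate_its(
    scenario: MaScenario,
    n: int,
    rng: np.random.Generator,
    params: RegressionParams | None = None,
    tau: int | None = None,
) -> ItsDesign:
    """Simulate one ITS from the segmented model with MA(3) errors.

    Returns the design with the simulated response attached.  The
    intervention starts mid-series (tau = n/2) unless overridden.
    """
    if n < 8:
        raise ValueError("simulated series must have n >= 8")
    params = params or RegressionParams()
    design = build_design(n=n, tau=tau if tau is not None else default_tau(n))
    eps = simulate_ma_errors(scenario.thetas, n, rng, params.sigma2_eta)
    return design.with_y(params.mean(design) + eps)


def scenarios_to_frame(scenarios: list[MaScenario]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scenario_id": [s.id for s in scenarios],
            "theta1": [s.thetas[0] for s in scenarios],
            "theta2": [s.thetas[1] for s in scenarios],
            "theta3": [s.thetas[2] for s in scenarios],
            "rho1": [s.acf[0] for s in scenarios],
            "rho2": [s.acf[1] for s in scenarios],
            "rho3": [s.acf[2] for s in scenarios],
            "label": [s.label for s in scenarios],
        }
    )
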