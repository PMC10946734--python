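"""Shared fixtures.

The heavyweight Monte-Carlo fixtures are session-scoped so that the
coverage, RMSE, bias and power checks all read from a single study run.
Replicate counts are reduced relative to the full study (the
Monte-Carlo SE bands used in the assertions account for this).
"""

from __future__ import annotations

import numpy as np
import pytest

from itsfit import MaScenario, RegressionParams, StudyConfig, run_study, simulate_its

SEED = 20230201


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def moderate_series():
    """One moderately autocorrelated simulated ITS of length 50."""
    scen = MaScenario.from_thetas((0.5, 0.3, 0.15))
    return simulate_its(scen, 50, np.random.default_rng(SEED))


@pytest.fixture(scope="session")
def main_grid():
    """The scenario x length grid shared by the headline-metric checks.

    20 scenarios drawn from the nested-uniform prior, n in
    {20, 50, 100, 300}; closed-form arms at 300 replicates per cell, the
    likelihood-based arms at reduced counts (stepwise ARMA 40, MA-ML 100;
    MA(1)/MA(2) only on the short-series cells where they are compared).
    """
    cfg = StudyConfig(
        n_scenarios=20,
        n_grid=(20, 50, 100, 300),
        nsim=300,
        methods=("ols", "nw", "pw", "arma", "ma3", "ma1", "ma2"),
        master_seed=SEED,
        method_nsim={"arma": 40, "ma3": 100, "ma1": 100, "ma2": 100},
        method_max_n={"ma1": 50, "ma2": 50},
    )
    metrics, _ = run_study(cfg)
    return metrics


@pytest.fixture(scope="session")
def bias_grid():
    """High-replicate run of the closed-form arms on a 5-scenario subset."""
    cfg = StudyConfig(
        n_scenarios=5,
        n_grid=(20, 50, 100, 300),
        nsim=2000,
        methods=("ols", "nw", "pw", "co"),
        master_seed=SEED + 1,
        params=RegressionParams(),
    )
    metrics, _ = run_study(cfg)
    return metrics
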