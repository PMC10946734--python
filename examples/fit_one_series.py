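"""Fit one interrupted time series with every autocorrelation-aware method.

Simulates a monthly series of length 100 with a mid-series intervention
(level drop of 1), a mild downward trend, and moderately autocorrelated
MA(3) errors, then compares the intervention-effect estimate and 95% CI
across OLS, Prais-Winsten, Cochrane-Orcutt, Newey-West, stepwise-ARMA and
the true MA(3) maximum-likelihood fit.
"""

import numpy as np

from itsfit import (
    MaScenario,
    fit_arma_regression,
    fit_cochrane_orcutt,
    fit_newey_west,
    fit_ols,
    fit_prais_winsten,
    simulate_its,
    stepwise_select,
)

scenario = MaScenario.from_thetas((0.6, 0.4, 0.2))
print(f"scenario: theta={scenario.thetas}, lag-1..3 ACF={np.round(scenario.acf, 3)}")

series = simulate_its(scenario, n=100, rng=np.random.default_rng(7))

fits = [
    fit_ols(series),
    fit_prais_winsten(series),
    fit_cochrane_orcutt(series),
    fit_newey_west(series),
    stepwise_select(series).to_fit_result("arma"),
    fit_arma_regression(series, p=0, q=3).to_fit_result("ma3"),
]

print(f"\n{'method':<8}{'beta1':>9}{'SE':>8}{'95% CI':>20}  notes")
for f in fits:
    lo, hi = f.ci_beta1
    note = ", ".join(
        f"{k}={v}" for k, v in f.extras.items() if k in ("phi1", "m", "order")
    )
    print(f"{f.method:<8}{f.beta1:>9.3f}{f.se_beta1:>8.3f}  [{lo:>7.3f}, {hi:>7.3f}]  {note}")

print(
    "\nThe true effect is -1.  All methods give similar point estimates; the\n"
    "autocorrelation-aware methods report wider intervals than OLS because\n"
    "positively correlated errors make the OLS standard error too small."
)
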