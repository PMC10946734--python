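"""A small scenario x length Monte-Carlo comparison of estimators.

Runs 6 scenarios x n in {20, 50} x 200 replicates for OLS, Prais-Winsten
and Newey-West, then prints per-stratum means of coverage and root-MSE.
(The full study uses 20 scenarios, four lengths and 2000 replicates.)
"""

from itsfit import StudyConfig, aggregate, run_study

config = StudyConfig(
    n_scenarios=6,
    n_grid=(20, 50),
    nsim=200,
    methods=("ols", "pw", "nw"),
    master_seed=42,
)
metrics, _ = run_study(config)

print("all cells (unweighted means over scenario x length cells):")
print(aggregate(metrics).round(3).to_string(index=False))
print("\nhigh-autocorrelation stratum (lag-1 ACF >= 0.6):")
print(aggregate(metrics, "rho1 >= 0.6").round(3).to_string(index=False))
print(
    "\ncoverage is the fraction of replicates whose 95% CI contains the true\n"
    "effect (-1); under positive autocorrelation OLS under-covers while\n"
    "Prais-Winsten stays closest to 0.95.  rmse is the root mean squared\n"
    "error of the intervention-effect estimate."
)
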