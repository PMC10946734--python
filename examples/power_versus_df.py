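"""The price of an over-parameterised error model: degrees of freedom and power.

Simulates white-noise series (no autocorrelation at all) of length 50 and
compares OLS with the MA(3)-REML fit using the Kenward-Roger adjustment.
OLS tests the intervention effect against t(47); the Kenward-Roger
procedure spends most of those degrees of freedom on the three estimated
MA parameters, which widens its intervals and lowers power even though
both methods have (near-)nominal coverage here.
"""

from itsfit import power_experiment

summary, _ = power_experiment(
    n=50,
    nsim=400,
    methods=("ols", "ma3_reml_kr"),
    master_seed=99,
)
cols = ["method", "coverage", "power", "mean_df", "nsim_used"]
print(summary[cols].round(3).to_string(index=False))
print(
    "\nmean_df: OLS always uses 47; the Satterthwaite/Kenward-Roger df for the\n"
    "MA(3) model averages ~9-10.  power: fraction of replicates whose 95% CI\n"
    "excludes zero (the true effect is -1) - fewer df means wider intervals\n"
    "and less power."
)
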