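"""Draw MA(3) autocorrelation scenarios from the nested-uniform prior.

theta1 ~ U(0,1), theta2 ~ U(0,theta1), theta3 ~ U(0,theta2) constrains the
implied lag-1..3 autocorrelations to be positive and decreasing, with
lag-1 autocorrelation at most 0.75.  Scenarios are labelled by their lag-1
value: low (<0.3), moderate (<0.6), high (>=0.6).
"""

import numpy as np

from itsfit import sample_scenarios
from itsfit.ma_dgp import scenarios_to_frame

rng = np.random.default_rng(20230201)
scenarios = sample_scenarios(20, rng)
table = scenarios_to_frame(scenarios)
print(table.round(3).to_string(index=False))
print(
    f"\nlabels: {table['label'].value_counts().to_dict()}\n"
    "Each row is one error-process scenario for the simulation study; rho1..3\n"
    "are the exact lag-1..3 autocorrelations implied by the MA coefficients."
)
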