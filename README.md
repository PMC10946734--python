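# itsfit

Segmented-regression estimators for **interrupted time series (ITS)** with
autocorrelated errors, plus the Monte-Carlo machinery to evaluate them.

ITS studies measure a population-level outcome (disease incidence, hospital
admissions, prescribing rates, ...) at equally spaced times before and after
an event — a vaccine introduction, a policy change — and estimate the
event's impact from the level change in a segmented regression

```
y_t = β₀ + β₁ x_t + β₂ t + ε_t ,     t = 0, …, n−1,
```

where `x_t` is the intervention step indicator (0 before time τ, 1 after)
and β₁ is the intervention effect. Such series are almost always positively
autocorrelated, and ignoring that makes OLS confidence intervals
anticonservative. This package implements, from a single design object, the
methods practitioners use to deal with ε_t:

- **OLS** with classical t(n−k) inference (the naive baseline);
- **Newey-West**: OLS point estimates with Bartlett-kernel HAC standard
  errors, lag chosen by fixed rules (⌊n^1/4⌋, ⌊0.75 n^1/3⌋, ⌊1.3 n^1/2⌋) or
  the Newey-West (1994) automatic plug-in rule;
- **Prais-Winsten / Cochrane-Orcutt**: feasible GLS under an AR(1) error
  model, by iterated quasi-differencing (ỹ_t = y_t − φ̂₁ y_{t−1}, first
  observation rescaled by √(1−φ̂₁²) in the PW variant);
- **Regression with ARMA(p,q) errors** by exact maximum likelihood (Kalman
  filter / state-space innovations, with a dense multivariate-normal
  cross-check), including **stepwise AICc order selection** with p, q ≤ 5;
- **REML** estimation of the error model with **Satterthwaite degrees of
  freedom** (d = 2φ²/var(φ̂) for φ = var(β̂₁)) and the **Kenward-Roger**
  small-sample variance adjustment.

A synthetic-data module generates the evaluation conditions: MA(3) error
scenarios `ε_t = η_t + θ₁η_{t−1} + θ₂η_{t−2} + θ₃η_{t−3}` with
θ₁ ~ U(0,1), θ₂ ~ U(0,θ₁), θ₃ ~ U(0,θ₂) (positive, decreasing
autocorrelation up to lag 3, lag-1 below ~0.775), and series simulated from the segmented model
with β = (4, −1, −1/n) and unit innovation variance. A simulation engine
runs scenario × length × method grids and reports bias, empirical SE, RMSE,
coverage and power with Monte-Carlo standard errors.

## Worked example

```python
import numpy as np
from itsfit import MaScenario, simulate_its, fit_ols, fit_prais_winsten, fit_newey_west

scenario = MaScenario.from_thetas((0.6, 0.4, 0.2))   # lag-1 ACF 0.59
series = simulate_its(scenario, n=100, rng=np.random.default_rng(7))

for fit in (fit_ols(series), fit_prais_winsten(series), fit_newey_west(series)):
    lo, hi = fit.ci_beta1
    print(f"{fit.method:<4} beta1 = {fit.beta1:6.3f}  95% CI [{lo:6.3f}, {hi:6.3f}]")
```

prints

```
ols  beta1 = -0.574  95% CI [-1.464,  0.317]
pw   beta1 = -0.629  95% CI [-2.036,  0.779]
nw   beta1 = -0.574  95% CI [-1.938,  0.790]
```

The true effect is −1. All three point estimates are close (and unbiased in
repeated sampling), but the OLS interval is markedly narrower than the
autocorrelation-aware ones — exactly the anticonservatism that motivates
the adjusted methods. The `examples/` directory has one short script per
capability (scenario sampling, single-series fitting, a small simulation
study, the power/df trade-off, CSV analysis with log2 percent-reduction
reporting).

There is also a thin CLI:

```bash
itsfit simulate --n 100 --theta1 0.6 --theta2 0.4 --theta3 0.2 --out series.csv
itsfit analyze --input series.csv --method ols --method pw --method nw
itsfit scenarios --count 20 --out scenarios.csv
itsfit reproduce-study --out study_out --scale reduced
```

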