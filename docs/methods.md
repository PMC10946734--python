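# Methods

This note documents the statistical content of `itsfit`: the model, each
estimator's exact computation, what the synthetic-data generator does and
does not emulate, the numerical choices, and known limitations.

## The model

An interrupted time series is modelled by segmented regression

    y_t = beta0 + beta1 * x_t + beta2 * t + (covariates) + eps_t,   t = 0..n-1,

with x_t = 1{t >= tau} the intervention step and beta1 the level change of
interest. An optional x*t interaction (a changing intervention effect) is
supported but off by default. Time is 0-based and equally spaced; the
default intervention time tau = (n+1)//2 splits the series 1:1 (odd n puts
the extra point pre-intervention). The error eps_t is a stationary
zero-mean Gaussian process; the estimators differ only in how they treat
its autocorrelation. One `ItsDesign` object backs both simulation and
fitting, so the two can never drift apart.

## Estimators

**OLS.** Classical least squares, vcov = s^2 (X'X)^{-1} with
s^2 = RSS/(n-k), t(n-k) reference distribution. Under positively
correlated errors the point estimate remains unbiased but the SE is
downward-biased.

**Newey-West.** Keeps the OLS point estimates and replaces the variance by
the Bartlett-kernel HAC sandwich

    (X'X)^{-1} [ sum_{|j|<=m} (1 - |j|/(m+1)) * sum_t u_t u_{t-j}' ] (X'X)^{-1},

u_t = x_t * resid_t. Lag rules: fixed m; floor(n^{1/4}); floor(0.75 n^{1/3});
floor(1.3 n^{1/2}) (bandwidth only — fixed-b critical values are out of
scope, standard t quantiles are used and this is a documented limitation);
and the default, the Newey-West (1994) plug-in rule with initial window
l = floor(4 (n/100)^{2/9}) and m = floor(1.1447 |s1/s0|^{2/3} n^{1/3}),
computed from the intervention-column score series (the focus parameter).
The plug-in's sampling distribution was checked against the reference
implementation of the rule: on white noise at n = 300 the two produce
nearly identical bandwidth distributions (the rule is noisy by nature —
small bandwidths are *not* guaranteed under iid errors). VAR(1)
prewhitening is implemented but off by default — on 20-50 point series the
VAR fit itself is so noisy that it can inflate the sandwich variance by
orders of magnitude, and simulated coverage identifies non-prewhitened
sandwiches as what ITS practice actually produces. Newey-West intervals
use standard-normal quantiles by default (the +/- 1.96 SE convention of
robust-SE practice; simulated short-series coverage also identifies the
normal, not t(n-k), as the convention behind published ITS evaluations of
this method); a t option is provided.

**Prais-Winsten / Cochrane-Orcutt.** Feasible GLS under a working AR(1)
error model. phi1 is the no-intercept slope of resid_t on resid_{t-1}
(intercept variant available), truncated to |phi1| <= 0.999 if outside the
stationary region. Quasi-differencing ytilde_t = y_t - phi1 y_{t-1} is
applied to y and every design column; the intercept becomes the
constructed regressor z (z_0 = sqrt(1-phi1^2), z_t = 1-phi1), the first
row is rescaled by sqrt(1-phi1^2) (PW) or dropped (CO), and the
transformed regression is fitted without an intercept. With known phi1
this is exactly GLS with Sigma_ij = phi1^|i-j|/(1-phi1^2) (tested to
1e-8). By default the residual/phi1 update iterates to |delta phi1| < 1e-6
(max 50 passes; non-convergence is flagged, not raised). CIs use t(n-k)
with k the untransformed model's column count — the convention of standard
regression output.

**Regression with ARMA(p,q) errors.** Exact Gaussian ML. The error process
is put in Harvey companion state-space form; the stationary state
covariance solves the discrete Lyapunov equation (direct Kronecker solve,
state dimension <= 6); the Kalman filter computes innovations and their
variances, switching to the steady-state gain once the covariance
recursion has converged (tolerance 1e-13). Both the Kalman pass and the
conditional-likelihood recursion (pre-sample innovations fixed at zero,
first p residuals conditioned on) are *linear* in the filtered series, so
beta is profiled out by least squares on the whitened response/design and
sigma2 is profiled analytically; the optimizer searches only the p+q error
parameters. Those are parameterised by partial autocorrelations through
tanh and the Durbin-Levinson recursion, which enforces stationarity and
invertibility by construction (|arctanh| capped at 6). Fits start from a
conditional-likelihood pre-fit and polish on the exact likelihood
(L-BFGS-B with jitted forward-difference gradients). vcov(beta-hat) is the
GLS expression at the estimated error parameters — the beta block of the
inverse observed information, as standard ARMA software reports — and CIs
use normal quantiles by default (t optional). sigma2-hat is the ML scale
RSS/n. The exact likelihood is verified against the dense
multivariate-normal density with the analytic ARMA autocovariance at 1e-6
and against an independent state-space implementation at 1e-8.

**Order selection.** Stepwise AICc search in the Hyndman-Khandakar
pattern: start set {(0,0), (1,0), (0,1), (2,2)}, moves p±1, q±1 and both,
clipped to p, q <= 5, stop when no neighbour improves; ties break toward
fewer parameters, then fewer MA parameters; the winner is refit by exact
ML. AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1) with k counting beta, phi,
theta and sigma2. Two selection details matter and were validated
empirically: (i) candidates are scored on the *exact* likelihood —
conditional log-likelihoods sum over n-p innovations, which is not
comparable across AR orders and rewards spurious near-cancelling AR/MA
pairs (a conditional-scoring mode exists for speed but is not the
default); (ii) a candidate whose fitted AR or MA polynomial has a root
with modulus < 1.001 is rejected, as in the standard automatic-ARIMA
implementation — such fits are boundary artifacts. With both rules, white
noise selects (0,0) in roughly three quarters of replicates.

**REML, Satterthwaite, Kenward-Roger.** The restricted likelihood

    l_R = -1/2 [ (n-k) log sigma2 + log|C| + log|X'C^{-1}X| + r'C^{-1}r / sigma2 ] + const

(C the unit-variance ARMA correlation matrix, dense n-by-n from the
analytic autocovariance, r the GLS residuals) is maximised over the error
parameters in the same pacf coordinates; sigma2 profiles to
r'C^{-1}r/(n-k), the unbiased estimator in the iid case. beta-hat is GLS
at the fitted error parameters. The dense-matrix route is exact and cheap
at the short lengths (n <= a few hundred) where small-sample corrections
matter; REML-vs-ML agreement of beta was checked at n = 3000 (1.8e-5).

Satterthwaite: phi = var(beta1-hat) = sigma2 [(X'C^{-1}X)^{-1}]_11 as a
function of psi = (error params, sigma2); its gradient is taken by central
differences with step 1e-4 (1+|psi|); var(phi-hat) = g' I^{-1} g with I
the *expected* REML information I_ij = tr(P dV_i P dV_j)/2 (P the REML
projection matrix, dV_i numeric central-difference derivatives of
V = sigma2 C). The expected information is PSD by construction, which
keeps var(phi-hat) non-negative even when the MA estimate sits on the
invertibility boundary — an observed numeric Hessian fails exactly there.
d = 2 phi^2 / var(phi-hat), capped at n-k; under the iid error model
d = n-k exactly.

Kenward-Roger (first order): Phi_A = Phi + 2 Phi [sum_ij W_ij (Q_ij -
P_i Phi P_j - R_ij/4)] Phi with W the inverse expected information and
P/Q/R the usual first/second-derivative forms of V; CI = beta1-hat ±
t_{d,0.975} sqrt([Phi_A]_11). Under an iid error model the adjustment
vanishes and the interval reduces to the classical OLS t(n-k) interval
(tested to 1e-6). KR is implemented for AR/MA error models through the
same dense-V machinery; a non-positive adjusted variance (numerically
possible at degenerate fits) falls back to the unadjusted Phi.
Non-convergence is reported per fit and excluded from simulation metrics
with counts logged.

## Synthetic-data generator

The generator *is* the study conditions: MA(3) errors
eps_t = eta_t + theta1 eta_{t-1} + theta2 eta_{t-2} + theta3 eta_{t-3}
with eta_t iid N(0,1), scenario coefficients drawn as theta1 ~ U(0,1),
theta2 ~ U(0,theta1), theta3 ~ U(0,theta2) (autocorrelation positive and
decreasing, rho1 <= 0.75, zero beyond lag 3); series lengths 20-300 with
tau = n/2; regression coefficients beta0 = 4, beta1 = -1, beta2 = -1/n
(inference is invariant to these values, which mimic a ~25% intervention
and ~25% total-trend reduction on a log scale). Scenarios are labelled by
lag-1 autocorrelation: low < 0.3 <= moderate < 0.6 <= high. q pre-sample
innovations are drawn so eps is exactly stationary from t = 0 (no burn-in
transient). The implied ACF rho_k = (sum_i theta_i theta_{i+k}) /
(sum_i theta_i^2), theta_0 = 1, is exact and is cross-checked against
long-run empirical ACFs.

What it does **not** emulate: seasonality, non-Gaussian or heteroskedastic
innovations, counts/rates with mean-variance coupling, missing values, AR
or longer-memory error processes. Passing tests therefore demonstrate
correct behaviour under a clean Gaussian MA(3) world, not robustness to
everything real surveillance data can do.

## Simulation engine and reproducibility

One master seed fans out through named substreams
SeedSequence((master_seed, 1, scenario_id, n, replicate)), so any cell or
single replicate is reproducible in isolation, every method sees identical
datasets within a cell, and results are independent of execution order or
worker count (cells can be farmed out via joblib). Metrics per
(scenario, n, method): bias, empirical SE, RMSE, coverage of 95% CIs,
power (CI excludes zero), each with Monte-Carlo SEs (emp_se/sqrt(B);
binomial formula for proportions); rmse^2 = bias^2 + (B-1)/B emp_se^2
holds as an identity. Replicates whose fit raises or reports
non-convergence are excluded from numerators and denominators and counted.
Stratum summaries are unweighted means over (scenario, n) cells —
e.g. "high autocorrelation" = cells with rho1 >= 0.6, "short series" =
n <= 50 — matching how grid-level results are usually quoted.

A known-parameter GLS arm (true MA(3) covariance, normal quantiles) serves
as the engine's calibration control: its t statistic is exactly standard
normal, so its coverage must sit at 95% up to Monte-Carlo error.

Problem sizes: the test suite runs the 20-scenario grid at 300 replicates
per cell for the closed-form arms, 40 for stepwise-ARMA and 100 for the
ML arms; `scripts/acceptance.py` uses 500 / 60 / 300 and 2000/1000 for the
power experiment. These are the package's own runtime choices; Monte-Carlo
SE bands in tests scale with the replicate counts. With re-drawn scenario
sets, grid-level aggregates reproduce reference values only up to
scenario-sampling variability (about one to two percentage points of
coverage for a 20-scenario draw).

## Numerical choices and degenerate inputs

- pacf coordinates capped at |arctanh| = 6 (|pacf| <= 1 - 1e-5): keeps the
  Lyapunov system and dense covariances solvable; a near-singular solve
  falls back to least squares.
- REML starts from white noise and retries from a
  positive-autocorrelation start if the first attempt stalls on its first
  iterations (L-BFGS-B line searches can die when the initial projected
  step lands on the 1e12 guard).
- Perfect fits (zero residual variance) are flagged `degenerate` rather
  than producing zero SEs silently; rank-deficient designs raise an error
  naming a removable column, scanning user covariates first.
- phi1 estimates outside (-1, 1) are truncated to ±0.999 and flagged.
- Numeric differentiation: central differences, step 1e-4 (1+|value|) for
  V-derivatives and the Satterthwaite gradient; 1e-6 forward differences
  inside the jitted likelihood gradient.

## Limitations

- Fixed-b critical values for the 1.3 n^{1/2} HAC rule are not
  implemented (bandwidth rule only).
- The Kenward-Roger procedure here is the first-order variance adjustment
  with Satterthwaite t(d) intervals; the fully scaled F variant (a
  lambda-scaled F statistic with its own denominator-df formula) is not
  implemented — prototypes were numerically unstable with
  expected-information weights on dense ARMA covariances.  In simulation
  this recipe runs one to three coverage points below nominal (and
  correspondingly a few power points above the fully scaled variant) on
  white-noise series of length 50.
- KR is first-order and routed through dense covariances: quadratic memory
  in n, intended for the short series where it is needed.
- No differencing, seasonal ARMA, drift, or unequally spaced time points.
- The stepwise search is a heuristic: it matches the behaviour of the
  standard automatic-ARIMA tool, not an exhaustive AICc minimisation.
- For very short series (n < 12) the study design itself is out of range;
  the engine refuses such lengths.
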