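# Methods

## Scope and model family

`micropredict` models two microbial processes on the log10 CFU scale:

* **Growth** under constant conditions, with four sigmoidal primary models:
  modified Gompertz and Logistic (log10 form, rate `rmax` in log10 CFU/h),
  and Baranyi–Roberts and Huang (natural-log form, rate `mumax` in 1/h).
  The rates are related by `mumax = rmax · ln 10`; the package reports
  `mumax` for every growth fit regardless of the model's internal log base,
  and populations always in log10 CFU/g at the API boundary.
* **Inactivation** under a chemical stressor, with three primary models:
  Log-Linear (`logN = logN0 − k·t`), Log-Linear + Tail
  (`logN = (logN0 − logNres)·e^(−k·t) + logNres`, an exponential decay of
  the *log-count* toward the residual tail — deliberately this form, not
  the Geeraerd arithmetic-count shoulder/tail model), and Weibull
  (`logN = logN0 − (t/δ)^p`), with time in seconds.

Secondary models link kinetic parameters to one environmental variable:

* growth: `mumax(X) = b1·(X − Xmin)²` and `lag(X) = b2 / mumax(X)`.
  The squared form is used exactly as written; with temperature in °C the
  coefficient `b1` then carries units 1/(h·°C²), which is what makes the
  equation dimensionally consistent even though responses of this family
  are often quoted in square-root form (`√mumax` linear in `T`).
* inactivation: `k or δ = a − b·log10(X)`. The logarithm is base 10, the
  convention under which the package's one-step and two-step estimates of
  `δ` at 50 mg/L agree.

Two closed-form adjustment functions are not uniquely fixed by the model
family and are documented constants here: the Baranyi–Roberts form
`F(t) = t + (1/µ)·ln(e^(−µt) + e^(−µλ) − e^(−µ(t+λ)))` (equivalent to
`h0 = µλ`, i.e. `q0 = 1/(e^(µλ) − 1)`), and the Huang transition
`B(t) = t + ¼·ln((1 + e^(−4(t−λ)))/(1 + e^(4λ)))` with the published
transition coefficient 4.

All exponentials whose arguments can reach `ymax·ln 10` are evaluated in
shifted (log-sum-exp) form, so the evaluators are finite for arbitrarily
large `µ·t`.

## Fitting

**Two-step**: each condition's curve is fitted by trust-region-reflective
least squares (`scipy.optimize.least_squares`, TRF, tolerances 1e−12);
the per-condition kinetic parameters are then regressed on the
environmental variable (nonlinear for the Ratkowsky-type response with a
square-root-linearised starting point; closed-form OLS for
`a − b·log10 X`; the lag coefficient `b2` has the closed-form solution of
a through-origin regression of lag on `1/mumax`). Replicate curves at one
condition are pooled into a single primary fit.

**One-step**: the secondary model is substituted into the primary
equation and a single parameter vector — `(y0, ymax, Xmin, b1, b2)` for
growth, `(logN0, a, b, p)` for the Weibull, analogous vectors for the
log-linear variants — is estimated over all curves jointly. `y0` and
`ymax` are global (one value across conditions).

Every fit runs a seeded multi-start (8 starts: data-driven heuristics
plus jittered copies). Heuristic initialisation: initial population from
the first observation, maximum from the largest, rate from the steepest
3-point secant, lag from the time-axis intercept of the tangent at that
secant, `δ` from the interpolated time of the first observed 1-log drop,
`p = 1`, and `(a, b)` from an OLS of per-condition `δ` seeds on
`log10 X`. For one-step fits the full two-step reconstruction is always
one of the starts, which guarantees the joint SSE never exceeds the SSE
of freezing the two-step estimates into the global model. Tie-breaking
among multi-start solutions: lowest SSE, then smallest parameter-vector
norm.

Box constraints keep estimates in their scientific domain (rates, `δ`,
`b1` positive; `p ∈ [0.05, 5]`; `lag ≥ 0`; `Xmin` below the smallest
observed condition). Two order constraints are enforced structurally by
reparametrisation rather than penalties: growth fits run internally on
`(x0, span)` with `span = xmax − x0 ≥ 0.5` log10, and the tail model on
`(logN0, k, drop)` with `drop = logN0 − logNres > 0`; the covariance is
mapped back through the corresponding linear transform. Inside the
one-step Weibull residual, `δ(X)` is floored at 1e−3 s (and `k(X)` at 0)
so the optimiser can traverse parameter regions where the secondary line
would otherwise predict a negative kinetic parameter.

Degenerate inputs are rejected with diagnostics rather than fitted:
growth fitting requires ≥ 5 points spanning more than 1 log10 and a
non-decreasing trend; inactivation fitting requires ≥ 4 points and a
non-increasing trend.

## Uncertainty

Parameter covariance uses the Gauss–Newton approximation
`C = s²(JᵀJ)⁻¹` with `s² = SSE/(n − p)` — the quantity
Levenberg–Marquardt-style least-squares implementations expose — with a
pseudo-inverse fallback (and warning) when the Jacobian is rank-deficient
at the optimum. Standard errors are the square roots of the diagonal.
Pointwise 95 % prediction bands follow the delta method,
`σ²(t) = ∇f(t,θ̂)ᵀ C ∇f(t,θ̂) + s²`, with the fixed normal quantile
1.96 (not a t-quantile). Gradients are central finite differences with
relative step 1e−6 unless an analytic gradient is registered.

Non-probabilistic regressors get percentile bootstrap bands: B = 100
refits (configurable) on joint resamples of the training rows, bounds at
the empirical 2.5th/97.5th percentiles of the per-point predictions.
B = 100 balances tail resolution against cost and is a config default,
not a constant.

## Machine-learning workflow

Features are exactly `(time, one environmental variable)`; the response
is the log10 count and is never scaled. The pipeline is: canonical row
ordering (condition, then time, then response — making every downstream
step invariant to input row order) → stratified 80/20 split on the
condition → z-score feature scaling fitted on training rows only
(population SD; constant columns guarded to SD 1) → augmentation of
training sets smaller than 750 rows by resampling with replacement up to
exactly 750 rows, adding uniform ±0.2 log CFU noise to the resampled
responses (the threshold itself is the minimal faithful target size) →
regressor fit → optional 5-fold CV (scaling and augmentation re-fit
within each training fold) and held-out metrics. The split happens
*before* augmentation, so no augmented copy of a test row ever enters
training.

Regressors: GPR with a squared-exponential kernel plus additive white
noise, hyperparameters by marginal-likelihood maximisation with 5 seeded
restarts; SVR (RBF) tuned by inner 5-fold CV over a small deterministic
grid (C ∈ {1, 10, 100}, ε ∈ {0.01, 0.1}, kernel width = median heuristic
× {0.5, 1, 2}); RFR with 500 trees, unrestricted depth, seeded. Decision
trees are excluded as a standalone regressor. ML RMSE uses denominator
`n` (no parameter count is defined for these models); mechanistic fits
use `n − s`.

Uncertainty: GPR bands are analytic (`mean ± 1.96·σ_GPR`); SVR/RFR bands
are percentile bootstrap with the selected hyperparameters held fixed
across replicates.

### A caution on augmentation and flexible regressors

Label-noise augmentation of small datasets duplicates feature rows.
Under a leakage-free split, a GP's marginal likelihood then tends to a
degenerate optimum: the white-noise term collapses to the known jitter
variance (≈ 0.2²/3) and the length scale shrinks until the mean function
interpolates the original *noisy* observations, and an unrestricted-depth
random forest resolves the duplicate clusters the same way. Both then
carry the measurement noise into held-out predictions (error
≈ √2 × noise SD), while a CV-tuned SVR smooths toward the noise floor.
Consequently, on this package's synthetic growth benchmarks the GPR/RFR
vs SVR ranking often *reverses* relative to results obtained when test
rows are noisy copies of training rows. The repeated ordering experiment
(`micropredict.experiments.ml_ordering_experiment`) measures this
directly; its outcome should be read as a property of the
augment-then-evaluate protocol, not of the regressors.

## Statistics

RMSE and R² follow the standard definitions with SST about the observed
mean. The paired comparison uses the two-sided Wilcoxon signed-rank
test: zero differences dropped, mid-ranks for ties, exact p for up to 25
non-zero pairs via dynamic programming over the signed-rank-sum
distribution (`p = P(min(W⁺, W⁻) ≤ observed)`), normal approximation
with tie correction beyond. The 0.05 threshold is a reporting default,
not a gate.

## Synthetic data

The generator emulates the two target systems: isothermal spoilage
growth on poultry at 2–20 °C (lag through stationary phase) and chlorine
inactivation of surface-attached Listeria at 50–200 mg/L over 0–360 s.
Noise is additive Gaussian on the log10 scale — the field's standard
error model — with defaults 0.15 log (growth) and 0.10 log
(inactivation). Growth time grids default to 15 points from 0 to the
time the true curve reaches 99 % of its span at that condition;
inactivation grids default to {0, 15, 30, 60, 120, 180, 240, 300, 360} s.
It does **not** emulate detection limits, censoring, plate-count
quantisation or between-batch variability, so passing recovery tests
shows estimator correctness under the assumed error model, not robustness
to real-data artifacts.

The validation experiments in `micropredict.experiments` use published
platform parameter estimates as generating truths (Baranyi at 20 °C:
y0 = 3.03, ymax = 8.19 log CFU/g, µmax = 0.243 1/h, λ = 2 h; Weibull at
50 mg/L: δ = 20.43 s, p = 0.33, logN0 = 7; one-step modified Gompertz:
y0 = 3.97, ymax = 9.66, Tmin = −9.24 °C, b1 = 0.0014, b2 = 1.29;
one-step Weibull: a = 64.49, b = 26.92, shape 0.33). Replicates come
from a single seeded RNG stream via `SimulationSpec.replicates`.
Experiment sizes (100 single-curve replicates for the two-step
experiments, 20 and 50 replicate datasets for the one-step experiments)
were chosen to keep the Monte-Carlo error of the reported means a few
times smaller than the per-replicate spread. Note the one-step Weibull
intercept `a` has a heavy-tailed, strongly ridge-correlated sampling
distribution on a 4-concentration design (per-replicate SD ≈ 12 s), so
means over 50 replicates still fluctuate by ±2–3 s between seeds.

## Numerical choices and defaults

| quantity | default | notes |
|---|---|---|
| optimiser | TRF least squares, ftol=xtol=gtol=1e−12 | `x_scale="jac"` for mixed parameter scales |
| multi-start | 8 starts | heuristics + jitter; two-step reconstruction included for one-step fits |
| seed | 20250910 | every stochastic routine takes an explicit seed |
| normal quantile | 1.96 | fixed, not t |
| FD gradient step | 1e−6 relative | central differences |
| bootstrap B | 100 | percentile bounds 2.5/97.5 |
| augment threshold / noise | 750 rows / ±0.2 log | training folds only |
| GPR restarts | 5 | reduced in the repeated ordering experiment purely for sizing |
| noise SD (synthetic) | 0.15 growth / 0.10 inactivation | Gaussian, log10 scale |

## Known limitations

* Constant conditions only: no dynamic temperature profiles and no
  interaction/competition models.
* One environmental variable; no multi-factor (gamma-type or cardinal
  parameter) secondary models.
* The tail inactivation model operates on log-counts (see above); users
  expecting the arithmetic-count tail model should note the difference.
* Delta-method bands assume local linearity; strongly ridge-shaped
  posteriors (one-step Weibull) make them optimistic in the ridge
  direction.
* The ML layer is restricted to two features by design.
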