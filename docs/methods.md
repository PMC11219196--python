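# Methods

## The occupancy-detection model

Each site `i` carries a latent occupancy state `z_i ~ Bernoulli(ψ)`,
constant over the season (closure assumption: no colonisation or
extinction between surveys, including between the sampling windows of
different methods).  Given occupancy, each surveyed occasion `j` — a
24-h bin for acoustic recorders and camera arrays, a single flight for
drones — yields a detection `y_ij ~ Bernoulli(p_ij)`.  Unoccupied sites
never produce detections (no false positives).  Integrating the latent
state gives the site likelihood

    L_i = ψ ∏_j p_ij^{y_ij} (1−p_ij)^{1−y_ij} + (1−ψ) · I(Σ_j y_ij = 0),

maximised over all sites jointly.  Both ψ and p use logit links.
Occasions that were not surveyed are simply absent (they contribute a
factor of 1); occasions surveyed but with missing weather keep a row
with NaN covariates and are excluded from covariate-model likelihoods
while remaining in intercept-only models, which uses the maximum of the
data without imputation.

### Detection formula and the candidate set

Occupancy is always intercept-only.  Detection always includes a method
main effect (treatment coding; the first method present in the data is
the reference level), optionally crossed with one or two weather
covariate blocks drawn from {rain, humidity, humidity², temperature,
temperature²}.  A quadratic block always carries its linear term — the
statistically standard nested parameterisation — so, for a three-method
dataset, a model with `method × temp²` has 3 (method) + 3 (linear
slopes) + 3 (quadratic slopes) + 1 (ψ) = 10 parameters.  Some published
rankings of equivalent model sets count such models differently (e.g.
reporting the same parameter count for linear-only and quadratic
models); we deliberately keep the nested count, since dropping the
linear term makes the quadratic model sensitive to the covariate's
centring.

The 15-model candidate set is: null (`p(.)`), method-only
(`p(method)`), the five single-block models, and the eight two-block
combinations that pair two distinct covariates (rain or humidity forms
with temperature forms, plus rain-with-humidity forms).  Covariates are
z-scored over the pooled dataset (all methods together, sample sd,
ddof = 1) so that coefficients are comparable across methods; the
mean/sd pairs are kept in a `CovariateScaler` for inverse transforms and
prediction at new covariate values.

### Fitting, covariance, AICc

Fitting is quasi-Newton (BFGS) on the joint link-scale parameter vector
with a finite-difference gradient, multi-start: one deterministic start
(naive occupancy = share of sites with a detection; naive p = overall
detection rate) plus, by default, 5 restarts jittered with seeded
Gaussian noise (sd 0.5 on the link scale).  Convergence requires
optimizer success or a gradient norm below 1e-3; the gradient tolerance
passed to BFGS is 1e-8.  The covariance matrix is the inverse of a
central-finite-difference observed-information matrix (step 1e-4
relative); if it is singular or has negative diagonal entries,
confidence intervals are reported as unavailable rather than fabricated.
Coefficients beyond ±12 on the logit scale flag the fit as a boundary
solution (p̂ or ψ̂ numerically at 0/1); boundary fits carry no CIs and
are rejected by the goodness-of-fit machinery.

AICc = −2ℓ + 2n + 2n(n+1)/(N_eff − n − 1) with N_eff = the number of
sites, the standard convention for occupancy models (recorded in each
`FitResult` as `n_eff_convention` so alternatives are auditable).
Akaike weights are exp(−Δ_m/2) normalised over the fitted set.

Method-specific detection predictions use the delta method on the link
scale — `var(η̂) = x'Σx`, 95 % interval `η̂ ± 1.96·se` — back-transformed
through the inverse logit, which guarantees intervals inside [0, 1].
Predictions outside the fitted covariate range warn but do not fail.

## Goodness of fit

Two discrepancy statistics are computed per surveyed occasion against
the unconditional expectation `ê_ij = ψ̂·p̂_ij`: the sum of squared
errors `Σ(y−ê)²` and the Freeman–Tukey statistic `Σ(√y−√ê)²`.  Their
null distributions come from a parametric bootstrap: simulate replicate
datasets from the fitted model on the observed site/occasion/covariate
layout, refit the same specification (warm-started at the fitted
coefficients, single start), recompute the statistics, and form
`p = (1 + #{T_b ≥ T_obs})/(B + 1)` (the add-one estimator, never exactly
zero).  Replicates whose refit fails or lands on a boundary are dropped
and counted; more than 20 % drops flags a warning.  The default is
B = 10,000 replicates; the test suite uses B = 100–200.

**Known property — conservatism.**  Because every replicate is refitted,
the bootstrap distribution's location automatically tracks the observed
statistic whenever the statistic is close to a smooth function of the
fitted parameters — which both occasion-level statistics are, especially
under covariate-free models where expectations are constant within
method.  The resulting p-values are therefore *conservative*: under a
correctly specified model they concentrate near 0.5 rather than being
uniform (the test suite demonstrates this concentration directly).  The
test retains power against gross misspecification, but small p-values
are rarer than their nominal rate, so a non-significant result is weak
evidence of adequacy.  Users who need sharper calibration should compare
nested models by AICc rather than relying on absolute fit.  The
expectation convention (unconditional ψ̂·p̂ per occasion, no site-level
conditioning) is recorded in every `GofResult`.

## Power analysis

For an occupied site, `P* = 1 − (1−p)^K` is the chance of at least one
detection in `K` occasions, and `K*(p, t) = ln(1−t)/ln(1−p)` is the
(real-valued) number of occasions needed to reach cumulative confidence
`t`.  Power to detect a proportional decline `R` (ψ₂ = ψ₁(1−R)) from two
survey rounds of `S` sites × `K` occasions each uses the asymptotic
variance of the occupancy MLE with detection-driven inflation

    F = (1 − P*) / (P* − K p (1−p)^{K−1}),      σ_i² = ψ_i (1 − ψ_i + F) / S,

and the two-sided Wald test at level α:

    G = 1 − Φ((z_{α/2}·s − D)/s) + Φ((−z_{α/2}·s − D)/s),
        D = ψ₁ − ψ₂,  s = √(σ₁² + σ₂²).

At R = 0 this reduces to G = α exactly, which the tests verify to 1e-9.
`K = 1` is rejected: the denominator of F is identically zero there
(occupancy and detection are not separable from a single visit).  K is
integer in grids (survey occasions) and real-valued only in the
cumulative-detection inversion.  Both rounds share S, K and p; only
occupancy changes.  The default α is 0.2, reflecting that for a
declining species a missed decline (Type II error) is costlier than a
false alarm; it is configurable everywhere.

The default design grid is S = 1..200 × K = 2..20 × R ∈ {0.3, 0.5, 0.8}
(11,400 cells); an extended K range (e.g. to 40, useful for
low-detectability methods such as camera traps) is a parameter.  The
decline magnitudes mirror IUCN-style thresholds (30/50/80 %).  Scenario
presets carry the two published variants of the koala daily detection
probabilities (0.32/0.28/0.019 and 0.31/0.28/0.017 for
acoustic/drone/camera) with shared ψ₁ = 0.54; which variant to use is a
user choice, so both ship.

## Cost model

`C = UC + S·CS + S·K·CSS`: a one-off startup cost per method, a per-site
cost, and a per-site-per-survey cost.  The cheapest feasible design is
found by exhaustively scanning the grid cells with `G ≥ threshold`
(grids are at most tens of thousands of cells); ties in cost are broken
by smaller S, then smaller K — fewer sites is usually the harder
logistic constraint in the field.  Cost parameters are pure
configuration with no defaults: realistic values depend on equipment,
labour and travel specific to a programme, and hard-coding any would
invite silent misuse.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes:

- 46 sites, ψ = 0.54 shared across methods (closure).
- Acoustic: one recorder per site, consecutive-day deployments with
  length ~ N(17, 12²) truncated to [8, 42] days, starting in
  spring–early summer (day-of-year 244–330).
- Camera: six cameras per site, deployments ~ N(99, 39²) truncated to
  [67, 264] days, starting in autumn (day-of-year 122–209).  The
  configured daily p (0.019) is the OR across the six cameras; each
  camera draws with `p_unit = 1 − (1−p_day)^{1/6}`, exercising the
  unit-level OR-binning path.  Cameras are independent given occupancy.
- Drone: a repeat count ~ round(N(2, 0.42²)), floor 1, on distinct
  winter nights.
- Weather: daily maximum temperature as a seasonal sinusoid (mean 22 °C,
  amplitude 8 °C, southern-hemisphere phase peaking mid-January) plus
  N(0, 3²) day-to-day noise; relative humidity ~ N(60, 15²) clipped to
  [2, 100] %; rain as a 0.3-probability wet day with exponential (6 mm)
  amounts.  Temperatures are placed on a z scale using the generator's
  own nominal sd `√(amplitude²/2 + noise²)`.
- Detection: `logit p_ij = logit p₀ + β₁ z_temp + β₂ z_temp²` with the
  default β₂ = −0.2 (concave-down: detection peaks at intermediate
  temperatures) and β₁ = 0.  The quadratic coefficient's magnitude was
  chosen once as a moderate, realistic effect (≈ 25 % reduction in
  detection odds two sds from the seasonal mean); it is not calibrated
  to any dataset.

Deployment lengths are rounded to integer days with floor 2.  Two
derived scenarios support validation: `recovery_scenario` (every method
at every site for exactly k days, no weather effect — a correctly
specified method-only world for coverage experiments) and
`calibration_scenario` (acoustic + drone only, fixed 10-day deployments
— detection high enough that bootstrap refits essentially never hit a
boundary, giving a clean null for goodness-of-fit calibration).

What the generator does **not** emulate: spatial structure within or
between sites, serial dependence in detections or weather beyond the
sinusoid, observer effects, false positives, abundance-driven
heterogeneity, or between-season occupancy dynamics.  Tests passing on
synthetic data therefore validate the estimators and the closed-form
design math under the model's own assumptions; they do not certify
robustness to violations of those assumptions in field data.

## Problem sizes used in the test suite

The validation suite scales simulations to what a laptop CPU handles
comfortably while keeping the checks meaningful: likelihood equivalence
with latent-state enumeration is exhaustive over all binary histories up
to 3 sites × 3 occasions; the MLE is cross-checked against a 200 × 200
likelihood grid on a 3-site toy; parameter recovery runs 100 seeded
replicates of a 200-site × 14-occasion method-only world; bootstrap
calibration runs 50 seeded datasets with B = 200 replicates each; the
goodness-of-fit default of B = 10,000 is exercised at reduced B in
tests.
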