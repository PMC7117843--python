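# Methods

This note documents the statistical model, the synthetic-data generator,
and the numerical and design choices behind `placebotwin`.

## Setting and estimands

A two-arm trial randomizes postmenopausal women with osteoporosis to
placebo or active treatment for a 3-year core study; all core completers
may enter a 7-year extension on active drug. Times are fractional years
from core baseline; the core period is [0, 3), the extension [3, 10).
Two analysis sets matter:

- **crossover subjects** (placebo in core, active in extension): their
  core-period data are the only untreated observations and calibrate all
  counterfactual models;
- **long-term 10-year completers** (active throughout, full 10-year
  follow-up): the set whose observed incidence is reported and for whom
  counterfactual placebo outcomes are estimated.

The endpoint is time to first major osteoporotic fracture (MOF — clinical
vertebral, hip, forearm or humerus), with hip alone as a secondary
endpoint. The primary estimand is the 10-year counterfactual cumulative
MOF incidence of the long-term completers had they never been treated, and
the derived treated-versus-counterfactual rate ratio.

## Observed incidence

`survival_km`-style estimation uses the standard product-limit estimator on
per-subject (first event time, observed) pairs, with Greenwood variance.
Numerical choices:

- 95% CIs are built on the complementary log-log scale,
  `θ = log(−log S)`, and back-transformed, keeping intervals inside
  [0, 1]; a plain linear-scale Greenwood interval is switchable
  (`ci_transform="linear"`).
- Ties between an event and a censoring at the same timestamp are resolved
  events-first (the censored subject counts as at risk).
- The horizon read-out is the right-continuous step value at the horizon,
  no interpolation.
- With zero observed events the incidence is 0 with CI
  `[0, 1 − 0.025^(1/n)]`, the exact one-sided binomial bound (the
  rule-of-three analogue at the 97.5% level).

Recurrent fractures are stored in the data model — the count model below
uses them — but incidence is time-to-first-event.

## The placebo-calibrated rate model

Fracture counts during the crossover arm's core follow-up are modeled as
Poisson with a log person-time offset:

`log E[N_i] = β·x_i + log t_i`,
`x = (1, age [yr], BMI [kg/m²], prior vertebral fx, prior nonvertebral fx,
total-hip T-score [SD], ever-smoker)`.

- The T-score predictor is the **total-hip** T-score: the twin procedure
  later simulates the end-of-core *total-hip* T-score, so using it as the
  fitted predictor keeps calibration and prediction on one scale. A
  femoral-neck switch exists (`tscore_predictor="femoral_neck"`).
- Prior vertebral and nonvertebral history enter as two separate
  indicators; a composite single-indicator variant is switchable
  (`composite_prior=True`).
- Fitting is Newton/IRLS on the exact score and observed information,
  iterated to a score max-norm below 1e-8 (cap 100 iterations; steps are
  damped to max-norm 10 to survive near-degenerate resamples).
  Non-converged fits are flagged and every downstream consumer refuses
  them. Covariance is the inverse observed information; rank-deficient
  designs are rejected with the collinear columns named (QR diagonal).
- No overdispersion adjustment (plain Poisson); the Pearson quasi-Poisson
  scale is computed and carried as a diagnostic only.

With sparse strata (e.g. no events among smokers in a small resample) the
MLE of an indicator coefficient lies at −∞; the damped iteration then
converges, in the score sense, at a large negative value. This is the
correct MLE-boundary behaviour for prediction (the stratum's predicted
rate is ~0) and is why cross-library coefficient comparisons are only
meaningful away from separation.

## Virtual twins

For each long-term completer a twin is built from the two crossover-arm
models (rate model above; an OLS model of end-of-core total-hip T-score on
age, baseline T-score and BMI, with residual SD computed with denominator
n − 4 and a zero-residual fit rejected as degenerate):

1. `μ_c = exp(β·x_baseline) · 3`;
2. history update: Bernoulli(`1 − exp(−μ_c)`) sets one history indicator,
   vertebral with the placebo arm's empirical vertebral share of
   core-period events (recorded in the report); an expectation-weighting
   variant (`history_mode="expectation"`) carries the continuous
   probabilities instead — the default is the draw, with the draw noise
   absorbed into the bootstrap;
3. simulated T-score `~ N(fit mean, residual SD)`; the standard-normal
   draw is recorded on the twin record for reproducibility;
4. `μ_e = exp(β·x_ext) · 7` with `x_ext` = (age + 3, same BMI and smoking,
   updated history, simulated T-score); the offset is log 7 because the
   analysis set is completers;
5. 10-year incidence `1 − exp(−(μ_c + μ_e))`: the two expected counts are
   summed as a cumulative hazard and converted to a probability, which is
   self-consistent with the Poisson model and bounded in [0, 1]. An
   uncapped count-scale composition (`composition="count"`) exists for
   sensitivity analysis.

The cohort estimate is the mean twin incidence. History is updated once,
at extension baseline, not again mid-extension.

**Low-event guard.** If the placebo arm's core-period event count for the
requested endpoint is below `min_events` (default 20), the twin analysis is
refused with a typed, message-carrying outcome rather than an exception or
a zero. At the default study conditions this triggers for hip (≈ 10
placebo core hip events) and not for MOF (≈ 70–90 events). An explicit
override passes with a recorded warning; endpoint-specific twin estimation
beyond the composite MOF remains out of scope even then.

## Uncertainty

CIs come from a subject-level percentile bootstrap: subjects are resampled
with replacement within each arm (per-arm sizes preserved exactly), both
calibration models are refitted on the resampled crossover subjects, fresh
twins (new history and T-score draws) are built for the resampled
long-term completers, and the observed incidence, twin incidence and their
ratio are recomputed jointly — so the ratio CI is internally consistent.
Defaults: 5000 draws (tests use 200 for speed); 95% CI = 2.5th/97.5th
percentiles. Percentile rather than BCa: the simplest defensible choice
for a smooth functional; BCa was not implemented. Draws failing through
rank deficiency or non-convergence are recorded; more than 1% failures is
an error.

The rate ratio is `−log(1 − p_obs) / −log(1 − p_twin)` — the ratio of
10-year cumulative hazards. A raw incidence quotient `p_obs / p_twin` is
computed alongside; the hazard-scale definition is primary because it is
the quantity a constant rate multiplier preserves under the Poisson model.

Randomness discipline: one master seed; `numpy.random.SeedSequence` spawns
independent substreams for twin draws and bootstrap resampling (and the
simulator uses its own seed), so each component is reproducible in
isolation and all CLI outputs are byte-identical under rerun.

## The synthetic-data generator

The generator emulates the completer population of the published trial
family: age truncated-normal on [60, 90] (mean 70.8, SD 4.6 yr), BMI
normal (25.8, SD 4.0 kg/m², floored at 15), femoral-neck T-score normal
(−2.1, SD 0.7), P(any prior fracture) 0.51 (split into two independent
indicators with equal marginals; correlation configurable), ever-smoker
0.07. Invented linkages, configurable: total-hip baseline T-score =
femoral-neck + N(+0.1, 0.3); end-of-core T-score drift +0.5 per 3 yr
treated, −0.1 placebo, noise SD 0.25.

Event model: piecewise-constant per-subject hazards, `exp(β·x)` with the
same predictor set as the fitted model — core hazard at baseline
covariates, extension hazard at updated covariates (age + 3, history
accumulated during the counterfactual core, placebo-drifted T-score). A
Weibull-shape option (`weibull_shape ≠ 1`) provides a
hazard-misspecification stress configuration; it defaults off. Event types
are hip with probability `hip_fraction` (default 0.12, reproducing the
observed hip/MOF share), else uniform over the other three. Dropout is
exponential and independent (0.12/yr core, 0.09/yr extension, giving
~37% 10-year completion, matching the roughly one-third completion of the
motivating trials).

Default rate coefficients are
`(−6.26, 0.03 age, −0.01 BMI, 0.40 prior-vert, 0.30 prior-nonvert,
−0.20 T-score, 0.30 smoker)`: slope magnitudes typical of published
fracture-risk gradients, intercept calibrated once so the placebo arm's
mean MOF rate is ≈ 0.024/yr, i.e. a ≈ 23% 10-year counterfactual
incidence and ≈ 11–13% treated incidence — the magnitudes of the setting
the package models.

**Treatment as a total effect.** The configured rate ratio (default 0.5)
multiplies each subject's *counterfactual placebo* hazard path; treated
subjects' covariates that enter the rate (history, T-score) evolve along
the placebo path. The treated T-score trajectory is still recorded as data
— it is what a treated chart shows, and it is what the crossover-arm
T-score model must not be fitted on — but it does not additionally
modulate the treated rate. Rationale: the multiplier then captures the
whole treatment effect including its BMD-mediated component (no double
counting), the configured ratio is exactly the realized hazard-scale rate
ratio, and the generator's counterfactual incidence is exactly the twin
estimator's estimand, which makes bias measurable.

`GroundTruth` carries the realized per-subject counterfactual hazards; the
population counterfactual incidence is the analytic mean of
`1 − exp(−Λ_i(h))` over subjects, cross-checked against brute-force Monte
Carlo in the tests. External-probability columns are filled, when enabled,
with each subject's own counterfactual 10-year probability — a synthetic
stand-in for an external calculator (labelled as such), which makes the
predicted-versus-observed comparison meaningful on simulated data. (A
consequence: on synthetic cohorts the external-probability mean and the
generator's true counterfactual coincide by construction.)

What the generator does **not** emulate: mortality or any competing risk;
informative dropout; secular or regional variation in background rates;
covariate drift other than T-score (BMI and smoking carried forward
unchanged); measurement error in covariates; the internal model of any
external risk calculator. Passing tests therefore demonstrate correctness
of the estimation machinery under the assumed model family — including a
Weibull stress option — not robustness to these real-data features.

## Risk-factor imputation (external-probability path)

Missing clinical risk factors are filled before an external calculator
would be run: continuous fields (age, BMI, femoral-neck T-score) each from
the other two by OLS plus a Gaussian residual draw; binary fields
(prior fracture, parental hip fracture, alcohol ≥ 3 units, current smoker)
from logistic models on the three continuous fields. Single stochastic
draw (not multiple imputation), deterministic given the seed; observed
values are never altered; ≥ 20 complete cases per imputed field are
required. Glucocorticoid use and rheumatoid arthritis are pinned to "no"
(trial exclusion criteria). The conditional models are fitted on the
analysis cohort itself — the large external development cohorts such
models were originally built on are not available — and this substitution
is a documented limitation.

## Test and experiment sizes

The statistical acceptance experiments run at the study conditions: two
arms of 1278 subjects; 100 replicates for parameter recovery (placebo arms
of n = 5000), null faithfulness and effect recovery; 200 outer replicates
with 200 bootstrap draws for CI calibration, with the population
counterfactual computed from a single 100 000-subject draw. Unit tests use
toy fixtures with hand-computable answers and independent oracles
(statsmodels GLM/OLS, lifelines, brute-force likelihood grids, Monte
Carlo).

## Known limitations

- Calibration rests entirely on ~3 person-years per crossover subject of
  untreated follow-up; the extension-period counterfactual is a model
  extrapolation with a single covariate update at extension baseline.
- At the default sample size the placebo arm yields only ~70–90 core MOF
  events, so the twin estimate's precision — and hence the rate ratio's —
  is limited by rate-model uncertainty (relative SE ≳ 1/√events); the
  bootstrap CIs reflect this honestly.
- Completer-only analysis sets inherit any healthy-completer selection in
  real data; the generator's dropout is independent, so this bias is not
  probed by the tests.
- No competing risk of death: over a 10-year horizon in this age group
  this overstates cumulative incidence for all three comparators alike.
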