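# Methods

## The model

Tumour burden is measured as the RECIST sum of longest diameters (SLD, cm).
On-treatment SLD trajectories are described by a biexponential
decay/re-growth law

    SLD(t) = A · (e^{−B·t} + e^{C·t} − 1),      A, B, C > 0,

with `A` the baseline SLD and `B`, `C` rates per week.  The trajectory is
strictly convex in `t` with a unique nadir at

    tp = (ln B − ln C) / (B + C),

which may be negative (the profile only grows on-study) or beyond the
observation window (the profile only shrinks).  In forward time — origin at
treatment start — `B` is the decay rate (DR), `C` the re-growth rate (GR)
and `tp` the time-to-re-growth (TTG).  In reverse time — the series
reflected about its last scan, so the clock runs from progression into the
past — the roles swap: the first phase away from the origin is the undoing
of re-growth.  The turning point of a reverse-time fit is the time-to-nadir
(TTN), and TTG is recovered as `observation span − TTN`.

Derived metrics clamp the turning point to `[0, span]`.  The clamp is this
package's convention for monotone profiles (nothing else keeps TTG finite
and non-negative); clamping events are logged at DEBUG level.

The model-predicted percent change at week 8,
`100·(e^{−8B} + e^{8C} − 2)`, is independent of `A` and is evaluated at
exactly t = 8 weeks regardless of the scan schedule.  It is distinct from
the *observed* week 6–10 percent change reported in cohort summaries, which
uses each patient's first scan falling in that window.

Internal time unit is weeks throughout; reporting converts to months as
weeks × 7 / 30.4375.

## Population fit

Inter-individual variability is log-normal on all three parameters
(diagonal covariance) with additive Gaussian residual error (SD `sigma`,
cm).  Estimation is an iterated two-stage penalised scheme — a first-order
Laplace approximation to the marginal likelihood:

1. per patient, the empirical Bayes (EB) mode of `log θ` minimises
   `‖(f(θ) − y)/σ‖² + ‖(log θ − μ)/ω‖²` (Levenberg–Marquardt with analytic
   Jacobians, warm-started between sweeps);
2. `μ` is updated as the mean of the EB modes; `ω²` as the spread of the
   modes **plus** the mean Gauss–Newton posterior variance (without that
   correction shrinkage makes the variance components collapse); `σ²` as
   the mean squared residual plus the matching Jacobian trace term;
3. iterate to a relative tolerance of 1e−6, at most 200 sweeps.

Starting values are seed-free heuristics (A from the first scan; B and C
from log-linear fits to the early-decline and late-rise segments, with
population-typical fallbacks).  Patients lacking a pre-treatment scan or
any on-treatment scan are excluded and reported; two-point series are
retained by default (shrinkage keeps them estimable; `FitConfig(min_points=3)`
tightens this).  Non-positive SLD values are floored at 0.1 cm (minimum
measurable lesion) with a warning.  Convergence failure is flagged, never
silent.  No equivalence to a specific FOCE implementation (NONMEM, nlme) is
claimed; at the 3–8 scans/patient density of the emulated trials the
scheme recovers generating values well (see below).

Defaults that matter: `sigma` floor 1e−3 cm and `ω²` floor 1e−6 keep the
penalised objective defined for noise-free/homogeneous test cohorts;
`min_patients` 10 guards against meaningless population estimates.

### Parameter recovery and the truncation bias

On cohorts observed on the full scan grid (n = 300, 8-weekly scans, noise
0.3 cm, log-SDs 0.3/0.4/0.5) the fitted `exp(μ)` recovers the generating
values within 10% per component (tested).  Under progression-triggered
truncation the recovery question changes character: stopping depends on the
*observed* noise — the running nadir is a minimum of noisy values (selected
low) and the triggering scan must exceed it by 20% (selected high) — so the
apparent decay is deepened and `exp(μ_B)` is biased upward by roughly
10–20% for *any* fitter that ignores the stopping rule.  With the noise
removed the truncated-design bias disappears (<5%), confirming the
mechanism.  This is a real feature of RECIST-style imaging drop-out, not an
estimator defect; correcting it would need a joint longitudinal–survival
model, which is out of scope here (and deliberately not used in the
analysis this package implements, because drop-out is dominated by
non-death progression).

## Reverse alignment is an approximation

The biexponential family is **not closed under reflection about the
progression scan**: reflecting the noise-free curve about `t = T` gives
`A e^{−BT} e^{Bs} + A e^{CT} e^{−Cs} − A`, whose three coefficients are
unequal, while the model forces all three to equal `A'`.  A reverse-time
refit therefore cannot reproduce the swapped rates exactly; numerically the
best fit places the nadir near its reflected position (TTN ≈ span − tp,
recovered to ~10–25% on noise-free trajectories) while the fitted rates can
sit far from the swapped values.  Note the exact swap would even be
self-contradictory: parameters `(C, B)` put the turning point at `−tp`,
i.e. TTN = 0 after clamping and TTG(reverse) = span ≠ TTG(forward).  The
identity TTG = span − TTN and the involution property of the reflection are
exact and tested; the rate-level duality is qualitative.  The same caveat
applies to any analysis fitting this model on progression-anchored
reversed series.

## Individual risk: signed concordance probability

For a metric with pre-specified benefit direction (TTG: higher is better;
GR: lower is better), a single-covariate Cox model (Efron tie handling,
Newton iteration, covariate centred) supplies `β̂`, and each unordered
patient pair contributes the model-implied probability that the
better-metric patient outlives the other,
`1/(1 + exp(β̂·(x_better − x_other)))`, ties contributing ½ — the
Gönen–Heller style model-based estimator, in a signed variant: when `β̂`
points against the pre-specified direction the CP falls below 0.5, which is
how reverse-alignment point estimates like 0.49 can arise.  The estimate
equals the standard unsigned estimator whenever the fitted sign matches
expectation.  CP is apparent (fitted and evaluated on the same patients);
no cross-validation, matching the analyses this package mirrors.

Inference is a percentile bootstrap (default 1,000 resamples of patients at
original size; `β̂` refitted per resample); a metric is called significant
when the 95% interval excludes 0.5.  No multiple-testing adjustment is
applied (per-metric CIs are reported as-is).  Forward alignment pairs
metrics with OS over all fitted patients; reverse alignment pairs
reverse-fit metrics with OS − PFS over progressed patients, excluding
progression-by-death records (their post-progression time is zero by
construction; the exclusion count is reported).

The Cox solver is implemented in-package because bootstrap and trial
resampling make it the innermost loop (~10⁵ fits per analysis); it agrees
with lifelines to ~1e−6 on tied and untied data (tested).  Kaplan–Meier
medians and their log-log CIs come from lifelines; a median is reported as
missing when the survival curve never reaches 0.5.

## Group risk: resampled test trials

A head-to-head trial between a test and a reference arm is emulated by
drawing, with replacement, the planned number of patients per arm (defaults
110/112) from the historical arms, each patient carrying PFS, OS, GR and
TTG intact; 1,000 replicates give predictive distributions of the PFS HR
(test vs reference), the GR mean ratio (test/reference) and the TTG mean
ratio (reference/test).  Both metric ratios are oriented so that values
below 1 favour the test arm and can be read alongside the HR; they are
*proxies* for an OS HR — no surrogacy mapping is claimed.  The squared
Pearson correlation between the two ratio vectors quantifies how
exchangeable the two metrics are as decision tools.

Per-patient metrics entering the resampler come from a single population
fit per arm; the mixed model is not refitted inside each replicate
(refitting 1,000 mixed models would be disproportionate; the choice is a
package decision and can be changed by driving the resampler with
externally supplied per-replicate metrics).

## Synthetic cohorts

`CohortSpec` defaults emulate a second-line docetaxel comparator arm;
presets for an erlotinib-like (6-weekly scans, early net growth, short
follow-up) and a first-line paclitaxel/carboplatin-like arm (larger
tumours, deeper response) are provided.  Per patient: log-normal
`(A, B, C)`; scans on a fixed grid (optional uniform jitter, default off);
additive N(0, σ²) noise floored at 0.1 cm; progression at the first scan
with SLD ≥ 1.2 × running nadir (a simplified RECIST rule on SLD only;
non-target/new-lesion progression can be emulated as an independent
per-scan hazard, default off); imaging stops at progression.  A small
per-interval death probability (default 0.015) produces the minority of
progression events that are deaths (~5%, matching the low proportions that
justify treating drop-out as uninformative of survival).  Post-progression
survival is exponential — independent of kinetics under the null model, or
with log-hazard linear in true GR and TTG under the linked model.
Administrative censoring acts as a calendar cut-off on both imaging and
survival.

Calibration of the docetaxel-like defaults: baseline `μ_A = ln 8.3` and
`ω²_A = 0.40` reproduce the target median/IQR of baseline SLD; `(μ_B, μ_C)`
solve "median week-8 change ≈ 0" jointly with a nadir at ~4 weeks; the
post-progression rate is ln 2 / 22.6 wk (median OS − PFS ≈ 5.2 months).
Rate IIV is set by the shape rule that NSCLC PFS distributions are
approximately exponential (CV ≈ 1), giving rate log-SDs of
√(ln 2) ≈ 0.83, i.e. `ω²_{B,C} = 0.64` — mid-range for published
tumour-growth-inhibition analyses.  Under these conditions the generated
arm hits median baseline SLD ≈ 8.3 cm, median PFS ≈ 3.7–5.5 months, median
OS ≈ 10 months, median OS − PFS ≈ 5.4 months and ~5% of progressions by
death (tested loosely).

What the generator does *not* emulate: lesion-level RECIST bookkeeping,
non-target/new-lesion reads beyond the optional random hazard, treatment
switching after progression, scan-time jitter of real calendars (off by
default), and — importantly — any frailty correlation between PFS and
post-progression survival: under the null model OS − PFS is pure noise with
respect to everything observed before progression.  Passing tests on these
cohorts therefore demonstrate the machinery and the alignment logic, not
real-data effect sizes.

### What the null model can and cannot reproduce

The qualitative alignment pattern emerges as designed: forward CPs for GR
and TTG are significantly above 0.5 (kinetics drive PFS, and PFS is part of
OS) while reverse CPs hover at 0.5 with CIs covering it.  The *magnitude*
of forward CPs, however, is capped near 0.60 under the null model: with
OS = PFS + an independent exponential of median ≈ 5 months, the
Gönen–Heller CP of even the strongest possible baseline covariate — PFS
itself — measures ≈ 0.596 (n = 4000), while published forward CPs from real
arms reach 0.63–0.72.  Two effects combine: the independent post-progression
time dominates OS variance, and the linear-Cox Gönen–Heller form compresses
discrimination for skewed covariates (the raw pairwise concordance of OS
given PFS is ≈ 0.71 in the same data).  Real arms plausibly carry
patient-level frailty linking PFS and post-progression survival, which the
null model deliberately removes.  This gap is measured and asserted
honestly by the acceptance-style pattern test rather than papered over.

## Numerical choices

* Turning-point evaluation is closed-form; the test oracle finds the root
  of the trajectory derivative by bisection (Brent) inside a provable
  bracket, robust to the near-flat minima of small-rate draws.
* Cox Newton iteration: ascent guaranteed by step halving; exponents
  clipped at ±500; constant covariates return β = 0 with infinite SE and a
  warning rather than an exception (bootstrap resamples may be degenerate).
* Percentile bootstrap (not BCa); resampling unit is the patient.
* LM per-patient solves use xtol/ftol/gtol 1e−12; the outer two-stage loop
  stops at a 1e−6 relative change in (μ, ω², σ).
* Problem sizes in the test-suite: population-fit checks run at n = 120–400
  patients and 10 pattern replicates; trial-simulator checks use the
  planned 110/112 arm sizes with 1,000 replicates; bootstrap calibration
  uses 200 replicates × 1,000 resamples.  These sizes are the package's
  chosen trade-off between Monte-Carlo precision and a test suite that runs
  in minutes on one CPU.

## Known limitations

* The two-stage fit is first-order; with very sparse or very noisy series
  the variance components inherit Laplace-approximation bias.
* Reverse-time rate estimates are structurally approximate (above).
* The progression rule ignores non-target and new lesions unless the
  random-PD hazard is enabled.
* Metric ratios as OS-HR proxies have no calibrated mapping to an actual
  hazard ratio; they support ranking/decision questions, not quantitative
  OS prediction.
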