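# Methods

## Scope

`tactsupp` implements the complete analysis chain of a movement-locked
tactile detection (tactile suppression) experiment, together with a
generative simulator of the experiment, so that every analysis stage can
be validated by parameter recovery without access to the original
recordings. The experiment it models: participants detect a brief
vibrotactile probe of one of 11 amplitudes on the right ring finger while
resting (baseline), shortly before a self-initiated wrist movement
(active), or shortly before a device-driven wrist movement (passive), in
sessions where the upcoming condition is announced (cue+) or not (cue−).
Half of the trials carry no stimulus. The analysis quantifies detection
with equal-variance signal-detection measures per amplitude bin and tests
condition effects with linear mixed models.

## Generative model

### Design

Each of the 6 movement × cue conditions holds 132 trials: 11 amplitudes ×
6 repetitions of stimulus-present trials plus an equal number of catch
trials, balanced across two blocks per session and shuffled within block
by a seeded RNG.

The default amplitude grid has 11 equally spaced levels with step
0.139/11 ≈ 0.01264 mm (top level 0.139 mm). The step is calibrated so
that the canonical 5-bin grouping of consecutive levels (2, 2, 3, 2, 2)
has bin mean amplitudes 0.019, 0.044, 0.076, 0.107, 0.133 mm at three
decimals. No equally spaced grid with a top level of exactly 0.140 mm
achieves all five of those means (the feasible step range for a `k·s`
grid is s ∈ [0.012619, 0.012647) and 0.140/11 ≈ 0.012727 lies outside
it), so the nominal "0.013 to 0.140 mm" description is internally
inconsistent; the calibrated grid is the default and both a literal
0.013-step grid (`AmplitudeGrid.literal_step`) and a 0.140-top grid
(`AmplitudeGrid.max_140`) remain available.

### Observer

Detection follows an equal-variance Gaussian signal-detection observer
with a linear transducer. On a signal trial of amplitude `a` (mm),

    P("yes") = guess + (1 − guess − lapse) · Φ(gain · a − λ)

and on a catch trial `P("yes") = guess + (1 − guess − lapse) · Φ(−λ)`.
With zero lapse/guess the generating sensitivity at amplitude `a` is
exactly `d' = gain·a` and the generating criterion `c = λ − gain·a/2`,
which makes the estimands of the downstream pipeline analytic — the
reason this observer family was chosen.

The `paper_like` preset uses gains of 16 (baseline), 10 (active) and
13 (passive) 1/mm with criteria λ = 1.0, 1.5 and 1.25 z-units and 2%
lapse/guess rates. These values preserve the empirical structure of the
phenomenon — sensitivity ordering baseline > passive > active, criterion
ordering active > passive > baseline, an active−passive sensitivity
contrast of ≈ −0.23 — while keeping every generating d' inside the range
that finite-trial cells can estimate without ceiling bias. The 50%
detection threshold λ/gain ≈ 0.06 mm sits mid-grid, matching the design
intent of an amplitude range spanning the threshold. Gains are *not*
calibrated to reproduce the absolute published group-mean d' values:
those sit near the measurement ceiling of a 12-trial cell, where the
loglinear-corrected estimator is necessarily biased, and no generative
setting can both match them and be recoverable. Absolute reproduction of
published group statistics is only possible from the original deposited
data (see the README's reproduction section).

Cohorts (`make_cohort`) add between-participant heterogeneity: a shared
sensitivity multiplier (SD 0.15) and shared criterion offset (SD 0.15)
applied to all conditions — these create the participant random-intercept
variance targeted by the mixed model — plus independent per-condition
jitter (SD 0.05). All deviates are truncated at ±2 SD so multipliers have
mean exactly 1 and the population-mean condition differences equal the
preset differences. The `null_effect` preset sets identical gains and
criteria in every condition.

### Timing

Trial timeline constants (ms): 1000 instruction, 3 × 500 countdown, 2500
movement window, 2000 response window, 750 inter-trial interval. The go
signal (end of countdown) is time zero.

Movement onsets are drawn per trial from Normal(1000, 139) ms for active
movements and Normal(1000, 20) ms for device-driven passive movements
(the device is far less variable than a human; the 20 ms value is a
package choice). Durations are Normal(1025, 80) and Normal(996, 20) ms.
Onset and duration families are assumptions — the source experiment does
not state distributional families — and are documented as such.

Stimulation scheduling reproduces the experiment's online rule
(`schedule_stimulation`): during the first five practice trials the probe
is fixed at 75 ms after the countdown; afterwards it is planned at the
mean of the five most recent movement onsets minus a 75 ms lead. Passive
probes are drawn from a normal fit to the participant's observed active
onsets, minus the lead (`sample_passive_stim_time`). Twelve practice
trials seed the onset history and are not emitted. Under stationary
onsets the generated active probe lead is centred on −75 ms with SD
≈ 139·√(6/5) ms; the published lead summaries (≈ −95 ± 139 ms active,
−86 ± 54 ms passive) are across-participant statistics of a drifting
human process that a stationary generator approximates but does not
reproduce exactly. `simulate_cohort(scheduling="iid")` replaces the
sequential rule with independent draws from its stationary distribution;
it is statistically equivalent for timing-independent observers and is
used for large Monte-Carlo studies.

An optional `gain_timecourse` multiplier lets the observer's sensitivity
depend on probe time relative to movement onset, used to validate the
detection-rate time-course analysis.

### Traces

Position traces are triangular out-and-back excursions (peak 100 encoder
units) anchored so the 2-unit threshold crossings fall exactly at the
recorded onset and offset; detected durations are therefore unbiased up
to sampling resolution. EMG traces are zero-mean Gaussian with a resting
scale of 5 a.u. and a burst scale added from 100 ms before onset until
offset, set per movement type (49 active, 24 passive, 8 baseline a.u.,
matching the observed ordering active > passive > baseline). Baseline
trials place their residual tone in a nominal 500–1500 ms window, which
the feature extractor also uses for baseline trials (no kinematic onset
exists there). The generator does not emulate real EMG spectra, motion
artefacts, or electrode noise; passing tests show the pipeline's
bookkeeping and ordering logic, not fidelity to physiological waveforms.

## Signal processing

Movement onset is the first sample after the go event whose absolute
excursion from the start position (position at go) strictly exceeds 2
encoder units; offset is the first sample after the peak excursion back
within 2 units (non-strict). Ties at a sample boundary resolve to the
earlier sample. A trace that never crosses, or never returns, raises a
typed error and the caller marks the trial invalid.

EMG preprocessing is full-wave rectification followed by a centred
moving average (default 50 ms; truncated windows at the edges keep the
length). The smoothing method is unspecified in the source description,
so this minimal standard envelope is a documented package choice; the
hardware band-pass is treated as already applied. The per-trial feature
is the mean of the 10 largest samples in the window from 500 ms before
onset to 500 ms after offset, minus the mean of the 1000 ms pre-stimulus
baseline taken from the instruction phase (the baseline statistic — mean
— is likewise a documented choice). The feature is exactly invariant to
adding a constant to the trace.

## Signal-detection pipeline

Trial exclusion is two-step. Step 1 removes behavioural/technical
failures: missing responses, trials flagged invalid, movement trials
without a detected onset. Step 2 keeps movement probes only if the
stimulation time relative to movement onset lies in [−300, 0) ms — the
−300 boundary inclusive ("maximum time" reading), onset itself excluded
(probes at or after onset). Baseline and catch trials are untouched by
step 2. Summaries account for every trial: kept + excluded = total.

Signal trials are grouped into 5 amplitude bins of 2, 2, 3, 2, 2
consecutive levels; catch trials are split randomly into 5 near-equal
groups per condition (66 → 14+13+13+13+13) with a seeded RNG, since no
principled amplitude exists for them. Note the bin trial counts implied
by 6 reps (12, 12, 18, 12, 12 signal trials) differ from some published
per-bin counts (12, 12, 16, 12, 12), which are inconsistent with a
2-2-3-2-2 partition at 6 reps; the partition is taken as authoritative.

Hit and false-alarm rates use the loglinear approach conditionally: only
when a rate sits at 0 or 1 are 0.5/+1 added to both counts/totals (an
`always` mode is available, as conventions differ). Measures are
d' = z(H) − z(F), c = −(z(H)+z(F))/2 and relative c = c/d' (undefined at
|d'| ≈ 0). Conditions whose mean |d'| < 0.1 ("nearly zero"; the epsilon
is configurable — no published value exists) or mean |relative c| > 30
are flagged and all their bins excluded.

Detection thresholds fit a cumulative-Gaussian psychometric function by
maximum likelihood (guess/lapse fixed at 0 by default), falling back to
linear interpolation of per-amplitude detection rates when the fit fails.
The detection-rate time course bins movement probes by stimulation time
relative to onset (default 50 ms bins over [−300, 0) ms — the exact
published supplementary edges are not stated) and reports per-bin rates
with Clopper-Pearson 95% intervals; empty bins are absent, not zero.

## Mixed-model inference

The condition model is `response ~ movement * cue (+ amplitude)` with a
participant random intercept, fitted by maximum likelihood. statsmodels'
MixedLM provides the fit; because its generic optimizer can stall near
the zero-variance boundary, the two variance components are polished on
the exact profiled log-likelihood (closed form for a random-intercept
model), taking the better optimum. Reported dummy-coding reference
levels are baseline (movement) and cue− (cue).

Satterthwaite denominator degrees of freedom are computed in-package:
for a contrast ℓ, df = 2·f²/Var(f) with f(θ) = ℓ'C(θ)ℓ, the gradient of f
and the observed information of the profiled log-likelihood both obtained
numerically on the log-variance scale (the df is invariant to that
reparameterization). Type-III F tests use the sum-to-zero
parameterization, in which each term's Type-III hypothesis is that its
own coefficients vanish; multi-df tests aggregate per-eigencontrast dfs
in the standard way (df = 2E/(E−q) with E = Σ νₘ/(νₘ−2)). SS and MS
follow the mixed-model reporting convention SS = F·df_num·σ̂². The
engine reproduces R's `lmerTest::anova(type=3)` and
`emmeans(..., lmer.df="satterthwaite")` to the reported precision; one
test runs that comparison as an independent oracle.

Marginal means average the design rows over the other factor at the
covariate grand mean (amplitude enters uncentered as the bin mean).
Pairwise contrasts are Bonferroni-adjusted (p × number of pairs, capped
at 1); CIs are Wald with the contrast's Satterthwaite df. Cohen's d is
converted from the t statistic as d = 2t/√df by default (an
estimate/total-SD variant is available) — the effect-size formula behind
the published values is not stated, so the conversion convention is a
documented choice.

Spearman correlation families use average-rank rho with a Bonferroni
per-test threshold (α/8 = 0.00625 by default, mirroring the eight
correlations per movement parameter). The a-priori sample size for a
paired two-tailed t test uses the exact noncentral-t power function (no
normal shortcut); d = 0.5, α = 0.05, power 0.80 gives n = 34.

## Validation design and problem sizes

`tactsupp.validation` runs the recovery and calibration studies used by
the acceptance tests and `scripts/acceptance.py`:

- **Recovery/coverage** (`recovery_study`): 200 zero-lapse paper-like
  cohorts of 34 observers with 48 repetitions per amplitude (96–144
  signal and ~105 noise trials per bin). At these counts the
  signal-detection estimator's small-sample and within-bin-pooling biases
  are an order of magnitude below the 0.1 bias bound, while
  between-participant heterogeneity keeps the contrast SEs large relative
  to the residual systematic error so that nominal 95% CI coverage is
  attainable. At the experiment's own per-cell counts (12 signal / ~13
  noise) the loglinear-corrected d' is biased by 0.2–0.5 near the rate
  boundaries — an intrinsic property of the estimator, not of this
  implementation — so recovery is validated in the well-powered regime.
- **Null calibration** (`null_calibration_study`): 300 no-effect cohorts
  at the experiment's design scale; condition-specific jitter is off so
  the movement null is exactly true (shared participant offsets remain
  and are absorbed by the random intercept). The movement F test's type-I
  rate is checked against 5% within Monte-Carlo error, and a vectorized
  10⁴-replicate study checks the Spearman family's rejection rate against
  its 0.05/8 threshold.
- **Exclusion behaviour** (`exclusion_study`): default paper-like cohorts
  at design scale; reports the fraction of condition cells excluded by
  the d'/relative-c rules (well under 1%) and the movement-window
  exclusion fractions (active > passive, as the active onset variability
  is larger).

## Numerical choices and degenerate inputs

- Normal quantiles/CDFs come from scipy; the test suite carries an
  independently coded quantile (rational approximation + Halley step) as
  an oracle.
- The psychometric fit optimizes (μ, log σ) by Nelder-Mead with an
  interpolation-based start; implausible optima fall back to
  interpolation and are flagged via `method_`.
- Satterthwaite dfs are clipped to [1, 1e7]; a singular information
  matrix (boundary fits) falls back to the residual df and the fit's
  convergence flag reports the optimizer state. Rank-deficient fixed
  designs raise a typed error rather than fitting silently.
- Zero-variance inputs: flat position traces, all-yes/all-no psychometric
  data, constant correlation vectors and empty SDT cells all raise typed
  errors or set explicit undefined flags; they are never silently
  dropped.

## Known limitations

- The simulator is stationary: no learning, drift, fatigue, or serial
  dependence in onsets or responses, so the printed across-participant
  lead summaries are only approximated.
- The equal-variance linear-transducer observer cannot express published
  absolute group d' levels in a recoverable way (see above); unequal
  variance and ROC-style analyses are out of scope.
- Only random intercepts are modelled (per the analysis being mirrored);
  per-condition participant heterogeneity beyond the intercept inflates
  residual variance rather than being modelled as random slopes.
- EMG synthesis is a scaled-noise envelope; spectral content is not
  modelled.
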