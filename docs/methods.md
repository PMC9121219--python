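# Methods

## Overview

`drawcog` studies the *drawing process* as a marker of global cognition.
The analysis chain is: raw pen-event streams → six kinematic features →
covariate-adjusted correlations with a 0–30 cognition score → a tuned
random-forest regressor trained on one cohort and tested on another,
with permutation inference and Shapley attribution. Because no human
data ship with the package, a synthetic-data generator plays the role of
the study populations; its defaults encode the study conditions the
analysis assumes (cohort demographics, device characteristics, and a
target feature–score correlation structure).

## Feature definitions and conventions

The six features and the exact conventions used (the field's naming is
standard, but the estimator conventions matter for reproducibility):

- **Instantaneous speed**: for each consecutive on-surface sample pair
  within a stroke, Euclidean displacement over the timestamp difference.
  Pairs spanning stroke boundaries are excluded; no smoothing; Δt comes
  from timestamps, not from the nominal rate, so dropped samples are
  handled correctly.
- **Speed CV**: sample SD (n−1 denominator) of the pooled per-pair
  speeds across all strokes, divided by their mean. Pooling (rather than
  averaging per-stroke CVs) treats the speed signal as one time series.
- **Pressure MAD**: median absolute deviation about the median of all
  on-surface pressure samples, *without* the 1.4826 normal-consistency
  constant (raw MAD).
- **Inclination SDs**: sample SDs of the horizontal and vertical
  inclination angles over on-surface samples, treated as plain real
  quantities in degrees (no circular statistics; dispersions here are
  far from the wrap-around regime).
- **Strokes**: maximal runs of samples with pressure > 0. Pressure is
  the direct contact signal; hover distance is ignored for segmentation.
- **Within-stroke pauses**: greedy anchor scan. From anchor sample *i*,
  extend *j* while every sample *i..j* lies within 0.25 mm of sample
  *i*'s position; if t_j − t_i > 100 ms (strictly), emit the pause
  [t_i, t_j] and restart at *j*+1, else advance the anchor by one. The
  circle is centered on the anchor sample, which makes the rule
  deterministic and exactly checkable by an O(n²) reference scan.
- **Between-stroke pauses**: every pen-up interval between consecutive
  strokes, with no minimum duration and no cap.
- **Pause ratio**: (within-stroke + between-stroke pause time) divided
  by (total stroke time − within-stroke pause time). Dwelling is not
  drawing motion, so within-stroke pause time is subtracted from the
  denominator.

Truncated sessions are processed as-is (features from partial drawing
data are legitimate inputs downstream).

## Synthetic-data generator

### What it emulates

- **Device**: 180 Hz sampling, 252 × 186 mm active area, 8192 pressure
  levels (emitted on a normalized [0, 1] scale and quantized to 1/8191
  steps), 1° inclination resolution.
- **Task**: 25 targets connected by 24 strokes. Targets are scattered
  uniformly inside a 10-mm margin with rejection sampling to keep a
  ≥ 20 mm mutual spacing (avoids degenerate zero-length strokes).
- **Cohorts**: an older, more educated "US-like" cohort (age 83.4
  (SD 6.9), 71% female, 16.3 (2.3) years of education, score 24.4 (3.2))
  and a younger "Japan-like" cohort (73.3 (4.5), 51% female, 13.8 (2.0),
  24.4 (2.6)). Ages are truncated at 65, education at 6 years; the score
  is drawn normal, clipped to the configured 16–30 participant range and
  rounded to an integer. Sex is coded 0/1 (1 = female).
- **Kinematics**: strokes traverse consecutive targets at a constant
  nominal speed modulated by AR(1) multiplicative log-noise (φ = 0.9);
  planned dwells hold the pen with ~5 µm jitter; pen-up gaps emit
  zero-pressure samples with a positive hover bump; pressure (φ = 0.97)
  and inclinations (φ = 0.99) are AR(1) series around per-participant
  baselines. Baselines for a cognitively average participant: 30 mm/s
  mean speed, speed CV 0.55, pause ratio 0.45, pressure MAD 0.06,
  inclination SDs 8° and 6°. With a ~2,200 mm total path this yields
  sessions of roughly two minutes, matching the intended task length.
  A constant-speed profile (rather than a per-stroke minimum-jerk bell)
  is used deliberately so that a noise-free session has near-zero speed
  CV; the speed-variability *feature* then measures configured
  variability, not the shape of a deterministic velocity profile.

### Cognition linkage and calibration

The score y is drawn first, standardized within-cohort as
z = (y − μ)/σ using the configured moments, and mapped to each
generating parameter on the log scale:

    g_f = base_f · exp(s · β_f · z + ε_f),   ε_f ~ N(0, σ_noise²)

with strength scale s (s = 0 disables all association) and
σ_noise = 0.25 by default. Log-linear mapping keeps dispersions
positive and makes the population correlation between y and log g_f
equal to β_f/√(β_f² + σ_noise²). `EffectConfig` therefore stores
*target correlations* r_f and derives β_f = σ_noise · r_f/√(1 − r_f²);
defaults are (speed mean 0, speed CV −0.42, pause ratio −0.49, pressure
MAD −0.34, horizontal-inclination SD +0.33, vertical-inclination SD
+0.17), i.e. worse cognition ⇒ more variable speed and pressure, more
pausing, stiffer pen carriage. Realized sample correlations track the
targets because feature-extraction noise from a two-minute session is
small relative to σ_noise (sessions have ~20,000 samples; empirically
the realized r's sit within ~0.06 of target at n = 1000).

Two couplings needed explicit handling:

- Dwell samples have near-zero speed and inflate the pooled speed CV.
  The dwell budget is therefore held *constant* (3% of drawing time,
  not cognition-linked), and the within-stroke log-noise spread is
  solved from cv_total² = (cv_move² + d)/(1 − d), where d is the dwell
  share of on-surface time, so the realized pooled CV equals the
  generating parameter. Pause-ratio modulation happens through pen-up
  gaps, which do not contribute speed samples.
- Demographics are generated but, by default, *not* causally linked to
  kinematics, so partial and plain correlations agree. An optional
  confound switch (`age_confound` ∈ [0, 1)) loads age negatively on both
  the score and the mean drawing speed; this exists to test that
  covariate adjustment removes a spurious speed–score association.

Determinism: each participant gets an independent child RNG spawned
from the cohort seed, so output is bit-reproducible and independent of
consumption order; `cohort_parameters` draws exactly the same
demographics and generating parameters as full session synthesis, which
the test suite exploits for cheap statistical calibration checks.

### What the generator does *not* emulate

No actual task stimuli or target-sequencing errors, no fatigue or
learning trends within a session, no handedness or device-placement
effects, no heavy-tailed or heteroscedastic noise, and the
feature–score linkage is exactly log-linear. Passing tests therefore
show that the *pipeline* recovers a known planted structure under
realistic signal-to-noise; they do not validate the clinical claim on
human data.

## Statistics

- **Partial correlation**: residualize x and y on [intercept |
  covariates] by least squares; r = Pearson correlation of residuals;
  two-sided p from t = r·√((n−2−k)/(1−r²)) with n−2−k df; 95% CI =
  tanh(atanh r ± 1.96/√(n−3−k)). With k = 0 this reduces exactly to the
  plain Pearson test.
- **Multiple testing**: Benjamini–Hochberg step-up within the
  six-feature family of each subset (combined, cohort A, cohort B),
  computed per its definition (sort, q_(i) = p_(i)·m/i, cumulative
  minimum from the largest, cap at 1, restore order).
- **Cohort contrasts**: pooled-variance (Student) two-sided t tests for
  the continuous demographics — chosen over Welch to match the
  single-df reporting convention of the reference cohort tables — and a
  1-df chi-square without continuity correction for the sex split
  (which reproduces χ²₁ ≈ 3.63 for splits of 39/16 vs 19/18).

## Regression model

`DrawingForestRegressor` wraps scikit-learn's random forest:

- 500 trees (fixed); exhaustive search over max_depth {2, 3, 4} ×
  max_features {2, 3, 4, 6} × bootstrap sample fraction {1.0, 0.75,
  0.5} × min_samples_leaf {2, 3, 4, 5} = 144 candidates, enumerated
  depth-major.
- 10-fold CV with fold assignment shuffled once from the seed and
  shared across candidates; selection by lowest mean CV squared error;
  ties broken by the first candidate in enumeration order; final refit
  on all training data. Every candidate evaluation is logged in
  `cv_results_`.
- **Metrics**: R² = 1 − SS_res/SS_tot with SS_tot about the *test-set*
  mean. Under this convention R² and the squared Pearson correlation
  can legitimately diverge on an external cohort.
- **Permutation test**: permute *training* labels, refit with the
  already-chosen hyperparameters (no re-tuning; full re-tuning per
  permutation is available behind `retune=True` but is costly and not
  the default), evaluate on the intact test set;
  p = (1 + #{null ≥ observed})/(1 + B), which avoids p = 0 and has
  minimum 1/(B+1).
- **Shapley attribution**: exact interventional Shapley values by full
  coalition enumeration (2⁶ = 64 coalitions for six features), with
  coalition values averaged over a background sample (default: up to 50
  seeded rows of the explained data). Additivity — base value plus the
  attribution sum equals the prediction — holds to machine precision
  per sample. Importance is the mean absolute attribution with its SD.
  Enumeration is preferred over path-dependent tree approximations
  because it is the axiomatic reference quantity and is cheap at d = 6.

## Numerical and design choices

- On-surface ⇔ pressure > 0; enforced as a stream invariant together
  with strictly increasing timestamps and pressure–hover exclusivity.
- Speed CV uses the n−1 SD; a zero-mean, zero-SD speed set returns
  CV = 0, while zero mean with nonzero SD is an error.
- Pause radius/duration use strict inequality (> 0.25 mm leaves the
  circle window; > 100 ms qualifies a dwell).
- Grid fraction 1.0 maps to bootstrap resampling of n samples (the
  forest's `max_samples=None`), keeping every remaining ensemble
  parameter pinned explicitly so behavior is library-version stable.
- All seeds flow through `numpy.random.SeedSequence`; derived seeds are
  reduced below 2³¹.

## Problem sizes

The default analysis configuration uses two cohorts of 200 participants,
the full 144-candidate search, and B = 200 permutations (the
`n_permutations` default of the pipeline config is 1000; the acceptance
script scales it to 200). The statistical suite checks run at sizes
chosen to make their conclusions stable while keeping the whole suite
fast: generator calibration at n = 500 per cohort; signal recovery over
10 replicates of 200/200 with a reduced 6-candidate grid and 100-tree
forests; permutation-test type-I error over 100 repeats at B = 99 with
40-tree forests on the generator's parameter layer (the p-value
calibration property is learner-agnostic, so a smaller forest checks the
same property at a fraction of the cost).

## Known limitations

- The generator's linkage is a calibration device, not a mechanistic
  model of drawing behavior; effect sizes are planted, so recovered
  cross-cohort R² reflects the configured correlation structure.
- Inclination angles are linear, not circular; sessions without
  on-surface samples, or with a single-sample stroke only, are rejected
  rather than imputed.
- The permutation scheme conditions on the tuned hyperparameters;
  tuning optimism under the null is therefore not penalized unless
  `retune=True` is used.
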