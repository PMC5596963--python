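# Methods

`gaitrsp` re-implements, as a tested library, an analysis pipeline that
predicts which knee-osteoarthritis patients will respond to a 6-week hip
strengthening programme, using only pre-intervention data: gait waveforms
from four body-worn IMUs (lower back, thigh, shank, foot; ±16 g / ±2000 °/s
at 100 Hz) and the four KOOS subscales (pain, symptoms, ADL, QoL).  Because
no raw patient data is available, all stages are exercised on synthetic
cohorts whose statistical structure matches the assumptions of the method;
what that does and does not demonstrate is discussed at the end.

## Signal processing

**Filtering.**  All six channels of every trial pass through a 4th-order
Butterworth low-pass at 10 Hz.  The filter is applied forward–backward
(`scipy.signal.filtfilt`), i.e. zero-phase: a causal single pass would lag
waveform features by several samples and bias the gait-event timing that
segmentation depends on.  Each trial is reflect-padded by one second per
end before filtering to suppress start-up transients in the first stride.
Whether the original analysis was zero-phase is unknown; zero-phase is this
package's choice and is applied uniformly.

**Attitude correction.**  A body-mounted sensor sits at an unknown
pitch/roll tilt.  During a ≥1 s quiet-standing trial the accelerometer
measures pure gravity, so the mean acceleration vector ḡ estimates the
sensor-frame "down".  We build the minimal rotation R (axis ĝ × ẑ, angle
arccos(ĝ·ẑ)) with R·ĝ = (0,0,1), and apply it to every walking-trial
acceleration sample.  Gravity contains no heading information, so yaw is
deliberately untouched; anteroposterior/mediolateral axis labels follow the
mounting convention (sensor x forward, y lateral).  Degenerate guard: a
mean-vector magnitude outside [0.5, 1.5] g is rejected as "not static".  An
exactly inverted sensor (ĝ = −ẑ) maps to a 180° rotation about x by
convention.  Gyroscope channels are filtered but never rotated: event
detection reads the sensor-frame mediolateral axis directly.

**Event detection.**  The foot's mediolateral angular velocity shows one
dominant positive peak per stride at mid-swing, flanked by negative troughs
at toe-off (before) and initial contact (after).  The flat foot in
mid-stance produces a second, smaller local maximum between the IC and TO
troughs, so peak picking is two-stage: candidate peaks need prominence
≥ 50 °/s (configurable), and only peaks with at least half the maximum
candidate prominence are kept — a shift-invariant dominance rule.  A median
inter-peak interval then sets the minimum peak separation (half a stride)
and the trough-search windows (40% of the interval before/after each
peak).  Incomplete first/last strides are discarded; fewer than 6 complete
strides is an error.  The rule is validated against the generator's ground
truth: exact recovery in the noiseless case, ≤ ±2 samples (20 ms) at
default noise.

**Segmentation and time-normalization.**  Each IC→IC cycle is split at TO
and linearly interpolated onto 60 stance + 40 swing points per axis (linear
rather than spline: monotone, no overshoot).  The stance grid runs from IC
to TO inclusive; swing starts one grid step after TO — so a cycle whose
stance spans exactly 60 samples and swing exactly 40 samples is returned
unchanged, and re-normalizing an already-gridded cycle is the identity.
Cycles whose stance fraction falls outside (0.4, 0.8) are dropped as event
mis-detections.  The retained cycles (≥5 required) are ensemble-averaged
and concatenated — vertical, anteroposterior, mediolateral — into one
300-point waveform per sensor, giving an n×300 cohort matrix per placement.

## Feature reduction

Each sensor's n×300 matrix is column z-scored (sample SD, ddof=1; constant
columns get scale 1) and decomposed into n−1 principal components, which
retain 100% of the variance of a mean-centered matrix of rank ≤ n−1.
Column scaling equalizes the influence of waveform regions with very
different variances; a centering-only mode is available (`scale=False`)
since the choice is not dictated by the procedure itself.  Component signs
are fixed (largest-magnitude loading element positive) so that feature
names like `T25` are stable across runs and row orderings.  PC scores are
named `B#`, `T#`, `S#`, `F#` by placement and joined with the four baseline
KOOS subscales (`koos_pain`, …) in a fixed column order: back, thigh,
shank, foot, PCs ascending, KOOS last.

The PCA is fit once on the full cohort and reused inside cross-validation,
mirroring the published procedure's cohort-level 39×38 score matrix.  This
leaks unlabeled variance structure across folds; since PCA never sees the
labels the leak is mild, but a strict per-fold refit can be had by passing
`pca_models=None` per training subset.  The package keeps the
procedure-faithful default and flags the caveat here rather than silently
"improving" the method.

## Responder labels

For subject i and subscale s, the individual effect size is
d(i,s) = (post(i,s) − pre(i,s)) / SD_pre(s), with SD_pre the cohort
baseline sample SD.  The literature does not pin down the denominator for
individual change scores; a pooled pre/post SD is available via
`denominator="pooled_sd"`.  The four subscale d values are averaged and
thresholded: mean d < 0.2 → Non-responder, 0.2 ≤ d < 0.8 → Low, d ≥ 0.8 →
High; boundaries go to the higher band, and worsening (negative d) is
Non-response.  The maximum chance criterion — always predicting the largest
sub-group — is 100·max(n_g)/n; for the 10/20/9 design that is 51.3%, the
baseline any classifier must beat.

## Classification

**LDA.**  Pooled within-class covariance with a ridge of 1e-6 on the
diagonal (greedy selection can propose collinear feature sets), empirical
priors, prediction by argmax of the linear Gaussian class scores.  With k
classes and ≥ k−1 features the model carries exactly k−1 canonical
discriminant functions (generalized eigenvectors of between-class scatter
against the pooled covariance), whose coefficients feed the importance
report.  Tests check exact agreement with an explicit Gaussian-density
Bayes oracle and with scikit-learn's implementation.

**Folds.**  Stratified 10-fold assignment is done by dealing each class's
shuffled members across folds with a continuing pointer: per-fold class
counts differ by at most one, folds stay non-empty, and — unlike library
stratifiers that refuse n_splits larger than the smallest class — a
9-member class simply leaves one fold without that class, keeping the
10-fold design intact for a 10/20/9 cohort.  Folds are capped (with a
warning) only when there are fewer subjects than folds.

**Sequential forward selection.**  Starting from no predictors (baseline:
each training fold's majority class), every unselected candidate is scored
by the total cross-validated misclassification count of LDA on
selected ∪ {candidate}; the best candidate is added only if strictly better,
ties break to the first feature in the deterministic column order, and the
search stops at the first non-improving step.  The error trajectory is
therefore strictly decreasing.  Scoring prunes a candidate as soon as its
running error count reaches the current best, which leaves the selected set
unchanged but makes the 10×10×15-set design cheap (~40 s for a full
cohort on one CPU; the acceptance script reports the measured time).

**Repetition and comparison.**  Iteration i re-deals folds with generator
seed (master, i) and reruns the selection; the mean (SD) accuracy over 10
iterations is the reported figure, formatted `74.4 (0.02)%`.  All 15
non-empty subsets of {back, thigh, shank, foot} are evaluated and compared
by one-way ANOVA on per-iteration accuracies followed by Fisher's LSD
(unprotected pairwise t-tests on the pooled MSE, α = 0.05); the report
names the best set and every set not significantly different from it.
Identical accuracy vectors are defined to compare at p = 1.

**Bias, and the two evaluation modes.**  The default `"selection"` mode
reports the selection's own CV accuracy, as the original procedure does.
That figure is optimistically biased: the greedy search minimizes exactly
the quantity being reported, over ~40–156 candidates at n = 39.  The
`"nested"` mode reruns the whole selection inside each outer training split
and scores held-out folds only.  The permutation-label control is run in
nested mode for precisely this reason — under the null, selection-mode
accuracy sits far above chance by construction, while nested accuracy does
not.  Users quoting a generalization estimate should quote the nested one.

**Reporting.**  Feature importance is the sum of squared discriminant
coefficients across the k−1 functions, normalized to 100%, computed on a
final model fitted to z-scored selected features so gait PCs and KOOS
subscales are comparable.  Loading maps project selected gait PCs back
onto the 300-point cycle as importance-weighted sums of loading vectors
(linear in the weights; zero where nothing was selected); figures are
optional, JSON/CSV outputs never require a display.

## The synthetic generator

The generator is a statistical emulator of treadmill gait, not a
biomechanical simulation.  Choices, made once and kept:

- **Waveforms.**  Per placement and axis, sums of ≤6 Gaussian bumps
  positioned in % gait cycle (impact transient just after IC, push-off
  activity near TO, a swing lobe), with amplitudes of 0.1–1.2 g growing
  from back to foot as real accelerations do.  Gravity enters through each
  sensor's random pitch/roll mounting tilt (sd 5°, no yaw — gravity-based
  correction cannot observe yaw, so simulating it would only add an
  unrecoverable nuisance).  Additive white accelerometer noise sd 0.05 g,
  gyro noise sd 5 °/s.
- **Timing.**  Subject cadence ~ N(1.0, 0.05) gait cycles/s; per-stride
  multiplicative duration jitter sd 2%, so cycles differ in length and
  time-normalization is exercised non-trivially.  Stance fraction 0.60.
  60 s walking and 5 s static trials at 100 Hz.
- **Foot gyro.**  Mediolateral axis: troughs −200 °/s at IC and −150 °/s at
  TO, +300 °/s mid-swing peak (sign convention fixed here; configurable
  only by editing the template).
- **Responder structure in gait.**  Each subject carries a latent effect
  level = group code (Non=0, Low=1, High=2) + N(0, 0.35).  The thigh
  observes this level with small extra noise (sd 0.15) through bumps in
  mid-stance (vertical) and near toe-off (AP); the back observes a weaker
  (0.6×/0.4×) and much noisier (sd 0.55) echo in its vertical channel
  before TO and IC; shank and foot carry none.  The extra observation
  noise matters: if two sensors read the same latent trait noiselessly
  they are statistically interchangeable regardless of amplitude, and the
  "thigh is the best single placement" structure would be accidental.
  Effect scale 0.08 g per level unit — comparable to the between-subject
  amplitude variability (multiplicative sd 0.10), so groups overlap but
  are learnable.
- **KOOS.**  Baselines ~ N(62/57/52, 12) for Non/Low/High (worse baselines
  improve more, leaving baseline KOOS weakly predictive), clipped to
  [5, 90].  Each subject draws a target mean d uniformly inside its label
  band with margins (Non: [−0.15, 0.10], Low: [0.30, 0.70], High:
  [0.90, 1.40]), per-subscale jitter sd 0.08; changes are scaled by the
  realized cohort baseline SD and post scores clipped to [0, 100].  The
  margins keep the labels recomputed by the outcomes module in agreement
  with the intended groups for ≥95% of subjects (empirically ~100%).

**What passing tests show — and don't.**  The synthetic cohorts prove that
the chain recovers what was planted: events to ±2 samples, mounting
rotations to noise level, the thigh as best single sensor (averaged over
five cohort seeds; individual seeds can deviate because selection-mode CV
at n=39 is noisy), classification far above the 51.3% chance criterion,
and collapse to chance under label permutation.  They do not show that
real knee-OA gait contains such group differences, nor that the published
cohort's accuracies (74.4% thigh, 80.0% back+thigh, 81.7%
back+thigh+shank) would be reproduced — the raw data for that cohort was
never deposited, and the template shapes here are free choices, not fits.

## Problem sizes used in the shipped checks

Unit and acceptance tests run on cohorts of n = 39 (five seeds) for
recovery checks, n = 12–20 for signal-level checks, and toy matrices for
algebraic identities.  The acceptance script processes five n = 39 cohorts
end-to-end, a full 15-set 10×10-fold analysis on one of them, and a
5-permutation nested-CV null, finishing in well under five minutes on a
single CPU.
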