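# Methods

This note documents the models, parameter choices, numerical decisions and
limitations behind `soarclass`.  Module references are to
`src/soarclass/`.

## Sequential change-point segmentation (`segmentation`)

The stream (by default the sway `x` channel, the axis most responsive to
flight-behavior changes) is treated as piecewise i.i.d. Gaussian with
unknown mean and variance per regime.  For the current run of length `t`,
the monitor computes the generalized likelihood ratio statistic

```
D_t = max_k  t·log σ̂²_full − k·log σ̂²_left(k) − (t−k)·log σ̂²_right(k)
```

over candidate splits `k ∈ [min_side, t − min_side]`, with
maximum-likelihood (1/n) variance estimates.  A change is declared when
`D_t > h_t`; the boundary is the argmax split `k̂`, and monitoring restarts
at `k̂ + 1`.  The burn-in (`startup`, default one second of observations,
i.e. the rounded nominal rate) is applied after every restart, counting the
reused post-change observations toward the new run.  The final partial run
closes as the last segment.

**Thresholds.** `h_t` must make the false-alarm hazard per observation under
a pure-noise stream ≈ 1/ARL₀ (ARL₀ = expected run length to a false alarm;
default 50,000 observations).  No closed form exists, so thresholds are
Monte-Carlo calibrated:

* *Conditional-hazard route* (ARL₀ ≤ 2000; used by the scaled studies and
  tests): a pool of `calibration_reps` standard-normal streams is monitored
  jointly; at each run length the threshold is the interpolated
  `1 − 1/ARL₀` quantile of `D_t` among streams that have survived so far,
  and exceeders are replaced by a surviving stream's history spliced onto
  their own future innovations (keeping pool size and survival conditioning
  intact).  The raw curve is smoothed with a centered 51-point moving
  average.  Self-consistency at ARL₀ = 500 with 1000 calibration streams:
  the empirical mean run length on fresh streams lands within ±15% of the
  target (the acceptance suite measures this).
* *Tail-extrapolated route* (ARL₀ > 2000): survival conditioning is
  negligible at such rare alarm rates, so `h_t` is the unconditional
  `1 − 1/ARL₀` quantile of `D_t`, estimated on a run-length grid by fitting
  an exponential upper tail (mean-excess over the 98th percentile) to
  simulated null statistics and extrapolating.  The default curve
  (ARL₀ = 50,000, `min_side` = 5) ships as package data
  (`data/cpm_thresholds_arl50000.json`, regenerable with
  `segmentation.build_default_threshold_cache`); thresholds between grid
  points are linearly interpolated and extend flat beyond the grid.

**Numerical choices.** The split scan evaluates at most `k_cap = 256`
candidate splits per window, evenly thinned — exact for windows up to
`256 + 2·min_side` samples, which covers typical behavior segments — and
each detection is followed by a full-resolution local refinement of `k̂`
around the coarse argmax, so boundary placement is not quantized.
Calibration and monitoring share the identical capped statistic, keeping
thresholds self-consistent.  Zero-variance windows are floored at
`var_floor = 1e−12`, so a noiseless constant stream yields `D_t = 0` and a
single segment rather than an error.  `min_side = 5` because MLE variances
on fewer points are unstable.  At low sampling rates the one-second burn-in
is clamped to at least `2·min_side` observations.

## Per-segment features (`features`)

Eight statistics per axis — mean, min, max, SD (n−1 denominator), skewness
and kurtosis as population moment ratios (`m₃/m₂^1.5`, `m₄/m₂²`; kurtosis
non-excess, 3 in the normal limit), trend (OLS slope in g/s, so the value
is sampling-rate invariant), dominant frequency (peak of a linearly
detrended periodogram, DC excluded, in Hz) — plus the three inter-axis
Pearson correlations on raw samples and ODBA, for 28 features total.

ODBA separates static from dynamic acceleration with a centered running
mean per axis over a 1 s window; the window shrinks symmetrically at trace
edges, so the estimate stays phase-centered and constants are reproduced
exactly.  Because typical segments (~0.4 s) are shorter than the smoothing
window, the static component is estimated on the full trace and sliced per
segment.  The per-segment ODBA value is the mean over samples of
`|dyn_x| + |dyn_y| + |dyn_z|`: a mean rather than a sum so that intensity
is not confounded with segment duration, and absolute values because signed
dynamic components cancel to ≈ 0.  Segments need ≥ 2 samples; skewness and
kurtosis are reported missing (NaN) below 3 samples or at zero variance.

## Ethograms and majority labeling (`labeling`)

The simple ethogram is {flapping, soaring, sitting}; the complex one splits
flight into straight vs banking variants at a body roll of about 20°.
Soaring aggregates gliding, thermal circling, wing tucks and single wing
beats, which share low energetic cost.  Each segment's time span (half-open,
`[t_a, t_b)`) is intersected with every annotation interval; the label with
the largest overlap wins, with the majority fraction recorded.  Duration
ties break deterministically toward the behavior whose annotation starts
earliest, and are flagged.  A segment overlapping *any* excluded interval
(bird on the glove, out of frame) is dropped whole rather than trimmed;
segments with no annotation cover are dropped as unannotated.

## Classifiers (`classify`)

**Random forest** (scikit-learn's `RandomForestClassifier` behind this
module's protocol): the grid scans ntree ∈ {500, …, 4000} by 500 and
mtry ∈ {1, …, 28} (an mtry of 0 is meaningless for split sampling), selects
the out-of-bag-error argmin with ties toward smaller ntree then smaller
mtry.  Variable importance is permutation importance (mean decrease in
accuracy) computed on held-out data: each feature column is permuted and
the accuracy drop recorded, seeded and sorted.  OOB-sample permutation
(per-tree) is not exposed by a stable scikit-learn API; held-out
permutation estimates the same quantity.

**KNN** classifies individual tri-axial measurements after per-feature
min-max normalization fitted on the training set only (test values clipped
to [−0.5, 1.5]).  K is selected by test-set accuracy on the coarse grid
5–50 by 5; the two best coarse values bracket a unit-step refinement; the
final K is the accuracy argmax with ties toward smaller K.  Prediction is a
majority vote of the K nearest neighbors under Euclidean distance; vote
ties resolve to the lexicographically smallest label, matching an
exhaustive brute-force oracle (property-tested).  Selecting K on the test
split mirrors the original workflow; the repeated cross-validation summary
provides the unbiased complement.

**Metrics.** One-vs-rest per class: sensitivity, specificity, PPV, NPV,
prevalence and balanced accuracy (exactly the mean of sensitivity and
specificity); overall accuracy; Cohen's κ from the marginals.  Ratios with
zero denominators are reported missing (NaN), never as 0.

**Repeated CV.** 10 repetitions of stratified 10-fold cross-validation
(stratified so the rare sitting class reaches every fold); the repetition
error is the mean fold misclassification rate; the summary is the
five-number summary plus mean over repetitions.  Folds whose training set
lacks a class are flagged and scored on predictable items.

## Synthetic generator (`synth`)

The generator emulates the *statistical signatures* the pipeline exploits,
not aerodynamics:

| behavior | signal model | defaults |
|---|---|---|
| sitting | static gravity (0, 0, 1 g) + white noise | SD 0.015 g |
| soaring | AR(1) drift on all axes around the (rolled) gravity vector | marginal SD 0.05 g, φ = 0.95 |
| flapping | sinusoid on heave + 0.3× in-phase sway component | 3.5 Hz, 0.6 g amplitude |
| banking | gravity rolled about the surge axis | roll ≥ 20° |

plus white sensor noise (SD 0.01 g) everywhere.  A roll of θ about the
surge axis maps gravity to (−sin θ, 0, cos θ)·g, so banking shows in the
sway mean — the separability channel for straight-vs-banking.  Roll is a
continuous per-bout quantity: straight flight draws N(0, 8°) truncated
inside the banking cutoff (a flying bird is never perfectly level), banking
draws ±(20° + Exp(10°)) capped at 55°; sitting is exactly level; setting
the spreads to zero recovers deterministic postures.  The wingbeat must lie
below Nyquist.

Benchmark schedules draw behaviors i.i.d. from the complex-ethogram class
mix observed in trained-eagle segment counts (soaring most common;
adjacent same-label bouts merge into longer stretches), with log-normal
bout durations (σ_log = 0.5, floor 0.15 s): mean 0.6 s for flapping (so a
bout holds at least two wingbeats) and 0.35 s otherwise, i.e. an overall
mean bout of ~0.4 s matching the short variable-length segments that
change-point segmentation of 140 Hz eagle data produces.  Everything is
reproducible from a single seed via spawned child seeds.

**What passing tests do and do not show.**  The generator's classes are
separable by design (distinct postures, amplitudes and spectra), bout
postures are constant, and annotations are exact.  Real recordings add
posture drift within behaviors, observer error around the 20° judgment,
sensor calibration drift and rate jitter — so synthetic accuracies
validate the *pipeline machinery* (segmentation, features, protocols,
metrics), not expected field performance.  Two published findings do not
reproduce under these idealizations, deliberately: (1) the dramatic
collapse of the random forest on the 5-class task (observed 61.6% on real
data) — with constant per-bout roll, segment means estimate posture so well
that RF complex accuracy stays ≈ 0.9 and the per-sample KNN's advantage on
the complex task is a statistical tie rather than a 30-point gap (the
acceptance check of that ordering can therefore fail by ~0.01 at a given
seed); (2) per-sample KNN accuracy is limited by genuine class structure
rather than inflated by extreme imbalance (the original per-sample soaring
prevalence was 0.97, with κ ≈ 0.33 despite 92% accuracy).

## Studies (`studies`)

**Subsampling** is grid-nearest decimation with no anti-alias filter (each
target-grid instant keeps the nearest original sample, each sample used at
most once); aliasing of the wingbeat above Nyquist at 5 Hz is accepted as
faithful to plain decimation.  The construction is idempotent, and
140→20 Hz reduces to exact 7-fold decimation.

**Frequency study.**  The full pipeline re-runs per rate with the burn-in
rescaled to ~1 s of samples.  The inflection is the lowest rate whose
accuracy is within ε = 0.01 of the best across rates.  Two desk-scale
safeguards keep per-rate accuracies comparable: the segment (RF) route is
flagged infeasible below 150 kept segments or 10 per class — at 5 Hz with
~0.4 s bouts, decimation merges the stream into a handful of degenerate
mega-segments whose "accuracy" is a different task — and the KNN training
set is capped at 12,000 samples at every rate so per-sample accuracy
responds to the sampling rate rather than to the shrinking sample count
(at full scale, hundreds of thousands of samples, this confound vanishes).
The study benchmark is 8 traces × 120 s so low-rate cells retain enough
segments.

**Budgets.**  Unannotated streams are classified (RF per segment, KNN per
sample), and classified time is aggregated per behavior (fractions summing
to 1) and optionally per clock hour.

## Problem sizes and reproducibility

Default study sizes — benchmark 6 traces × 60 s (≈ 50,000 samples, ≈ 600
segments) for end-to-end evaluation, 8 × 120 s for the frequency study,
ARL₀ scaled to 500 with 1000 calibration streams for monitor validation,
and KNN cross-validation on ≤ 30,000 samples — are the package's chosen
desk-scale study conditions.  Every stochastic step (generation,
calibration, splits, folds, permutation importance) is seeded; re-running
with the same seed is bit-identical.

## Known limitations

* Only the x-axis is monitored by default (configurable); no multivariate
  or retrospective (globally optimal) segmentation.
* Threshold calibration assumes a Gaussian null; heavy-tailed sensor noise
  would shift the realized ARL₀.
* The generator does not model wing tucks, thermalling trajectories, GPS,
  altitude, rate jitter, or within-bout posture drift (see above for the
  consequences).
* Behavior budgets inherit whatever bias the trained classifier has; the
  two model routes can disagree substantially on ambiguous streams, and
  both are reported side by side rather than reconciled.
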