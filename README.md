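# soarclass

Supervised classification of soaring-bird flight behavior from tri-axial
accelerometry.

Large soaring raptors such as golden eagles (*Aquila chrysaetos*) switch
between energetically cheap soaring/gliding and costly flapping flight, and
the time budget across these modes shapes their energetics and movement
ecology.  Body-mounted accelerometers sampling the sway (x), surge (y) and
heave (z) axes at ~140 Hz record both the static (gravity/posture) and
dynamic (movement) components of acceleration, from which behavior can be
classified — provided the continuous stream is segmented, summarized and
matched to ground-truthed behavior.  `soarclass` implements that full
supervised pipeline for movement ecologists:

1. **Segmentation** — a sequential change-point monitor on the sway channel
   using a generalized likelihood ratio (GLR) statistic for joint
   mean-and-variance changes.  With in-control average run length ARL₀ (the
   expected samples to a false alarm; default 50,000) and a one-second
   burn-in per run, a detection at run length *t* occurs when
   `D_t = max_k [ t·log σ̂² − k·log σ̂²_left(k) − (t−k)·log σ̂²_right(k) ] > h_t`,
   the boundary is placed at the maximizing split `k̂`, and monitoring
   restarts there.  The thresholds `h_t` are Monte-Carlo calibrated so the
   per-observation false-alarm hazard is ≈ 1/ARL₀.
2. **Features** — 28 per-segment statistics: mean, min, max, SD, skewness,
   kurtosis, trend (g/s) and dominant spectral frequency per axis, three
   inter-axis Pearson correlations, and overall dynamic body acceleration
   ODBA = mean(|dyn_x| + |dyn_y| + |dyn_z|), with the static component
   estimated by a centered 1 s running mean per axis.
3. **Labeling** — each segment takes the video-annotated behavior occupying
   the majority of its duration, under a simple 3-class ethogram (flapping,
   soaring, sitting) or a complex 5-class one splitting straight vs banking
   (body roll ≳ 20°) flight.
4. **Classification** — a random forest over segment features with
   (ntree, mtry) selected by out-of-bag error over a grid (500–4000 × 1–28),
   and a K-nearest-neighbor classifier over individual min-max-normalized
   samples with K chosen on a 5–50 coarse grid plus unit refinement;
   both evaluated by stratified 70/30 splits, one-vs-rest confusion
   metrics, Cohen's κ, and repeated 10×10-fold cross-validation.
5. **Studies** — sampling-frequency analysis (decimation to 5/10/20/40 Hz
   with per-rate re-training and an accuracy inflection point) and behavior
   time budgets for unannotated streams.

Because the original eagle recordings are not publicly deposited, the
package ships a first-class synthetic generator (`soarclass.synth`) that
emulates 140 Hz eagle accelerometry — static gravity plus noise for
sitting, autoregressive attitude drift for soaring, wingbeat-frequency
oscillation for flapping, and per-bout continuous roll with a 20° banking
cutoff — with exact behavior boundaries for end-to-end validation.

## Worked example

```python
import numpy as np
from soarclass import labeling, segmentation, studies, synth

# one minute of synthetic eagle accelerometry with known behaviors
bench = studies.default_benchmark(n_traces=4, seed=11, trace_duration_s=60.0)
trace, annotations = bench[0]

segs = segmentation.segment_stream(trace, segmentation.CPMParams())
lab = labeling.assign_labels(segs, trace, annotations,
                             labeling.SIMPLE_ETHOGRAM)
print(labeling.class_counts(lab).to_dict())

res = studies.run_pipeline(bench, labeling.SIMPLE_ETHOGRAM,
                           studies.PipelineConfig(seed=11))
print(f"RF  accuracy {res.rf_accuracy:.3f}  kappa {res.rf_report.kappa:.3f}")
print(f"KNN accuracy {res.knn_accuracy:.3f}  kappa {res.knn_report.kappa:.3f}"
      f"  (K = {res.knn_result.selected_k})")
print(res.rf_report.per_class_frame().round(3))
```

Output:

```
{'flapping': 43, 'soaring': 48, 'sitting': 11}
RF  accuracy 0.976  kappa 0.957
KNN accuracy 0.924  kappa 0.875  (K = 15)
          sensitivity  specificity    ppv    npv  prevalence  balanced_accuracy
flapping        1.000        0.987  0.979  1.000       0.379              0.994
soaring         0.985        0.966  0.970  0.983       0.524              0.975
sitting         0.833        1.000  1.000  0.982       0.097              0.917
```

The first trace's 8,400 samples split into 102 variable-length segments
(mean 82 samples); after majority labeling, the held-out random forest
classifies the 3-class ethogram at 97.6% and the per-sample KNN at 92.4%.
Per-class rows read as one-vs-rest: e.g. flapping segments are recovered
with sensitivity 1.00 at specificity 0.99, and balanced accuracy is exactly
their mean.

A command-line interface mirrors the library
(`soarclass simulate|segment|featurize|label|subsample|evaluate|study-frequency|budget`):

```bash
soarclass simulate --n-traces 3 --duration 60 --seed 0 --out-dir data/
soarclass segment data/trace_0.csv segments.csv --arl0 50000
soarclass featurize data/trace_0.csv segments.csv features.csv
soarclass label data/trace_0.csv segments.csv data/annotations_0.csv labeled.csv
soarclass evaluate data/ reports/ --ethogram simple
```

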