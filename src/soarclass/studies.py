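"""End-to-end pipeline orchestration and design studies.

Ties the modules together: segment each trace with the change-point monitor,
extract the 28 per-segment statistics, assign majority-duration behavior
labels, then train and evaluate the random-forest (per-segment) and KNN
(per-sample) classifiers.  On top of that pipeline sit two studies:

* the **sampling-frequency study** — decimate traces to 5/10/20/40 Hz,
  re-run the full pipeline per rate and per model, and locate the inflection
  rate above which accuracy no longer improves;
* **behavior budgets** — classify an unannotated stream and report the
  fraction of time spent in each behavior, optionally by hour of day.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import classify, features, labeling, segmentation, synth
from .io_formats import AccelTrace, AnnotationTrack

logger = logging.getLogger(__name__)

STANDARD_RATES = (5.0, 10.0, 20.0, 40.0)

#: accuracy tolerance used to call the inflection rate
INFLECTION_EPS = 0.01


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

def subsample_trace(trace: AccelTrace, target_hz: float) -> AccelTrace:
    """Decimate a trace onto a coarser time grid (no anti-alias filter).

    For each instant of the uniform target grid the nearest original sample
    is kept, each original sample at most once; the resulting nominal rate is
    within ~2% of the target.  A target at or above the native rate returns
    the trace unchanged with a warning.  The construction is idempotent:
    re-subsampling at the same rate keeps the same samples.
    """
    if not target_hz > 0:
        raise ValueError("target_hz must be positive")
    if target_hz >= trace.nominal_rate_hz:
        logger.warning("target %.3g Hz >= native %.3g Hz; returning trace "
                       "unchanged", target_hz, trace.nominal_rate_hz)
        return trace
    t0 = trace.time[0]
    n_target = int(np.floor((trace.time[-1] - t0) * target_hz)) + 1
    grid = t0 + np.arange(n_target) / target_hz
    pos = np.searchsorted(trace.time, grid)
    pos = np.clip(pos, 1, trace.n - 1)
    left, right = trace.time[pos - 1], trace.time[pos]
    idx = np.where(grid - left <= right - grid, pos - 1, pos)
    idx = np.unique(idx)
    t = trace.time[idx]
    rate = (t.size - 1) / (t[-1] - t[0]) if t.size > 1 else target_hz
    return AccelTrace(t, trace.x[idx], trace.y[idx], trace.z[idx], rate)


# ---------------------------------------------------------------------------
# dataset preparation and model evaluation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to run benchmark traces through both classifiers."""

    cpm: segmentation.CPMParams = dataclasses.field(
        default_factory=segmentation.CPMParams)
    odba: features.OdbaParams = dataclasses.field(
        default_factory=features.OdbaParams)
    rf: classify.RFConfig = dataclasses.field(
        default_factory=lambda: classify.RFConfig(
            ntree_grid=(500,), mtry_grid=(5,)))
    knn: classify.KNNConfig = dataclasses.field(
        default_factory=classify.KNNConfig)
    optimize_rf_grid: bool = False
    #: cap on KNN training samples (seeded subsample); None = use all.
    #: The frequency study sets this so per-sample accuracy compares rates
    #: at equal training-set size instead of confounding rate with n.
    knn_max_train: int | None = None
    seed: int = 0


@dataclasses.dataclass(eq=False)
class SegmentDataset:
    """Pooled per-segment features/labels and per-sample measurements."""

    X_seg: np.ndarray
    y_seg: np.ndarray
    X_sample: np.ndarray
    y_sample: np.ndarray
    n_segments_total: int
    n_segments_kept: int


def annotation_sample_labels(trace: AccelTrace, annot: AnnotationTrack,
                             ethogram: labeling.Ethogram) -> np.ndarray:
    """Per-sample behavior labels straight from the annotation timeline.

    Samples inside excluded intervals, or outside every interval, get ``""``.
    This is the per-measurement ground truth the KNN route trains on — the
    measurement unit is the individual sample, not the segment.
    """
    out = np.full(trace.n, "", dtype=object)
    j = np.searchsorted(annot.start_s, trace.time, side="right") - 1
    valid = (j >= 0)
    jj = np.clip(j, 0, max(annot.n - 1, 0))
    inside = valid & (trace.time < annot.end_s[jj]) & ~annot.excluded[jj]
    labels = annot.label[jj[inside]]
    if ethogram.name == "simple":
        labels = np.array([labeling.map_to_simple(str(l)) for l in labels],
                          dtype=object)
    out[np.flatnonzero(inside)] = labels
    return out


def prepare_dataset(benchmark: list[tuple[AccelTrace, AnnotationTrack]],
                    ethogram: labeling.Ethogram,
                    config: PipelineConfig) -> SegmentDataset:
    """Segment, featurize and label every trace; pool across traces.

    Segment rows (the RF route) carry the 28 statistics and the
    majority-duration label of their kept segment; feature rows with
    non-finite entries (degenerate tiny segments) are excluded.  Per-sample
    rows (the KNN route) carry the raw x/y/z measurement labeled directly
    from the annotation timeline, independent of the segmentation.
    """
    Xs, ys, Xm, ym = [], [], [], []
    total = kept = 0
    for trace, annot in benchmark:
        segs = segmentation.segment_stream(trace, config.cpm)
        lab = labeling.assign_labels(segs, trace, annot, ethogram)
        feats = features.featurize(trace, segs, config.odba)
        merged = lab.kept.merge(feats, on=["segment_id", "n_samples"])
        total += len(lab.table)
        fmat = merged[list(features.FEATURE_NAMES)].to_numpy(float)
        ok = np.isfinite(fmat).all(axis=1)
        merged = merged.loc[ok]
        kept += len(merged)
        Xs.append(merged[list(features.FEATURE_NAMES)].to_numpy(float))
        ys.append(merged["label"].to_numpy(object))
        slab = annotation_sample_labels(trace, annot, ethogram)
        keep = slab != ""
        Xm.append(trace.xyz()[keep])
        ym.append(slab[keep])
    return SegmentDataset(np.vstack(Xs), np.concatenate(ys),
                          np.vstack(Xm), np.concatenate(ym),
                          total, kept)


@dataclasses.dataclass(eq=False)
class EvaluationResult:
    """Held-out evaluation of both classifiers on one dataset."""

    rf_report: classify.ConfusionReport | None
    knn_report: classify.ConfusionReport | None
    rf_config: classify.RFConfig
    knn_result: classify.KNNResult | None
    rf_model: object
    dataset: SegmentDataset

    @property
    def rf_accuracy(self) -> float:
        """Overall RF accuracy; NaN if the segment route was infeasible."""
        return (np.nan if self.rf_report is None
                else self.rf_report.overall_accuracy)

    @property
    def knn_accuracy(self) -> float:
        return (np.nan if self.knn_report is None
                else self.knn_report.overall_accuracy)


def evaluate_models(dataset: SegmentDataset, ethogram: labeling.Ethogram,
                    config: PipelineConfig,
                    allow_partial: bool = False) -> EvaluationResult:
    """70/30 train/test both classifiers and report confusion metrics.

    With ``allow_partial`` a route that cannot run (e.g. too few segments of
    some class after heavy decimation) is flagged and reported as missing
    instead of raising.
    """
    seed = config.seed
    try:
        return _evaluate_rf_and_knn(dataset, ethogram, config, seed)
    except ValueError:
        if not allow_partial:
            raise
    # RF route infeasible; still evaluate the per-sample KNN route
    knn_res, knn_report = _evaluate_knn(dataset, ethogram, config, seed)
    logger.warning("segment route infeasible for this dataset; RF flagged")
    return EvaluationResult(None, knn_report, config.rf, knn_res, None,
                            dataset)


def _evaluate_knn(dataset: SegmentDataset, ethogram: labeling.Ethogram,
                  config: PipelineConfig, seed: int):
    str_, ste = classify.split_70_30(dataset.y_sample, seed=seed)
    if config.knn_max_train is not None:
        rng = np.random.default_rng(seed + 77)
        if str_.size > config.knn_max_train:
            str_ = np.sort(rng.choice(str_, config.knn_max_train,
                                      replace=False))
        max_test = int(config.knn_max_train * 3 / 7)
        if ste.size > max_test:
            ste = np.sort(rng.choice(ste, max_test, replace=False))
    knn_res = classify.knn_optimize_and_classify(
        dataset.X_sample[str_], dataset.y_sample[str_],
        dataset.X_sample[ste], dataset.y_sample[ste],
        dataclasses.replace(config.knn, seed=seed))
    knn_report = classify.confusion_metrics(dataset.y_sample[ste],
                                            knn_res.predictions,
                                            labels=ethogram.labels)
    return knn_res, knn_report


def _evaluate_rf_and_knn(dataset: SegmentDataset,
                         ethogram: labeling.Ethogram,
                         config: PipelineConfig, seed: int) -> EvaluationResult:
    tr, te = classify.split_70_30(dataset.y_seg, seed=seed)
    rf_cfg = config.rf
    if config.optimize_rf_grid:
        rf_cfg = classify.optimize_rf(dataset.X_seg[tr], dataset.y_seg[tr],
                                      dataclasses.replace(rf_cfg, seed=seed))
        ntree, mtry = rf_cfg.selected_ntree, rf_cfg.selected_mtry
    else:
        ntree = rf_cfg.selected_ntree or max(rf_cfg.ntree_grid)
        mtry = rf_cfg.selected_mtry or min(
            max(rf_cfg.mtry_grid), max(1, int(np.sqrt(dataset.X_seg.shape[1]))))
    rf = classify.fit_rf(dataset.X_seg[tr], dataset.y_seg[tr], ntree, mtry,
                         seed=seed, oob=False)
    rf_pred = rf.predict(dataset.X_seg[te])
    rf_report = classify.confusion_metrics(dataset.y_seg[te], rf_pred,
                                           labels=ethogram.labels)
    knn_res, knn_report = _evaluate_knn(dataset, ethogram, config, seed)
    return EvaluationResult(rf_report, knn_report,
                            dataclasses.replace(rf_cfg, selected_ntree=ntree,
                                                selected_mtry=mtry),
                            knn_res, rf, dataset)


def run_pipeline(benchmark: list[tuple[AccelTrace, AnnotationTrack]],
                 ethogram: labeling.Ethogram,
                 config: PipelineConfig | None = None,
                 allow_partial: bool = False) -> EvaluationResult:
    """Full segment -> featurize -> label -> train -> evaluate run."""
    config = config or PipelineConfig()
    dataset = prepare_dataset(benchmark, ethogram, config)
    return evaluate_models(dataset, ethogram, config, allow_partial)


# ---------------------------------------------------------------------------
# sampling-frequency study
# ---------------------------------------------------------------------------

@dataclasses.dataclass(eq=False)
class FrequencyStudyResult:
    """Accuracy per target rate per model, and per-model inflection rates.

    The inflection is the lowest rate whose accuracy comes within
    ``INFLECTION_EPS`` of the best accuracy across rates.
    """

    table: pd.DataFrame  # columns: rate_hz, rf_accuracy, knn_accuracy
    inflection_hz: dict[str, float]

    def accuracy(self, model: str, rate_hz: float) -> float:
        row = self.table.loc[np.isclose(self.table["rate_hz"], rate_hz)]
        return float(row[f"{model}_accuracy"].iloc[0])


def find_inflection(rates: np.ndarray, accuracies: np.ndarray,
                    eps: float = INFLECTION_EPS) -> float:
    """Lowest rate whose accuracy is within ``eps`` of the maximum.

    Rates whose accuracy is missing (flagged infeasible) are ignored.
    """
    rates = np.asarray(rates, dtype=float)
    accuracies = np.asarray(accuracies, dtype=float)
    ok = np.isfinite(accuracies)
    rates, accuracies = rates[ok], accuracies[ok]
    if rates.size == 0:
        return np.nan
    order = np.argsort(rates)
    rates, accuracies = rates[order], accuracies[order]
    best = accuracies.max()
    for r, a in zip(rates, accuracies):
        if a >= best - eps:
            return float(r)
    return float(rates[-1])


def frequency_study(benchmark: list[tuple[AccelTrace, AnnotationTrack]],
                    ethogram: labeling.Ethogram,
                    config: PipelineConfig | None = None,
                    rates: tuple[float, ...] = STANDARD_RATES,
                    include_native: bool = True) -> FrequencyStudyResult:
    """Re-run the full pipeline at each decimated rate and locate inflections.

    The burn-in of the change-point monitor is rescaled to ~1 s of samples at
    each rate (clamped to the monitor's minimum), matching the native-rate
    convention of one second of startup data.

    Two scale safeguards keep accuracies comparable across rates: the RF
    (segment) route is flagged as infeasible at a rate when decimation
    leaves fewer than ``min_rf_segments`` kept segments (or fewer than 10 of
    some class) — with short behavior bouts, heavy decimation merges the
    stream into a handful of degenerate mega-segments whose accuracy is not
    the same task; and the KNN training set is capped at a fixed size
    (``knn_max_train``, seeded subsample) so per-sample accuracy responds to
    the sampling rate rather than to the shrinking number of samples.
    """
    config = config or PipelineConfig()
    if config.knn_max_train is None:
        config = dataclasses.replace(config, knn_max_train=12_000)
    min_rf_segments = 150
    native = float(np.median([tr.nominal_rate_hz for tr, _ in benchmark]))
    all_rates = sorted(set(float(r) for r in rates)
                       | ({round(native, 3)} if include_native else set()))
    rows = []
    for rate in all_rates:
        if rate >= native:
            bench_r = benchmark
        else:
            bench_r = [(subsample_trace(tr, rate), an)
                       for tr, an in benchmark]
        cpm_r = dataclasses.replace(
            config.cpm,
            startup=max(int(round(rate)), 2 * config.cpm.min_side))
        cfg_r = dataclasses.replace(config, cpm=cpm_r)
        dataset = prepare_dataset(bench_r, ethogram, cfg_r)
        class_counts = np.unique(dataset.y_seg, return_counts=True)[1]
        rf_feasible = (len(dataset.y_seg) >= min_rf_segments
                       and class_counts.min() >= 10
                       and class_counts.size == len(ethogram.labels))
        if rf_feasible:
            res = evaluate_models(dataset, ethogram, cfg_r,
                                  allow_partial=True)
        else:
            logger.warning("RF route flagged at %g Hz: %d segments too few",
                           rate, len(dataset.y_seg))
            knn_res, knn_report = _evaluate_knn(dataset, ethogram, cfg_r,
                                                cfg_r.seed)
            res = EvaluationResult(None, knn_report, cfg_r.rf, knn_res,
                                   None, dataset)
        rows.append({"rate_hz": rate, "rf_accuracy": res.rf_accuracy,
                     "knn_accuracy": res.knn_accuracy})
        logger.info("frequency study @%g Hz: RF %.4f, KNN %.4f", rate,
                    res.rf_accuracy, res.knn_accuracy)
    table = pd.DataFrame(rows)
    infl = {m: find_inflection(table["rate_hz"].to_numpy(),
                               table[f"{m}_accuracy"].to_numpy())
            for m in ("rf", "knn")}
    return FrequencyStudyResult(table, infl)


# ---------------------------------------------------------------------------
# behavior budgets
# ---------------------------------------------------------------------------

@dataclasses.dataclass(eq=False)
class BehaviorBudget:
    """Fraction of classified time per behavior, optionally by hour of day."""

    fractions: pd.Series
    by_hour: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        total = float(self.fractions.sum())
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("budget fractions must sum to 1")


def behavior_budget_rf(trace: AccelTrace, rf_model, ethogram,
                       config: PipelineConfig | None = None,
                       start_hour: float | None = None) -> BehaviorBudget:
    """Classify an unannotated trace segment-wise and aggregate time."""
    config = config or PipelineConfig()
    segs = segmentation.segment_stream(trace, config.cpm)
    feats = features.featurize(trace, segs, config.odba)
    fmat = feats[list(features.FEATURE_NAMES)].to_numpy(float)
    ok = np.isfinite(fmat).all(axis=1)
    if not ok.any():
        raise ValueError("no classifiable segments")
    pred = rf_model.predict(fmat[ok])
    dur = feats.loc[ok, "n_samples"].to_numpy(float) / trace.nominal_rate_hz
    starts = np.array([a for a, _ in segs.segments])
    mid_idx = starts[ok.nonzero()[0]] + feats.loc[ok, "n_samples"].to_numpy(int) // 2
    times = trace.time[np.clip(mid_idx, 0, trace.n - 1)]
    return _aggregate_budget(pred, dur, times, ethogram, start_hour)


def behavior_budget_knn(trace: AccelTrace, knn_result: classify.KNNResult,
                        train_X: np.ndarray, train_y: np.ndarray, ethogram,
                        start_hour: float | None = None) -> BehaviorBudget:
    """Classify an unannotated trace sample-wise and aggregate time."""
    Z = knn_result.normalizer.transform(trace.xyz())
    Ztr = knn_result.normalizer.transform(train_X)
    pred = classify.knn_predict(Ztr, train_y, Z, knn_result.selected_k)
    dur = np.full(trace.n, 1.0 / trace.nominal_rate_hz)
    return _aggregate_budget(pred, dur, trace.time, ethogram, start_hour)


def _aggregate_budget(pred, dur, times, ethogram, start_hour) -> BehaviorBudget:
    labels = list(ethogram.labels)
    df = pd.DataFrame({"label": pred, "duration_s": dur})
    total = df["duration_s"].sum()
    if total <= 0:
        raise ValueError("empty classification")
    frac = (df.groupby("label")["duration_s"].sum()
            .reindex(labels, fill_value=0.0) / total)
    by_hour = None
    if start_hour is not None:
        hours = np.floor((start_hour + np.asarray(times) / 3600.0) % 24).astype(int)
        df["hour"] = hours
        tab = df.pivot_table(index="hour", columns="label",
                             values="duration_s", aggfunc="sum",
                             fill_value=0.0)
        by_hour = tab.div(tab.sum(axis=1), axis=0).reindex(
            columns=labels, fill_value=0.0)
    return BehaviorBudget(frac, by_hour)


# ---------------------------------------------------------------------------
# benchmark convenience
# ---------------------------------------------------------------------------

def default_benchmark(n_traces: int = 6, ethogram=None, seed: int = 0,
                      trace_duration_s: float = 60.0):
    """A seeded complex-ethogram benchmark with the generator defaults."""
    ethogram = ethogram or labeling.COMPLEX_ETHOGRAM
    return synth.generate_benchmark(n_traces, ethogram, seed=seed,
                                    trace_duration_s=trace_duration_s)
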