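"""Supervised classifiers over segments (random forest) and samples (KNN).

The random-forest route classifies change-point segments from their 28
summary statistics; its hyperparameters (number of trees ``ntree`` and
variables per split ``mtry``) are selected by grid search on the out-of-bag
(OOB) error.  The K-nearest-neighbor route classifies individual tri-axial
measurements after per-feature min-max normalization; K is selected on a
coarse grid (5..50 by 5) followed by unit refinement between the two best
coarse values.

Both routes share 70/30 stratified splits, one-vs-rest confusion-matrix
metrics (sensitivity, specificity, PPV, NPV, prevalence, balanced accuracy),
overall accuracy, Cohen's kappa, and repeated stratified k-fold
cross-validation summaries.  The ensemble/neighbor learners themselves are
scikit-learn's; this module owns the optimization protocol and metrics.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_70_30(labels: Sequence, seed: int = 0,
                train_fraction: float = 0.7) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 70/30 split; returns (train_idx, test_idx) index arrays.

    The split is disjoint and exhaustive, stratified by class, and
    reproducible by seed.  Classes with fewer than 2 items are rejected.
    """
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 items to split")
    idx = np.arange(y.size)
    train, test = train_test_split(idx, train_size=train_fraction,
                                   stratify=y, random_state=seed,
                                   shuffle=True)
    return np.sort(train), np.sort(test)


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RFConfig:
    """Random-forest hyperparameter grid and selection state.

    The default grid scans ntree 500..4000 by 500 and mtry 1..28 (an mtry of
    0 is meaningless for split sampling, so the grid starts at 1).
    """

    ntree_grid: tuple[int, ...] = tuple(range(500, 4001, 500))
    mtry_grid: tuple[int, ...] = tuple(range(1, 29))
    selected_ntree: int | None = None
    selected_mtry: int | None = None
    oob_error_surface: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t < 1 for t in self.ntree_grid):
            raise ValueError("ntree values must be >= 1")
        if any(m < 1 for m in self.mtry_grid):
            raise ValueError("mtry values must be >= 1")


def fit_rf(X: np.ndarray, y: np.ndarray, ntree: int, mtry: int,
           seed: int = 0, oob: bool = True) -> RandomForestClassifier:
    """Fit a random forest with the given tree count and variables per split."""
    clf = RandomForestClassifier(n_estimators=int(ntree),
                                 max_features=int(mtry),
                                 oob_score=oob, bootstrap=True,
                                 random_state=seed, n_jobs=1)
    clf.fit(np.asarray(X, dtype=float), np.asarray(y))
    return clf


def optimize_rf(X: np.ndarray, y: np.ndarray,
                config: RFConfig | None = None) -> RFConfig:
    """Select (ntree, mtry) minimizing the out-of-bag error over the grid.

    Ties break toward the smaller ntree, then the smaller mtry.  The scanned
    OOB error surface is kept on the returned config.
    """
    config = config or RFConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training segments")
    if np.unique(y).size < 2:
        raise ValueError("training labels are a single class")
    n_feat = X.shape[1]
    rows = []
    best = (np.inf, None, None)
    for ntree in sorted(config.ntree_grid):
        for mtry in sorted(config.mtry_grid):
            if mtry > n_feat:
                continue
            clf = fit_rf(X, y, ntree, mtry, seed=config.seed)
            err = 1.0 - float(clf.oob_score_)
            rows.append({"ntree": ntree, "mtry": mtry, "oob_error": err})
            if err < best[0]:
                best = (err, ntree, mtry)
    if best[1] is None:
        raise ValueError("empty hyperparameter grid")
    return dataclasses.replace(
        config, selected_ntree=best[1], selected_mtry=best[2],
        oob_error_surface=pd.DataFrame(rows))


def rf_variable_importance(model: RandomForestClassifier, X: np.ndarray,
                           y: np.ndarray,
                           feature_names: Sequence[str] | None = None,
                           seed: int = 0, n_repeats: int = 5) -> pd.DataFrame:
    """Permutation importance (mean decrease in accuracy), sorted descending.

    Each feature is permuted in turn on held-out data and the drop in
    accuracy recorded; deterministic under ``seed``.
    """
    X = np.asarray(X, dtype=float)
    res = permutation_importance(model, X, np.asarray(y),
                                 n_repeats=n_repeats, random_state=seed,
                                 scoring="accuracy")
    names = (list(feature_names) if feature_names is not None
             else [f"f{i}" for i in range(X.shape[1])])
    df = pd.DataFrame({"feature": names,
                       "mean_decrease_accuracy": res.importances_mean,
                       "sd": res.importances_std})
    return df.sort_values("mean_decrease_accuracy", ascending=False,
                          kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# K-nearest neighbors
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MinMaxNormalizer:
    """Per-feature min-max scaling fitted on training data only.

    Transformed test values are clipped to [-0.5, 1.5] so extreme
    out-of-range measurements cannot dominate distances.
    """

    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None
    clip: tuple[float, float] = (-0.5, 1.5)

    def fit(self, X: np.ndarray) -> "MinMaxNormalizer":
        X = np.asarray(X, dtype=float)
        self.mins = X.min(axis=0)
        self.maxs = X.max(axis=0)
        if np.any(~np.isfinite(self.mins)) or np.any(self.maxs <= self.mins):
            raise ValueError("normalization needs finite bounds with min < max")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mins is None:
            raise ValueError("normalizer not fitted")
        Z = (np.asarray(X, dtype=float) - self.mins) / (self.maxs - self.mins)
        return np.clip(Z, *self.clip)


@dataclasses.dataclass
class KNNConfig:
    """K-selection protocol state: coarse grid then unit refinement."""

    k_coarse: tuple[int, ...] = tuple(range(5, 51, 5))
    selected_k: int | None = None
    accuracy_by_k: dict[int, float] = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.k_coarse):
            raise ValueError("K values must be >= 1")


def knn_predict(X_train: np.ndarray, y_train: np.ndarray,
                X_query: np.ndarray, k: int) -> np.ndarray:
    """Majority vote of the K nearest training points (Euclidean distance).

    Vote ties resolve to the smallest class index (lexicographically first
    label), matching an exhaustive brute-force vote.
    """
    if k > len(X_train):
        raise ValueError("K exceeds the training-set size")
    clf = KNeighborsClassifier(n_neighbors=int(k), algorithm="auto")
    clf.fit(np.asarray(X_train, dtype=float), np.asarray(y_train))
    return clf.predict(np.asarray(X_query, dtype=float))


def refinement_range(k_a: int, k_b: int) -> range:
    """Unit-step K values bracketed by the two best coarse K (inclusive)."""
    lo, hi = min(k_a, k_b), max(k_a, k_b)
    return range(lo, hi + 1)


@dataclasses.dataclass
class KNNResult:
    selected_k: int
    predictions: np.ndarray
    config: KNNConfig
    normalizer: MinMaxNormalizer


def knn_optimize_and_classify(X_train: np.ndarray, y_train: np.ndarray,
                              X_test: np.ndarray, y_test: np.ndarray,
                              config: KNNConfig | None = None) -> KNNResult:
    """Select K and classify the test set.

    Min-max normalization is fitted on the training features and applied to
    both sets.  Test-set accuracy is computed for every coarse K; the two
    best coarse values bracket a unit-step refinement; the final K is the
    accuracy argmax over everything evaluated (ties to the smaller K).
    """
    config = config or KNNConfig()
    norm = MinMaxNormalizer().fit(X_train)
    Ztr, Zte = norm.transform(X_train), norm.transform(X_test)
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    acc: dict[int, float] = {}

    def eval_k(k: int) -> None:
        if k not in acc and k <= len(Ztr):
            acc[k] = float((knn_predict(Ztr, y_train, Zte, k) == y_test).mean())

    for k in config.k_coarse:
        eval_k(k)
    if not acc:
        raise ValueError("no feasible K in the coarse grid")
    coarse_sorted = sorted(acc.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(coarse_sorted) >= 2:
        for k in refinement_range(coarse_sorted[0][0], coarse_sorted[1][0]):
            eval_k(k)
    best_k = min(acc, key=lambda k: (-acc[k], k))
    preds = knn_predict(Ztr, y_train, Zte, best_k)
    out_cfg = dataclasses.replace(config, selected_k=best_k,
                                  accuracy_by_k=dict(sorted(acc.items())))
    return KNNResult(best_k, preds, out_cfg, norm)


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

def balanced_accuracy_from_rates(sensitivity: float,
                                 specificity: float) -> float:
    """Balanced accuracy is exactly the mean of sensitivity and specificity."""
    return 0.5 * (sensitivity + specificity)


def npv_from_rates(sensitivity: float, specificity: float,
                   prevalence: float) -> float:
    """Negative predicted value from class rates via the Bayes identity.

    ``npv = spec (1 - prev) / ((1 - sens) prev + spec (1 - prev))``.
    """
    num = specificity * (1.0 - prevalence)
    den = (1.0 - sensitivity) * prevalence + num
    return num / den


@dataclasses.dataclass(eq=False)
class ConfusionReport:
    """Confusion matrix with per-class one-vs-rest statistics.

    Per class: sensitivity TP/(TP+FN), specificity TN/(TN+FP), ppv
    TP/(TP+FP), npv TN/(TN+FN), prevalence (TP+FN)/N and balanced accuracy
    (sens+spec)/2; plus overall accuracy (trace/N) and Cohen's kappa.
    Ratios with a zero denominator are reported as NaN (missing), not 0.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray  # true x predicted counts
    per_class: dict[str, dict[str, float]]
    overall_accuracy: float
    kappa: float

    def per_class_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_class).T.loc[list(self.labels)]

    def matrix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels),
                            columns=list(self.labels))

    def to_dict(self) -> dict:
        return {"labels": list(self.labels),
                "matrix": self.matrix.tolist(),
                "per_class": {l: {k: (None if not np.isfinite(v) else v)
                                  for k, v in d.items()}
                              for l, d in self.per_class.items()},
                "overall_accuracy": self.overall_accuracy,
                "kappa": self.kappa}

    @classmethod
    def from_dict(cls, d: dict) -> "ConfusionReport":
        per_class = {l: {k: (np.nan if v is None else float(v))
                         for k, v in stats.items()}
                     for l, stats in d["per_class"].items()}
        return cls(tuple(d["labels"]), np.asarray(d["matrix"], dtype=np.int64),
                   per_class, float(d["overall_accuracy"]), float(d["kappa"]))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def confusion_metrics(y_true: Sequence, y_pred: Sequence,
                      labels: Sequence[str] | None = None) -> ConfusionReport:
    """Build a :class:`ConfusionReport` from true and predicted labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size or y_true.size == 0:
        raise ValueError("label sequences must be equal-length and non-empty")
    if labels is None:
        labels = sorted(set(map(str, y_true)) | set(map(str, y_pred)))
    labels = tuple(str(l) for l in labels)
    index = {l: i for i, l in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        m[index[str(t)], index[str(p)]] += 1
    n = int(m.sum())
    per_class: dict[str, dict[str, float]] = {}
    for i, lab in enumerate(labels):
        tp = float(m[i, i])
        fn = float(m[i].sum() - tp)
        fp = float(m[:, i].sum() - tp)
        tn = float(n - tp - fn - fp)
        sens = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        per_class[lab] = {
            "sensitivity": sens,
            "specificity": spec,
            "ppv": _safe_div(tp, tp + fp),
            "npv": _safe_div(tn, tn + fn),
            "prevalence": _safe_div(tp + fn, n),
            "balanced_accuracy": (balanced_accuracy_from_rates(sens, spec)
                                  if np.isfinite(sens) and np.isfinite(spec)
                                  else np.nan),
        }
    po = float(np.trace(m)) / n
    pe = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / (n * n)
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else np.nan
    return ConfusionReport(labels, m, per_class, po, kappa)


# ---------------------------------------------------------------------------
# repeated k-fold cross-validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CVSummary:
    """Five-number summary plus mean of repetition-level error rates."""

    rep_errors: np.ndarray
    flagged_folds: int = 0

    def __post_init__(self) -> None:
        self.rep_errors = np.asarray(self.rep_errors, dtype=float)

    @property
    def min(self) -> float:
        return float(self.rep_errors.min())

    @property
    def q1(self) -> float:
        return float(np.percentile(self.rep_errors, 25))

    @property
    def median(self) -> float:
        return float(np.median(self.rep_errors))

    @property
    def mean(self) -> float:
        return float(self.rep_errors.mean())

    @property
    def q3(self) -> float:
        return float(np.percentile(self.rep_errors, 75))

    @property
    def max(self) -> float:
        return float(self.rep_errors.max())

    def to_dict(self) -> dict:
        return {"min": self.min, "q1": self.q1, "median": self.median,
                "mean": self.mean, "q3": self.q3, "max": self.max,
                "rep_errors": self.rep_errors.tolist(),
                "flagged_folds": self.flagged_folds}


def repeated_kfold(X: np.ndarray, y: np.ndarray,
                   estimator_factory: Callable[[int], object],
                   k: int = 10, reps: int = 10, seed: int = 0) -> CVSummary:
    """Repeated stratified k-fold cross-validation error summary.

    Each repetition uses a fresh seeded stratified fold assignment; the
    repetition error is the mean fold misclassification rate.  If a class is
    absent from some training fold, that fold is flagged and its error is
    computed over items whose class the model could predict.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) < k:
        raise ValueError("need at least k items")
    rep_errors = []
    flagged = 0
    for r in range(reps):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=seed + 1000 * r)
        fold_errors = []
        for tr, te in skf.split(X, y):
            model = estimator_factory(seed + r)
            model.fit(X[tr], y[tr])
            known = np.isin(y[te], np.unique(y[tr]))
            if not known.all():
                flagged += 1
            pred = model.predict(X[te][known])
            fold_errors.append(float((pred != y[te][known]).mean()))
        rep_errors.append(float(np.mean(fold_errors)))
    return CVSummary(np.array(rep_errors), flagged)
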