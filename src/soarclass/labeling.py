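"""Ethograms and majority-duration labeling of change-point segments.

Two behavior catalogues are supported: a *simple* 3-class ethogram
(flapping, soaring, sitting) and a *complex* 5-class one that splits the two
flight behaviors into straight vs banking variants (body rolled by roughly
20 degrees or more).  Each detected segment receives the annotated behavior
that occupies the majority of its duration; segments touching an excluded
annotation (bird on the glove / out of frame) are dropped from training.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_formats import AccelTrace, AnnotationTrack
from .segmentation import SegmentSet

SIMPLE_LABELS = ("flapping", "soaring", "sitting")
COMPLEX_LABELS = ("flapping_straight", "flapping_banking",
                  "soaring_straight", "soaring_banking", "sitting")

_TO_SIMPLE = {
    "flapping_straight": "flapping",
    "flapping_banking": "flapping",
    "soaring_straight": "soaring",
    "soaring_banking": "soaring",
    "sitting": "sitting",
}


@dataclasses.dataclass(frozen=True)
class Ethogram:
    """A named, ordered behavior catalogue with a projection to simple labels."""

    name: str
    labels: tuple[str, ...]
    to_simple: dict[str, str]

    def __contains__(self, label: str) -> bool:
        return label in self.labels


SIMPLE_ETHOGRAM = Ethogram("simple", SIMPLE_LABELS,
                           {l: l for l in SIMPLE_LABELS})
COMPLEX_ETHOGRAM = Ethogram("complex", COMPLEX_LABELS, dict(_TO_SIMPLE))

ETHOGRAMS = {"simple": SIMPLE_ETHOGRAM, "complex": COMPLEX_ETHOGRAM}


def map_to_simple(label: str) -> str:
    """Project a complex-ethogram label onto the 3-class simple ethogram.

    ``flapping_*`` collapse to ``flapping``, ``soaring_*`` to ``soaring``
    (gliding, thermal circling, wing tucks and single wing beats all share
    the low-cost soaring category); ``sitting`` is unchanged.  Simple labels
    pass through unchanged.
    """
    if label in SIMPLE_LABELS:
        return label
    try:
        return _TO_SIMPLE[label]
    except KeyError:
        raise KeyError(f"unknown behavior label {label!r}") from None


@dataclasses.dataclass(eq=False)
class LabeledSegmentSet:
    """Segments with assigned behavior, majority fraction and drop bookkeeping."""

    table: pd.DataFrame  # segment_id,start_idx,end_idx,n_samples,label,majority_fraction,tie,dropped,reason
    ethogram: Ethogram

    @property
    def kept(self) -> pd.DataFrame:
        return self.table.loc[~self.table["dropped"]]

    @property
    def dropped(self) -> pd.DataFrame:
        return self.table.loc[self.table["dropped"]]

    def __len__(self) -> int:
        return len(self.table)


def assign_labels(segments: SegmentSet, trace: AccelTrace,
                  annotations: AnnotationTrack,
                  ethogram: Ethogram = SIMPLE_ETHOGRAM) -> LabeledSegmentSet:
    """Assign each segment the behavior occupying the majority of its time.

    Overlaps are computed by half-open interval intersection between the
    segment's time span and every annotation interval.  Segments overlapping
    any excluded interval are dropped (``reason="excluded"``); segments with
    no annotation cover are dropped (``reason="unannotated"``).  A duration
    tie is broken toward the behavior whose contributing annotation starts
    earliest, and flagged.

    Annotation labels are projected through ``ethogram.to_simple`` when the
    simple ethogram is requested, so complex-annotated data can be labeled
    against either scheme.
    """
    n = trace.n
    # segment time spans (half-open); the final segment ends one sample period
    # past the last timestamp
    tgrid = np.append(trace.time, trace.end_time_s)
    rows = []
    for sid, (a, b) in enumerate(segments.segments):
        t0, t1 = tgrid[a], tgrid[b]
        ov_start = np.maximum(annotations.start_s, t0)
        ov_end = np.minimum(annotations.end_s, t1)
        ov = np.maximum(0.0, ov_end - ov_start)
        hit = ov > 0
        row = {"segment_id": sid, "start_idx": int(a), "end_idx": int(b),
               "n_samples": int(b - a), "label": "", "majority_fraction": np.nan,
               "tie": False, "dropped": False, "reason": ""}
        if np.any(hit & annotations.excluded):
            row.update(dropped=True, reason="excluded")
            rows.append(row)
            continue
        if not np.any(hit):
            row.update(dropped=True, reason="unannotated")
            rows.append(row)
            continue
        # aggregate overlap per (projected) label
        per_label: dict[str, float] = {}
        first_start: dict[str, float] = {}
        for s, o, lab in zip(annotations.start_s[hit], ov[hit],
                             annotations.label[hit]):
            lab = str(lab)
            if ethogram.name == "simple":
                lab = map_to_simple(lab)
            elif lab not in ethogram:
                raise KeyError(f"annotation label {lab!r} not in "
                               f"{ethogram.name} ethogram")
            per_label[lab] = per_label.get(lab, 0.0) + float(o)
            first_start.setdefault(lab, float(s))
        cover = sum(per_label.values())
        best = max(per_label.values())
        winners = [l for l, v in per_label.items() if v >= best - 1e-12]
        tie = len(winners) > 1
        if tie:  # earlier-starting behavior wins, deterministically
            winners.sort(key=lambda l: (first_start[l], l))
        row.update(label=winners[0], majority_fraction=best / cover, tie=tie)
        rows.append(row)
    table = pd.DataFrame(rows)
    return LabeledSegmentSet(table, ethogram)


def class_counts(labeled: LabeledSegmentSet) -> pd.Series:
    """Count kept segments per behavior, indexed in ethogram label order."""
    kept = labeled.kept
    counts = kept["label"].value_counts()
    return counts.reindex(list(labeled.ethogram.labels), fill_value=0).astype(int)


def sample_labels(labeled: LabeledSegmentSet, n_samples: int) -> np.ndarray:
    """Expand segment labels to per-sample labels; dropped segments get ``""``.

    This is the per-measurement view used by the KNN classifier, which
    operates on individual samples of the segmented-and-annotated stream.
    """
    out = np.full(n_samples, "", dtype=object)
    for _, r in labeled.kept.iterrows():
        out[r["start_idx"]:r["end_idx"]] = r["label"]
    return out
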