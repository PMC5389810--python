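"""Delimited-text interchange for accelerometry pipelines.

All formats are plain CSV (comma separated, ``.`` decimal, UTF-8, mandatory
header row) so that traces, annotation tracks, segment tables, feature
matrices and metric reports survive a write/read round trip losslessly.

Conventions
-----------
* Time intervals are half-open ``[start, end)`` in seconds; sample ``i``
  belongs to the interval containing ``time[i]``.
* Sample indices are 0-based; segment index ranges are half-open.
* The default sample schema is ``time_s,x_g,y_g,z_g`` (remappable); the
  annotation schema is ``start_s,end_s,label,excluded``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default mapping from logical channel to CSV column name
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "time": "time_s", "x": "x_g", "y": "y_g", "z": "z_g"}

ANNOTATION_COLUMNS = ("start_s", "end_s", "label", "excluded")

AXES = ("x", "y", "z")


@dataclasses.dataclass(eq=False)
class AccelTrace:
    """Tri-axial acceleration samples in g on a strictly increasing time base.

    Axes follow the bird-frame convention: ``x`` sway (lateral), ``y`` surge
    (anterior-posterior), ``z`` heave (dorso-ventral); gravity lies along +z
    when the body is level.

    Parameters
    ----------
    time : array of seconds, strictly increasing
    x, y, z : acceleration channels in g, same length as ``time``
    nominal_rate_hz : mean observed sampling rate, ``(n - 1) / span``
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    nominal_rate_hz: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.time.size
        if not (self.x.size == self.y.size == self.z.size == n):
            raise ValueError("trace channels must have equal length")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("trace time must be strictly increasing")
        if not self.nominal_rate_hz > 0:
            raise ValueError("nominal_rate_hz must be positive")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def duration_s(self) -> float:
        """Half-open duration: span plus one nominal sample period."""
        return float(self.time[-1] - self.time[0] + 1.0 / self.nominal_rate_hz)

    @property
    def end_time_s(self) -> float:
        """Exclusive end of the trace's half-open time support."""
        return float(self.time[-1] + 1.0 / self.nominal_rate_hz)

    def channel(self, axis: str) -> np.ndarray:
        if axis not in AXES:
            raise KeyError(f"unknown axis {axis!r}; expected one of {AXES}")
        return getattr(self, axis)

    def xyz(self) -> np.ndarray:
        """Samples as an (n, 3) array in x, y, z order."""
        return np.column_stack([self.x, self.y, self.z])

    def to_frame(self, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
        cm = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
        return pd.DataFrame({cm["time"]: self.time, cm["x"]: self.x,
                             cm["y"]: self.y, cm["z"]: self.z})


@dataclasses.dataclass(eq=False)
class AnnotationTrack:
    """Labeled, possibly excluded, half-open behavior intervals in seconds.

    Intervals are sorted by start on construction; overlapping intervals are
    rejected (abutting ones are fine).  ``excluded`` marks spans that must not
    feed the classifiers (e.g. bird on the trainer's glove, out of frame).
    """

    start_s: np.ndarray
    end_s: np.ndarray
    label: np.ndarray
    excluded: np.ndarray

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.end_s = np.asarray(self.end_s, dtype=float)
        self.label = np.asarray(self.label, dtype=object)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        n = self.start_s.size
        if not (self.end_s.size == self.label.size == self.excluded.size == n):
            raise ValueError("annotation fields must have equal length")
        if np.any(self.end_s <= self.start_s):
            raise ValueError("annotation intervals need end > start")
        if any(not str(l) for l in self.label):
            raise ValueError("annotation labels must be non-empty")
        order = np.argsort(self.start_s, kind="stable")
        self.start_s = self.start_s[order]
        self.end_s = self.end_s[order]
        self.label = self.label[order]
        self.excluded = self.excluded[order]
        if n > 1 and np.any(self.start_s[1:] < self.end_s[:-1] - 1e-12):
            raise ValueError("annotation intervals overlap")

    @classmethod
    def from_intervals(
        cls, intervals: Sequence[tuple[float, float, str, bool]]
    ) -> "AnnotationTrack":
        """Build from ``(start_s, end_s, label, excluded)`` tuples."""
        if len(intervals) == 0:
            return cls(np.empty(0), np.empty(0), np.empty(0, dtype=object),
                       np.empty(0, dtype=bool))
        s, e, lab, ex = zip(*intervals)
        return cls(np.array(s), np.array(e),
                   np.array(lab, dtype=object), np.array(ex, dtype=bool))

    @property
    def n(self) -> int:
        return self.start_s.size

    def intervals(self) -> list[tuple[float, float, str, bool]]:
        return [(float(s), float(e), str(l), bool(x)) for s, e, l, x in
                zip(self.start_s, self.end_s, self.label, self.excluded)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"start_s": self.start_s, "end_s": self.end_s,
                             "label": self.label.astype(str),
                             "excluded": self.excluded.astype(int)})


# ---------------------------------------------------------------------------
# sample streams
# ---------------------------------------------------------------------------

def read_accel_csv(path, column_map: Mapping[str, str] | None = None) -> AccelTrace:
    """Read a delimited sample stream into an :class:`AccelTrace`.

    Rows whose mapped columns fail numeric parsing are dropped with a logged
    count.  The nominal rate is ``(n - 1) / (t_last - t_first)``.
    """
    cm = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in cm.values() if c not in df.columns]
    if missing:
        raise KeyError(f"missing columns in {path}: {missing}")
    vals = df[[cm["time"], cm["x"], cm["y"], cm["z"]]].apply(
        pd.to_numeric, errors="coerce")
    bad = vals.isna().any(axis=1)
    if int(bad.sum()):
        logger.warning("read_accel_csv: dropped %d unparseable row(s) from %s",
                       int(bad.sum()), path)
    vals = vals.loc[~bad]
    if len(vals) < 2:
        raise ValueError(f"{path}: fewer than 2 valid sample rows")
    vals = vals.sort_values(cm["time"], kind="stable")
    t = vals[cm["time"]].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time not strictly increasing after sort")
    rate = (t.size - 1) / (t[-1] - t[0])
    return AccelTrace(t, vals[cm["x"]].to_numpy(float),
                      vals[cm["y"]].to_numpy(float),
                      vals[cm["z"]].to_numpy(float), rate)


def write_accel_csv(trace: AccelTrace, path,
                    column_map: Mapping[str, str] | None = None) -> None:
    trace.to_frame(column_map).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# annotation interval tracks
# ---------------------------------------------------------------------------

def read_annotations(path) -> AnnotationTrack:
    """Read ``start_s,end_s,label,excluded`` intervals; overlaps are an error."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"missing columns in {path}: {missing}")
    return AnnotationTrack(df["start_s"].to_numpy(float),
                           df["end_s"].to_numpy(float),
                           df["label"].astype(str).to_numpy(object),
                           df["excluded"].astype(int).to_numpy() != 0)


def write_annotations(track: AnnotationTrack, path) -> None:
    track.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# segment tables and feature matrices
# ---------------------------------------------------------------------------

_SEGMENT_INT_COLS = ("segment_id", "start_idx", "end_idx", "n_samples")


def write_segments(segments: pd.DataFrame, path) -> None:
    """Write a segment table (plain or labeled) as CSV."""
    segments.to_csv(path, index=False)


def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for c in _SEGMENT_INT_COLS:
        if c in df.columns:
            df[c] = df[c].astype(int)
    if "dropped" in df.columns:
        df["dropped"] = df["dropped"].astype(bool)
    return df


def write_features(features: pd.DataFrame, path) -> None:
    """Write a per-segment feature matrix; header order is preserved."""
    features.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("segment_id", "n_samples"):
        if c in df.columns:
            df[c] = df[c].astype(int)
    return df


# ---------------------------------------------------------------------------
# metric reports
# ---------------------------------------------------------------------------

def write_report(report, json_path, table_path=None) -> None:
    """Serialize a confusion report as structured JSON plus a CSV table.

    ``report`` is any object exposing ``to_dict()`` and ``per_class_frame()``
    (see :class:`soarclass.classify.ConfusionReport`).  When ``table_path`` is
    omitted the table lands next to the JSON with a ``.csv`` suffix.
    """
    json_path = Path(json_path)
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")
    if table_path is None:
        table_path = json_path.with_suffix(".csv")
    report.per_class_frame().to_csv(table_path, index=True)


def read_report(json_path) -> dict:
    with open(json_path, encoding="utf-8") as fh:
        return json.load(fh)
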