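"""Per-segment summary statistics used as classifier inputs.

For each behavioral segment, 28 statistics are computed: per axis (sway x,
surge y, heave z) the mean, minimum, maximum, standard deviation, skewness,
kurtosis, trend and dominant spectral frequency (8 x 3 = 24); the three
pairwise Pearson correlations between axes; and the overall dynamic body
acceleration (ODBA).

ODBA separates gravity from movement with a centered 1 s running mean per
axis (the static component); the dynamic residual's absolute values are
summed over the three axes and averaged over the segment.  Because typical
change-point segments (~0.35 s) are shorter than the 1 s smoothing window,
the static component is estimated from the full trace and sliced per
segment.

Conventions: standard deviation uses the n-1 denominator; skewness and
kurtosis are population moment ratios (kurtosis non-excess, 3 for a normal
limit); the trend is the ordinary-least-squares slope in g per second; the
dominant frequency is the maximum-ordinate frequency of a linearly detrended
periodogram, zero frequency excluded.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import signal, stats

from .io_formats import AXES, AccelTrace
from .segmentation import SegmentSet

_PER_AXIS = ("mean", "min", "max", "sd", "skew", "kurt", "trend", "domfreq")

#: the 28 feature names, in canonical column order
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{ax}" for ax in AXES for stat in _PER_AXIS
) + ("corr_xy", "corr_xz", "corr_yz", "odba")

assert len(FEATURE_NAMES) == 28


@dataclasses.dataclass
class OdbaParams:
    """Running-mean window for the static/dynamic split (seconds)."""

    window_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.window_s > 0:
            raise ValueError("window_s must be positive")


def static_acceleration(channel: np.ndarray, rate_hz: float,
                        params: OdbaParams | None = None) -> np.ndarray:
    """Centered running mean estimating the static (gravity) component.

    The window spans ``round(window_s * rate_hz)`` samples and shrinks
    symmetrically at the edges (the output stays centered, so a constant
    input is reproduced exactly and no phase shift is introduced).  Output
    length equals input length.
    """
    params = params or OdbaParams()
    v = np.asarray(channel, dtype=float)
    n = v.size
    if n == 0:
        return v.copy()
    w = max(int(round(params.window_s * rate_hz)), 1)
    half = (w - 1) // 2
    if half == 0:
        return v.copy()
    c = np.concatenate(([0.0], np.cumsum(v)))
    i = np.arange(n)
    he = np.minimum(half, np.minimum(i, n - 1 - i))
    lo = i - he
    hi = i + he + 1
    return (c[hi] - c[lo]) / (hi - lo)


def dynamic_acceleration(trace: AccelTrace,
                         params: OdbaParams | None = None) -> np.ndarray:
    """(n, 3) dynamic components: raw minus per-axis static running mean."""
    params = params or OdbaParams()
    return np.column_stack([
        trace.channel(ax) - static_acceleration(trace.channel(ax),
                                                trace.nominal_rate_hz, params)
        for ax in AXES])


def odba(window_xyz: np.ndarray, rate_hz: float,
         params: OdbaParams | None = None,
         dynamic: np.ndarray | None = None) -> float:
    """Mean per-sample ODBA of a tri-axial window.

    Per sample, ODBA is ``|dyn_x| + |dyn_y| + |dyn_z|`` where the dynamic
    component is raw minus static (1 s running mean per axis); the returned
    value is the mean over the window.  Pass ``dynamic`` to reuse components
    already computed from a full trace.
    """
    if dynamic is None:
        w = np.asarray(window_xyz, dtype=float)
        if w.ndim != 2 or w.shape[1] != 3:
            raise ValueError("window must be (n, 3)")
        params = params or OdbaParams()
        dynamic = w - np.column_stack([
            static_acceleration(w[:, j], rate_hz, params) for j in range(3)])
    return float(np.abs(dynamic).sum(axis=1).mean())


def _dominant_frequency(v: np.ndarray, rate_hz: float) -> float:
    """Peak frequency (Hz) of the linearly detrended periodogram, DC excluded."""
    if v.size < 2:
        return np.nan
    freqs, pxx = signal.periodogram(v, fs=rate_hz, detrend="linear")
    if freqs.size < 2:
        return np.nan
    return float(freqs[1:][np.argmax(pxx[1:])])


def segment_features(trace: AccelTrace, segment: tuple[int, int],
                     params: OdbaParams | None = None,
                     dynamic: np.ndarray | None = None) -> dict[str, float]:
    """Compute the 28 statistics for one half-open index segment.

    ``dynamic`` is the full-trace (n, 3) dynamic component; when omitted it
    is computed on the fly (prefer :func:`featurize` for many segments).
    Segments must hold at least 2 samples; skewness and kurtosis require 3
    and are NaN below that.
    """
    a, b = int(segment[0]), int(segment[1])
    if not (0 <= a < b <= trace.n):
        raise IndexError(f"segment ({a}, {b}) outside trace of {trace.n}")
    if b - a < 2:
        raise ValueError("segments need at least 2 samples")
    params = params or OdbaParams()
    if dynamic is None:
        dynamic = dynamic_acceleration(trace, params)
    t = trace.time[a:b]
    out: dict[str, float] = {}
    chans = {ax: trace.channel(ax)[a:b] for ax in AXES}
    for ax, v in chans.items():
        out[f"mean_{ax}"] = float(v.mean())
        out[f"min_{ax}"] = float(v.min())
        out[f"max_{ax}"] = float(v.max())
        out[f"sd_{ax}"] = float(v.std(ddof=1))
        if v.size >= 3 and v.std() > 0:
            out[f"skew_{ax}"] = float(stats.skew(v, bias=True))
            out[f"kurt_{ax}"] = float(stats.kurtosis(v, fisher=False,
                                                     bias=True))
        else:
            out[f"skew_{ax}"] = np.nan
            out[f"kurt_{ax}"] = np.nan
        out[f"trend_{ax}"] = float(np.polyfit(t - t[0], v, 1)[0])
        out[f"domfreq_{ax}"] = _dominant_frequency(v, trace.nominal_rate_hz)
    for pair in ("xy", "xz", "yz"):
        u, v = chans[pair[0]], chans[pair[1]]
        if u.std() > 0 and v.std() > 0:
            out[f"corr_{pair}"] = float(np.corrcoef(u, v)[0, 1])
        else:
            out[f"corr_{pair}"] = np.nan
    out["odba"] = odba(None, trace.nominal_rate_hz, params,
                       dynamic=dynamic[a:b])
    return out


def featurize(trace: AccelTrace, segments: SegmentSet | list[tuple[int, int]],
              params: OdbaParams | None = None) -> pd.DataFrame:
    """Feature matrix for all segments of a trace.

    Returns one row per segment with columns ``segment_id``, ``n_samples``
    and the 28 features in :data:`FEATURE_NAMES` order.  The static
    component is estimated once from the full trace.
    """
    params = params or OdbaParams()
    seg_list = segments.segments if isinstance(segments, SegmentSet) else list(segments)
    dynamic = dynamic_acceleration(trace, params)
    rows = []
    for sid, (a, b) in enumerate(seg_list):
        row = {"segment_id": sid, "n_samples": int(b - a)}
        row.update(segment_features(trace, (a, b), params, dynamic))
        rows.append(row)
    return pd.DataFrame(rows, columns=["segment_id", "n_samples",
                                       *FEATURE_NAMES])
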