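"""Sequential change-point segmentation of acceleration streams.

A continuous stream (by default the sway ``x`` channel, the axis most
responsive to flight-behavior changes) is monitored sequentially with a
generalized likelihood ratio (GLR) statistic sensitive to changes in both
mean and variance.  When the maximized statistic for the current run exceeds
a run-length-dependent threshold, the change point is estimated as the argmax
split, a segment boundary is recorded there, and monitoring restarts from the
observation after the estimated change with a fresh burn-in.

Thresholds are calibrated by Monte Carlo so that the false-alarm hazard per
observation under an i.i.d. Gaussian null is approximately ``1/ARL0``, where
ARL0 is the expected run length to a false alarm (default 50,000
observations).  Two calibration routes are used:

* **conditional-hazard calibration** (small ARL0, used in scaled studies):
  thresholds are the conditional quantiles of the GLR maximum among streams
  that have survived monitoring so far, with survivor resampling to keep the
  pool size constant;
* **tail-extrapolated calibration** (large ARL0): the unconditional
  ``1 - 1/ARL0`` quantile of the GLR maximum, estimated by fitting an
  exponential upper tail to simulated null statistics.  At large ARL0 the
  survival conditioning is negligible, and the default (ARL0 = 50,000,
  ``min_side`` = 5) curve ships with the package as a precomputed cache.

The GLR split scan evaluates at most ``k_cap`` candidate splits per window
(evenly thinned; exact for windows up to ``k_cap + 2 * min_side`` samples,
which covers typical behavior segments), and every detection is followed by a
full-resolution local refinement of the split around the coarse argmax.
Calibration and monitoring share the identical capped statistic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from importlib import resources
from pathlib import Path

import numba
import numpy as np

from .io_formats import AccelTrace

logger = logging.getLogger(__name__)

#: ARL0 above which calibration switches to the tail-extrapolation route
_CONDITIONAL_ARL0_MAX = 2000.0

_DEFAULT_CACHE_NAME = "cpm_thresholds_arl50000.json"

# in-process calibration cache
_MEMO: dict[tuple, "ThresholdCurve"] = {}


@dataclasses.dataclass
class CPMParams:
    """Configuration of the sequential change-point monitor.

    Parameters
    ----------
    arl0 : expected run length to a false alarm, in observations (>= 100)
    startup : burn-in observation count per run before detections are
        allowed; ``None`` means "one second of data", i.e. the trace's
        rounded nominal rate, clamped to at least ``2 * min_side``
    statistic : test statistic identifier (only the joint mean+variance
        GLR, ``"glr_meanvar"``, is implemented)
    min_side : minimum observations on each side of a candidate split
    calibration_reps : Monte-Carlo streams used for threshold calibration
    seed : seed for calibration randomness
    k_cap : maximum candidate splits evaluated per window
    var_floor : variance floor guarding degenerate (constant) windows
    """

    arl0: float = 50_000.0
    startup: int | None = None
    statistic: str = "glr_meanvar"
    min_side: int = 5
    calibration_reps: int = 1000
    seed: int = 0
    k_cap: int = 256
    var_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.arl0 < 100:
            raise ValueError("arl0 must be >= 100")
        if self.min_side < 2:
            raise ValueError("min_side must be >= 2")
        if self.startup is not None and self.startup < 2 * self.min_side:
            raise ValueError("startup must be >= 2 * min_side")
        if self.statistic != "glr_meanvar":
            raise ValueError(f"unknown statistic {self.statistic!r}")

    def effective_startup(self, nominal_rate_hz: float | None = None) -> int:
        """Resolve the burn-in count, defaulting to ~1 s of observations."""
        if self.startup is not None:
            return int(self.startup)
        if nominal_rate_hz is None:
            raise ValueError("startup unset and no nominal rate given")
        return max(int(round(nominal_rate_hz)), 2 * self.min_side)


@dataclasses.dataclass(eq=False)
class SegmentSet:
    """Half-open sample-index segments produced by the monitor.

    ``boundaries`` is strictly increasing and includes 0 and ``n_samples``;
    ``detection_delays[i]`` is the number of samples between interior boundary
    ``i`` (the estimated change point) and the observation at which it was
    detected.
    """

    boundaries: np.ndarray
    detection_delays: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=np.int64)
        self.detection_delays = np.asarray(self.detection_delays, dtype=np.int64)
        b = self.boundaries
        if b.size < 2 or b[0] != 0 or b[-1] != self.n_samples:
            raise ValueError("boundaries must run from 0 to n_samples")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.detection_delays.size != b.size - 2:
            raise ValueError("one detection delay per interior boundary")
        if np.any(self.detection_delays < 0):
            raise ValueError("detection delays must be >= 0")

    @property
    def segments(self) -> list[tuple[int, int]]:
        b = self.boundaries
        return [(int(b[i]), int(b[i + 1])) for i in range(b.size - 1)]

    @property
    def n_segments(self) -> int:
        return self.boundaries.size - 1

    def to_frame(self):
        import pandas as pd

        segs = self.segments
        return pd.DataFrame({
            "segment_id": np.arange(len(segs)),
            "start_idx": [a for a, _ in segs],
            "end_idx": [b for _, b in segs],
            "n_samples": [b - a for a, b in segs],
        })

    @classmethod
    def from_frame(cls, df) -> "SegmentSet":
        start = df["start_idx"].to_numpy(np.int64)
        end = df["end_idx"].to_numpy(np.int64)
        bounds = np.append(start, end[-1])
        return cls(bounds, np.zeros(max(bounds.size - 2, 0), dtype=np.int64),
                   int(end[-1]))


@dataclasses.dataclass(eq=False)
class ThresholdCurve:
    """Run-length-dependent detection thresholds ``h_t``.

    ``t`` is a strictly increasing grid of run lengths and ``h`` the
    threshold at each grid point; between grid points thresholds are linearly
    interpolated, beyond the last point the curve is flat, and below
    ``t[0]`` detection is disabled (infinite threshold).
    """

    t: np.ndarray
    h: np.ndarray
    arl0: float
    min_side: int
    k_cap: int
    method: str
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.h = np.asarray(self.h, dtype=float)
        if self.t.size != self.h.size or self.t.size == 0:
            raise ValueError("threshold grid and values must match")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("threshold grid must be strictly increasing")

    def dense(self, max_t: int) -> np.ndarray:
        """Thresholds indexed by run length ``0..max_t`` (inf below grid)."""
        tt = np.arange(max_t + 1)
        out = np.interp(tt, self.t, self.h)
        out[tt < self.t[0]] = np.inf
        return out

    def at(self, t: int) -> float:
        if t < self.t[0]:
            return np.inf
        return float(np.interp(t, self.t, self.h))

    def to_dict(self) -> dict:
        return {"arl0": self.arl0, "min_side": self.min_side,
                "k_cap": self.k_cap, "method": self.method,
                "t": self.t.tolist(),
                "h": [round(float(v), 4) for v in self.h],
                "meta": self.meta}

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdCurve":
        return cls(np.array(d["t"]), np.array(d["h"]), float(d["arl0"]),
                   int(d["min_side"]), int(d["k_cap"]), str(d["method"]),
                   dict(d.get("meta", {})))


# ---------------------------------------------------------------------------
# GLR statistic
# ---------------------------------------------------------------------------

def glr_statistic(window: np.ndarray, k: int, min_side: int = 2,
                  var_floor: float = 1e-12) -> float:
    """Joint mean+variance GLR statistic for a split of ``window`` at ``k``.

    Returns ``n log s2_full - k log s2_left - (n-k) log s2_right`` with
    maximum-likelihood (1/n) variance estimates; non-negative up to rounding.
    Zero-variance sides are floored at ``var_floor`` so degenerate (constant)
    inputs yield a statistic of 0 instead of an error.
    """
    w = np.asarray(window, dtype=float)
    n = w.size
    if not (min_side <= k <= n - min_side):
        raise ValueError(f"split {k} outside [{min_side}, {n - min_side}]")
    v_full = max(w.var(), var_floor)
    v_l = max(w[:k].var(), var_floor)
    v_r = max(w[k:].var(), var_floor)
    return float(n * np.log(v_full) - k * np.log(v_l) - (n - k) * np.log(v_r))


@numba.njit(cache=False)
def _glr_max(cs, cq, a, b, min_side, k_cap, var_floor):  # pragma: no cover
    """Max GLR over thinned candidate splits of window [a, b); returns (stat, k)."""
    n = b - a
    S = cs[b] - cs[a]
    Q = cq[b] - cq[a]
    v_full = Q / n - (S / n) ** 2
    if v_full < var_floor:
        v_full = var_floor
    base = n * np.log(v_full)
    n_cand = n - 2 * min_side + 1
    step = 1
    if n_cand > k_cap:
        step = (n_cand + k_cap - 1) // k_cap
    best = -1e300
    best_k = min_side
    k = min_side
    while k <= n - min_side:
        Sl = cs[a + k] - cs[a]
        Ql = cq[a + k] - cq[a]
        v_l = Ql / k - (Sl / k) ** 2
        v_r = (Q - Ql) / (n - k) - ((S - Sl) / (n - k)) ** 2
        if v_l < var_floor:
            v_l = var_floor
        if v_r < var_floor:
            v_r = var_floor
        stat = base - k * np.log(v_l) - (n - k) * np.log(v_r)
        if stat > best:
            best = stat
            best_k = k
        k += step
    return best, best_k, step


@numba.njit(cache=False)
def _glr_refine(cs, cq, a, b, k_lo, k_hi, var_floor):  # pragma: no cover
    """Full-resolution argmax split of window [a, b) within [k_lo, k_hi]."""
    n = b - a
    S = cs[b] - cs[a]
    Q = cq[b] - cq[a]
    v_full = Q / n - (S / n) ** 2
    if v_full < var_floor:
        v_full = var_floor
    base = n * np.log(v_full)
    best = -1e300
    best_k = k_lo
    for k in range(k_lo, k_hi + 1):
        Sl = cs[a + k] - cs[a]
        Ql = cq[a + k] - cq[a]
        v_l = Ql / k - (Sl / k) ** 2
        v_r = (Q - Ql) / (n - k) - ((S - Sl) / (n - k)) ** 2
        if v_l < var_floor:
            v_l = var_floor
        if v_r < var_floor:
            v_r = var_floor
        stat = base - k * np.log(v_l) - (n - k) * np.log(v_r)
        if stat > best:
            best = stat
            best_k = k
    return best, best_k


@numba.njit(cache=False)
def _monitor(x, h_dense, t_start, min_side, k_cap, var_floor):  # pragma: no cover
    """Sequential monitor; returns (boundaries, delays, counts)."""
    n = x.shape[0]
    cs = np.empty(n + 1)
    cq = np.empty(n + 1)
    cs[0] = 0.0
    cq[0] = 0.0
    for i in range(n):
        cs[i + 1] = cs[i] + x[i]
        cq[i + 1] = cq[i] + x[i] * x[i]
    max_h = h_dense.shape[0] - 1
    boundaries = np.empty(n + 2, dtype=np.int64)
    delays = np.empty(n + 1, dtype=np.int64)
    nb = 0
    run_start = 0
    i = 0
    while i < n:
        t = i + 1 - run_start
        if t >= t_start and t >= 2 * min_side:
            ti = t if t < max_h else max_h
            h = h_dense[ti]
            stat, k_hat, step = _glr_max(cs, cq, run_start, i + 1,
                                         min_side, k_cap, var_floor)
            if stat > h:
                if step > 1:
                    lo = k_hat - step
                    if lo < min_side:
                        lo = min_side
                    hi = k_hat + step
                    if hi > t - min_side:
                        hi = t - min_side
                    _, k_hat = _glr_refine(cs, cq, run_start, i + 1,
                                           lo, hi, var_floor)
                bound = run_start + k_hat
                boundaries[nb] = bound
                delays[nb] = (i + 1) - bound
                nb += 1
                run_start = bound
        i += 1
    return boundaries[:nb], delays[:nb]


@numba.njit(cache=False)
def _first_alarm(x, h_dense, t_start, min_side, k_cap, var_floor):  # pragma: no cover
    """Observation count at the first alarm of a fresh run, or -1."""
    n = x.shape[0]
    cs = np.empty(n + 1)
    cq = np.empty(n + 1)
    cs[0] = 0.0
    cq[0] = 0.0
    for i in range(n):
        cs[i + 1] = cs[i] + x[i]
        cq[i + 1] = cq[i] + x[i] * x[i]
    max_h = h_dense.shape[0] - 1
    for i in range(n):
        t = i + 1
        if t >= t_start and t >= 2 * min_side:
            ti = t if t < max_h else max_h
            stat, _, _ = _glr_max(cs, cq, 0, i + 1, min_side, k_cap, var_floor)
            if stat > h_dense[ti]:
                return t
    return -1


@numba.njit(cache=False)
def _calibrate_conditional(cs, cq, horizon, t_start, min_side, k_cap,
                           var_floor, arl0, donor_idx):  # pragma: no cover
    """Conditional-hazard thresholds with survivor resampling.

    At each run length ``t`` the statistic is evaluated for every stream in
    the pool and the threshold is the interpolated ``1 - 1/arl0`` quantile
    (so the per-observation false-alarm hazard targets ``1/arl0``); each
    stream exceeding it is replaced by the history of a surviving stream
    spliced onto the exceeder's own future innovations, keeping the pool
    size constant.
    """
    R = cs.shape[0]
    h_out = np.full(horizon + 1, np.inf)
    stats = np.empty(R)
    for t in range(t_start, horizon + 1):
        for r in range(R):
            s, _, _ = _glr_max(cs[r], cq[r], 0, t, min_side, k_cap, var_floor)
            stats[r] = s
        order = np.argsort(stats)
        pos = (1.0 - 1.0 / arl0) * (R - 1)
        i0 = int(np.floor(pos))
        frac = pos - i0
        lo = stats[order[i0]]
        hi = stats[order[i0 + 1]] if i0 + 1 < R else lo
        h = lo + frac * (hi - lo)
        h_out[t] = h
        if t == horizon:
            break
        # exceeders occupy the top of the sort order
        m = 0
        while m < R and stats[order[R - 1 - m]] > h:
            m += 1
        n_surv = R - m
        if n_surv <= 0:
            continue
        for j in range(m):
            dead = order[R - 1 - j]
            donor = order[(donor_idx[t] + j) % n_surv]
            # splice donor history onto the dead stream's future increments
            off_s = cs[donor, t] - cs[dead, t]
            off_q = cq[donor, t] - cq[dead, t]
            for u in range(t + 1):
                cs[dead, u] = cs[donor, u]
                cq[dead, u] = cq[donor, u]
            for u in range(t + 1, horizon + 1):
                cs[dead, u] += off_s
                cq[dead, u] += off_q
    return h_out


@numba.njit(cache=False)
def _null_stat_samples(cs, cq, t_grid, min_side, k_cap, var_floor):  # pragma: no cover
    """GLR max at each grid run length for each null stream: (R, grid) array."""
    R = cs.shape[0]
    G = t_grid.shape[0]
    out = np.empty((R, G))
    for r in range(R):
        for g in range(G):
            s, _, _ = _glr_max(cs[r], cq[r], 0, t_grid[g], min_side, k_cap,
                               var_floor)
            out[r, g] = s
    return out


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _prefix_sums(streams: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    R, H = streams.shape
    cs = np.zeros((R, H + 1))
    cq = np.zeros((R, H + 1))
    np.cumsum(streams, axis=1, out=cs[:, 1:])
    np.cumsum(streams ** 2, axis=1, out=cq[:, 1:])
    return cs, cq


def _smooth(h: np.ndarray, window: int = 51) -> np.ndarray:
    """Centered moving average with edge shrinkage, ignoring inf entries."""
    finite = np.isfinite(h)
    idx = np.flatnonzero(finite)
    if idx.size == 0:
        return h
    v = h[idx]
    half = window // 2
    c = np.cumsum(np.concatenate(([0.0], v)))
    out = v.copy()
    for i in range(v.size):
        lo = max(0, i - half)
        hi = min(v.size, i + half + 1)
        out[i] = (c[hi] - c[lo]) / (hi - lo)
    res = h.copy()
    res[idx] = out
    return res


def calibrate_thresholds(params: CPMParams, horizon: int,
                         startup: int | None = None,
                         use_cache: bool = True) -> ThresholdCurve:
    """Monte-Carlo calibrate run-length thresholds for the GLR monitor.

    The conditional false-alarm hazard per observation under an i.i.d.
    Gaussian null is targeted at ``1/arl0``.  For ``arl0`` <= 2000 the
    conditional-hazard route is used (``calibration_reps`` streams, survivor
    resampling); for larger ``arl0`` the tail-extrapolation route is used and
    a shipped cache is consulted first.  Results are memoized in-process,
    keyed by the calibration inputs, and reproducible by ``params.seed``.

    Parameters
    ----------
    horizon : largest run length calibrated explicitly; beyond it the
        threshold curve extends flat.
    startup : burn-in used during calibration (defaults to
        ``params.effective_startup()`` when set, else ``2 * min_side``).
    """
    if startup is None:
        startup = (params.startup if params.startup is not None
                   else 2 * params.min_side)
    t_start = max(int(startup), 2 * params.min_side)
    if horizon < t_start + 1:
        raise ValueError("horizon must exceed the burn-in")

    conditional = params.arl0 <= _CONDITIONAL_ARL0_MAX
    key = (params.arl0, params.statistic, params.min_side, params.k_cap,
           t_start if conditional else -1, horizon if conditional else -1,
           params.calibration_reps if conditional else -1, params.seed,
           conditional)
    if use_cache and key in _MEMO:
        return _MEMO[key]

    if not conditional:
        curve = _load_shipped_cache(params)
        if curve is None:
            curve = _calibrate_tail(params, max(horizon, 4000))
        _MEMO[key] = curve
        return curve

    if params.calibration_reps < 200:
        raise ValueError("calibration_reps must be >= 200")
    R = int(params.calibration_reps)
    rng = np.random.default_rng(params.seed)
    streams = rng.standard_normal((R, horizon))
    cs, cq = _prefix_sums(streams)
    donor_idx = rng.integers(0, R, size=horizon + 1)
    h = _calibrate_conditional(cs, cq, horizon, t_start,
                               params.min_side, params.k_cap,
                               params.var_floor, params.arl0, donor_idx)
    h = _smooth(h)
    t = np.arange(t_start, horizon + 1)
    curve = ThresholdCurve(t, h[t_start:], params.arl0, params.min_side,
                           params.k_cap, "conditional-hazard",
                           {"reps": R, "t_start": t_start,
                            "seed": params.seed})
    _MEMO[key] = curve
    return curve


def _tail_quantile(samples: np.ndarray, p_exceed: float,
                   tail_frac: float = 0.02) -> float:
    """Quantile with exceedance prob ``p_exceed`` via exponential tail fit."""
    u = np.quantile(samples, 1.0 - tail_frac)
    exc = samples[samples > u] - u
    if exc.size == 0 or p_exceed >= tail_frac:
        return float(np.quantile(samples, 1.0 - p_exceed))
    theta = float(exc.mean())
    return float(u + theta * np.log(tail_frac / p_exceed))


def _calibrate_tail(params: CPMParams, horizon: int,
                    reps: int = 6000) -> ThresholdCurve:
    """Unconditional tail-extrapolated thresholds for large ARL0."""
    t_lo = 2 * params.min_side
    dense = np.arange(t_lo, min(61, horizon + 1), 2)
    coarse = np.unique(np.round(np.geomspace(
        max(62, t_lo + 1), horizon, 48)).astype(np.int64))
    t_grid = np.unique(np.concatenate([dense, coarse]))
    rng = np.random.default_rng(params.seed)
    h = np.zeros(t_grid.size)
    n_batches = 3
    per = reps // n_batches
    samples = np.empty((per * n_batches, t_grid.size))
    for b in range(n_batches):
        streams = rng.standard_normal((per, horizon))
        cs, cq = _prefix_sums(streams)
        samples[b * per:(b + 1) * per] = _null_stat_samples(
            cs, cq, t_grid, params.min_side, params.k_cap, params.var_floor)
        del streams, cs, cq
    for g in range(t_grid.size):
        h[g] = _tail_quantile(samples[:, g], 1.0 / params.arl0)
    # light smoothing across the grid
    if h.size >= 5:
        sm = h.copy()
        for i in range(h.size):
            lo, hi = max(0, i - 2), min(h.size, i + 3)
            sm[i] = h[lo:hi].mean()
        h = sm
    return ThresholdCurve(t_grid, h, params.arl0, params.min_side,
                          params.k_cap, "tail-extrapolated",
                          {"reps": per * n_batches, "horizon": horizon,
                           "seed": params.seed})


def _load_shipped_cache(params: CPMParams) -> ThresholdCurve | None:
    try:
        ref = resources.files("soarclass") / "data" / _DEFAULT_CACHE_NAME
        with ref.open("r", encoding="utf-8") as fh:
            d = json.load(fh)
    except (FileNotFoundError, ModuleNotFoundError, OSError):
        return None
    if (float(d["arl0"]) == float(params.arl0)
            and int(d["min_side"]) == params.min_side
            and int(d["k_cap"]) == params.k_cap):
        return ThresholdCurve.from_dict(d)
    return None


def build_default_threshold_cache(path: str | Path | None = None,
                                  reps: int = 6000, horizon: int = 4000,
                                  seed: int = 20170412) -> Path:
    """Regenerate the shipped threshold cache for the default monitor.

    Uses the tail-extrapolation route at ARL0 = 50,000 with ``min_side`` = 5
    and the default split cap; writes JSON next to the package data.
    """
    params = CPMParams(arl0=50_000.0, min_side=5, seed=seed)
    curve = _calibrate_tail(params, horizon, reps=reps)
    if path is None:
        path = Path(__file__).parent / "data" / _DEFAULT_CACHE_NAME
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(curve.to_dict(), fh)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# monitoring
# ---------------------------------------------------------------------------

def segment_stream(trace: AccelTrace, params: CPMParams | None = None,
                   axis: str = "x",
                   thresholds: ThresholdCurve | None = None) -> SegmentSet:
    """Divide a trace into variable-length segments by sequential monitoring.

    Only the requested channel (default sway ``x``) is monitored.  No
    detection occurs before ``startup`` observations of the current run; on
    detection the boundary is recorded at the estimated change point (argmax
    split), monitoring restarts from the next observation, and the burn-in
    applies afresh to the new run (observations after the estimated change
    already in hand count toward it).  The final partial run is closed as the
    last segment.  Identical parameters and seed give bit-identical output.
    """
    params = params or CPMParams()
    x = trace.channel(axis)
    n = x.size
    startup = params.effective_startup(trace.nominal_rate_hz)
    if n <= startup:
        logger.warning("trace of %d samples not longer than startup %d; "
                       "returning a single segment", n, startup)
        return SegmentSet(np.array([0, n]), np.empty(0, dtype=np.int64), n)
    if thresholds is None:
        horizon = max(min(n, 4000), startup + 2)
        thresholds = calibrate_thresholds(params, horizon, startup=startup)
    h_dense = thresholds.dense(min(n, int(thresholds.t[-1])) + 1)
    bounds, delays = _monitor(np.ascontiguousarray(x, dtype=np.float64),
                              h_dense, startup, params.min_side,
                              params.k_cap, params.var_floor)
    all_bounds = np.concatenate(([0], bounds, [n]))
    return SegmentSet(all_bounds, delays, n)


def estimate_arl(params: CPMParams, thresholds: ThresholdCurve,
                 n_streams: int = 500, horizon: int | None = None,
                 startup: int | None = None,
                 seed: int | None = None) -> float:
    """Empirical mean run length to false alarm on fresh Gaussian null streams.

    Runs the monitor from a cold start on each stream and averages the first
    alarm time; streams with no alarm by ``horizon`` contribute ``horizon``
    (a slight downward bias, negligible for ``horizon >> arl0``).
    """
    if startup is None:
        startup = (params.startup if params.startup is not None
                   else 2 * params.min_side)
    if horizon is None:
        horizon = int(6 * params.arl0) + startup
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    h_dense = thresholds.dense(horizon + 1)
    total = 0.0
    for _ in range(n_streams):
        x = rng.standard_normal(horizon)
        t = _first_alarm(x, h_dense, startup, params.min_side, params.k_cap,
                         params.var_floor)
        total += horizon if t < 0 else t
    return total / n_streams
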