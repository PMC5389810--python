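"""GLR statistic against brute-force oracles; monitor behavior; calibration."""

import math

import numpy as np
import pytest

from soarclass import segmentation
from soarclass.io_formats import AccelTrace
from soarclass.segmentation import (CPMParams, SegmentSet, ThresholdCurve,
                                    calibrate_thresholds, glr_statistic,
                                    segment_stream)


def _glr_oracle(w, k):
    """Straight-from-formula GLR with MLE variances, no shared code."""
    w = list(map(float, w))
    n = len(w)

    def mle_var(v):
        m = sum(v) / len(v)
        return max(sum((x - m) ** 2 for x in v) / len(v), 1e-12)

    return (n * math.log(mle_var(w)) - k * math.log(mle_var(w[:k]))
            - (n - k) * math.log(mle_var(w[k:])))


class TestGlrStatistic:
    def test_matches_bruteforce_on_random_points(self, rng):
        w = rng.standard_normal(20)
        for k in range(2, 19):
            assert glr_statistic(w, k) == pytest.approx(_glr_oracle(w, k),
                                                        abs=1e-9)

    def test_true_split_is_argmax(self, rng):
        """Exhaustive scan: a hard level shift maximizes the GLR at its split."""
        w = np.concatenate([np.zeros(20), np.full(20, 5.0)])
        w += rng.normal(0.0, 1e-3, 40)
        stats = {k: glr_statistic(w, k) for k in range(2, 39)}
        assert max(stats, key=stats.get) == 20
        assert all(stats[20] > v for k, v in stats.items() if k != 20)

    def test_nonnegative_and_degenerate_guard(self, rng):
        w = rng.standard_normal(30)
        assert glr_statistic(w, 15) >= -1e-9
        # constant window: variance floor keeps the statistic at 0
        assert glr_statistic(np.ones(30), 15) == pytest.approx(0.0, abs=1e-6)

    def test_split_bounds_enforced(self, rng):
        w = rng.standard_normal(10)
        with pytest.raises(ValueError):
            glr_statistic(w, 1, min_side=2)

    def test_capped_scan_agrees_with_public_statistic(self, rng):
        """The monitor's thinned+refined scan finds the exhaustive argmax."""
        x = np.concatenate([rng.standard_normal(25),
                            rng.standard_normal(15) + 3.0])
        cs = np.concatenate(([0.0], np.cumsum(x)))
        cq = np.concatenate(([0.0], np.cumsum(x ** 2)))
        stat, k, step = segmentation._glr_max(cs, cq, 0, 40, 2, 256, 1e-12)
        assert step == 1
        expect = {k2: glr_statistic(x, k2) for k2 in range(2, 39)}
        assert stat == pytest.approx(max(expect.values()), abs=1e-9)
        assert k == max(expect, key=expect.get)


class TestCalibration:
    def test_reps_floor(self):
        p = CPMParams(arl0=500.0, startup=20, calibration_reps=100)
        with pytest.raises(ValueError):
            calibrate_thresholds(p, horizon=500)

    def test_thresholds_increase_with_arl0(self):
        """Rarer target false alarms need higher thresholds everywhere."""
        lo = CPMParams(arl0=500.0, startup=20, calibration_reps=600, seed=9)
        hi = CPMParams(arl0=1000.0, startup=20, calibration_reps=600, seed=9)
        h_lo = calibrate_thresholds(lo, horizon=800)
        h_hi = calibrate_thresholds(hi, horizon=800)
        diff = h_hi.h - h_lo.h
        assert diff.mean() > 0
        assert np.all(diff > -0.5)  # pointwise up to Monte-Carlo noise

    def test_thresholds_nonincreasing_at_large_t(self, cpm500):
        """Hazard-calibrated thresholds flatten and drift down for t >> burn-in."""
        _, curve = cpm500
        assert curve.at(2400) <= curve.at(600) + 0.3

    def test_curve_dense_extension(self):
        curve = ThresholdCurve(np.array([10, 20, 40]),
                               np.array([5.0, 4.0, 3.0]), 500.0, 5, 256, "x")
        d = curve.dense(60)
        assert np.isinf(d[5])
        assert d[20] == pytest.approx(4.0)
        assert d[60] == pytest.approx(3.0)  # flat beyond the grid

    def test_memoized_and_reproducible(self):
        p = CPMParams(arl0=500.0, startup=20, calibration_reps=300, seed=4)
        a = calibrate_thresholds(p, horizon=400)
        b = calibrate_thresholds(p, horizon=400)
        assert a is b
        segmentation._MEMO.clear()
        c = calibrate_thresholds(p, horizon=400)
        np.testing.assert_array_equal(a.h, c.h)


def _trace_from(x, rate=140.0):
    return AccelTrace(np.arange(x.size) / rate, x, np.zeros(x.size),
                      np.ones(x.size), rate)


class TestMonitor:
    def test_constant_trace_single_segment(self, cpm500):
        params, curve = cpm500
        segs = segment_stream(_trace_from(np.zeros(1000)), params,
                              thresholds=curve)
        assert segs.n_segments == 1
        assert segs.segments == [(0, 1000)]

    def test_short_trace_single_segment_with_warning(self, cpm500, caplog):
        params, curve = cpm500
        with caplog.at_level("WARNING"):
            segs = segment_stream(_trace_from(np.zeros(50)), params,
                                  thresholds=curve)
        assert segs.n_segments == 1
        assert any("single segment" in r.message for r in caplog.records)

    def test_segments_tile_and_rerun_identical(self, cpm500, rng):
        params, curve = cpm500
        x = np.concatenate([rng.standard_normal(400),
                            rng.standard_normal(400) + 3.0,
                            rng.standard_normal(400) * 3.0])
        a = segment_stream(_trace_from(x), params, thresholds=curve)
        b = segment_stream(_trace_from(x), params, thresholds=curve)
        np.testing.assert_array_equal(a.boundaries, b.boundaries)
        assert a.boundaries[0] == 0 and a.boundaries[-1] == x.size
        assert np.all(np.diff(a.boundaries) > 0)
        assert np.all(a.detection_delays >= 0)

    def test_mean_shift_boundary_recovered(self, cpm500):
        """A 4-SD level shift at sample 2000 yields a boundary within +/-25."""
        params, curve = cpm500
        hits = 0
        for r in range(30):
            g = np.random.default_rng(1000 + r)
            x = np.concatenate([g.standard_normal(2000),
                                g.standard_normal(500) + 4.0])
            segs = segment_stream(_trace_from(x), params, thresholds=curve)
            inner = segs.boundaries[1:-1]
            if np.any(np.abs(inner - 2000) <= 25):
                hits += 1
        assert hits >= 27  # >= 90% of seeded runs

    def test_segment_set_validation(self):
        with pytest.raises(ValueError):
            SegmentSet(np.array([0, 10, 5, 20]), np.array([0, 0]), 20)
        with pytest.raises(ValueError):
            SegmentSet(np.array([0, 20]), np.array([1]), 20)


class TestCpmParams:
    def test_invariants(self):
        with pytest.raises(ValueError):
            CPMParams(arl0=50.0)
        with pytest.raises(ValueError):
            CPMParams(startup=5, min_side=5)
        with pytest.raises(ValueError):
            CPMParams(statistic="cusum")

    def test_effective_startup_defaults_to_one_second(self):
        p = CPMParams()
        assert p.effective_startup(144.2) == 144
        assert p.effective_startup(6.0) == 10  # clamped to 2 * min_side
        with pytest.raises(ValueError):
            p.effective_startup(None)

    def test_shipped_large_arl0_cache_loads(self):
        curve = calibrate_thresholds(CPMParams(), horizon=2000)
        assert curve.arl0 == 50_000.0
        assert curve.method == "tail-extrapolated"
        # thresholds well above the scaled-ARL0 curves
        assert curve.at(500) > 20.0
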