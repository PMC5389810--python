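"""Feature oracles: running-mean gain, ODBA, trends, spectra, correlations."""

import numpy as np
import pytest

from soarclass import features, synth
from soarclass.features import (FEATURE_NAMES, OdbaParams, featurize, odba,
                                segment_features, static_acceleration)
from soarclass.io_formats import AccelTrace

RATE = 140.0


def _trace(x, y, z, rate=RATE):
    n = len(x)
    return AccelTrace(np.arange(n) / rate, x, y, z, rate)


def _windowed_mean_oracle(v, w):
    """Direct centered mean with symmetric edge shrinkage, loop form."""
    n = v.size
    half = (w - 1) // 2
    out = np.empty(n)
    for i in range(n):
        he = min(half, i, n - 1 - i)
        out[i] = v[i - he:i + he + 1].mean()
    return out


class TestStaticAcceleration:
    def test_constant_is_reproduced(self):
        v = np.full(300, 0.73)
        np.testing.assert_allclose(static_acceleration(v, RATE), 0.73)

    def test_single_sample_window_is_identity(self, rng):
        v = rng.standard_normal(50)
        out = static_acceleration(v, RATE, OdbaParams(window_s=1.0 / RATE))
        np.testing.assert_array_equal(out, v)

    def test_matches_direct_windowed_mean(self, rng):
        v = rng.standard_normal(400)
        out = static_acceleration(v, RATE, OdbaParams(window_s=0.25))
        np.testing.assert_allclose(out, _windowed_mean_oracle(v, 35),
                                   atol=1e-10)

    def test_sine_attenuation_near_dirichlet_gain(self):
        """A 1 s mean over a 4 Hz sine leaves only the Dirichlet-kernel gain."""
        t = np.arange(1400) / RATE
        v = np.sin(2 * np.pi * 4.0 * t)
        out = static_acceleration(v, RATE, OdbaParams(window_s=1.0))
        w = 140
        # closed-form moving-average gain at f=4 Hz
        gain = abs(np.sin(np.pi * 4.0 * w / RATE)
                   / (w * np.sin(np.pi * 4.0 / RATE)))
        interior = slice(w, 1400 - w)
        measured = np.abs(out[interior]).max()
        assert measured == pytest.approx(gain, abs=0.01)
        assert measured < 0.05  # strongly attenuated


class TestOdba:
    def test_noiseless_constant_window_is_zero(self):
        w = np.tile([0.0, 0.0, 1.0], (200, 1))
        assert odba(w, RATE) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_absolute_residual_sum(self):
        """Numeric oracle: mean over samples of summed |raw - windowed mean|."""
        t = np.arange(280) / RATE
        w = np.column_stack([np.zeros(280), np.zeros(280),
                             np.sin(2 * np.pi * 4.0 * t)])
        resid = np.abs(w[:, 2] - _windowed_mean_oracle(w[:, 2], 140))
        assert odba(w, RATE) == pytest.approx(resid.mean(), abs=1e-12)
        # interior samples (full windows) show the 2/pi mean-rectified sine
        assert resid[70:210].mean() == pytest.approx(2 / np.pi, rel=0.05)

    def test_homogeneity(self, rng):
        w = rng.standard_normal((300, 3))
        assert odba(2 * w, RATE) == pytest.approx(2 * odba(w, RATE))


class TestSegmentFeatures:
    def test_linear_ramp_trend_and_sd_exact(self):
        t = np.arange(140) / RATE
        x = 0.5 * t
        f = segment_features(_trace(x, x * 0, x * 0 + 1), (0, 140))
        assert f["trend_x"] == pytest.approx(0.5, abs=1e-9)
        assert f["sd_x"] == pytest.approx(0.5 * np.std(t, ddof=1), abs=1e-12)
        assert f["min_x"] <= f["mean_x"] <= f["max_x"]

    def test_dominant_frequency_of_pure_sine(self):
        t = np.arange(140) / RATE
        z = np.sin(2 * np.pi * 4.0 * t)
        f = segment_features(_trace(z * 0, z * 0, z), (0, 140))
        assert f["domfreq_z"] == pytest.approx(4.0)

    def test_identical_channels_fully_correlated(self, rng):
        x = rng.standard_normal(100)
        f = segment_features(_trace(x, x.copy(), x + 1.0), (0, 100))
        assert f["corr_xy"] == pytest.approx(1.0)

    def test_kurtosis_is_non_excess(self, rng):
        """Moment-ratio kurtosis approaches 3 for a large normal sample."""
        x = rng.standard_normal(20000)
        f = segment_features(_trace(x, x * 0 + x[::-1], x * 0 + 1.0),
                             (0, 20000))
        assert f["kurt_x"] == pytest.approx(3.0, abs=0.15)

    def test_reversal_negates_trend_only(self, rng):
        x = rng.standard_normal(120) + np.linspace(0, 1, 120)
        y = rng.standard_normal(120)
        z = rng.standard_normal(120) + 1.0
        fwd = segment_features(_trace(x, y, z), (0, 120))
        rev = segment_features(_trace(x[::-1], y[::-1], z[::-1]), (0, 120))
        assert rev["trend_x"] == pytest.approx(-fwd["trend_x"], abs=1e-9)
        for name in ("mean_x", "min_x", "max_x", "sd_x", "skew_x", "kurt_x",
                     "domfreq_x", "corr_xy", "corr_yz"):
            assert rev[name] == pytest.approx(fwd[name], abs=1e-9), name

    def test_bounds_and_size_validation(self):
        tr = _trace(np.zeros(10), np.zeros(10), np.ones(10))
        with pytest.raises(IndexError):
            segment_features(tr, (5, 15))
        with pytest.raises(ValueError):
            segment_features(tr, (3, 4))

    def test_registry_has_28_features(self):
        assert len(FEATURE_NAMES) == 28
        per_axis = [n for n in FEATURE_NAMES if n.endswith("_z")]
        assert len(per_axis) == 8

    def test_all_features_finite_on_benchmark_segments(self, benchmark,
                                                       e2e_results):
        """Every statistic is finite for every kept benchmark segment."""
        ds = e2e_results["simple"].dataset
        assert np.isfinite(ds.X_seg).all()
        assert ds.X_seg.shape[1] == 28

    def test_featurize_uses_full_trace_static(self):
        """ODBA of a short segment uses trace-wide static, not segment-local."""
        t = np.arange(560) / RATE
        z = 1.0 + 0.2 * np.sin(2 * np.pi * 0.5 * t)  # slow posture drift
        tr = _trace(np.zeros(560), np.zeros(560), z)
        df = featurize(tr, [(200, 240)])
        seg_local = odba(np.column_stack([np.zeros(40), np.zeros(40),
                                          z[200:240]]), RATE)
        # trace-wide static tracks the slow drift; segment-local cannot
        assert df.loc[0, "odba"] != pytest.approx(seg_local, rel=1e-3)
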