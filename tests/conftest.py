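"""Shared fixtures: scaled CPM calibration and the seeded benchmark pipeline.

The expensive artifacts (Monte-Carlo threshold calibration at ARL0=500, the
default synthetic benchmark and its end-to-end evaluations) are built once
per session and shared across test modules.
"""

import numpy as np
import pytest

from soarclass import labeling, segmentation, studies


@pytest.fixture(scope="session")
def cpm500():
    """Scaled-down monitor (ARL0=500, 1 s burn-in at 100 Hz) with thresholds."""
    params = segmentation.CPMParams(arl0=500.0, startup=100, min_side=5,
                                    calibration_reps=1000, seed=1)
    curve = segmentation.calibrate_thresholds(params, horizon=2500,
                                              startup=100)
    return params, curve


@pytest.fixture(scope="session")
def benchmark():
    """Default complex-ethogram benchmark: 6 traces x 60 s at 140 Hz, seed 0."""
    return studies.default_benchmark(n_traces=6, seed=0,
                                     trace_duration_s=60.0)


@pytest.fixture(scope="session")
def e2e_results(benchmark):
    """Both classifiers evaluated end-to-end under both ethograms."""
    out = {}
    for eth in (labeling.SIMPLE_ETHOGRAM, labeling.COMPLEX_ETHOGRAM):
        cfg = studies.PipelineConfig(seed=0)
        out[eth.name] = studies.run_pipeline(benchmark, eth, cfg)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
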