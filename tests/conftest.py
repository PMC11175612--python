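import numpy as np
import pytest

from embryomotion import PipelineConfig, generate_trace, get_preset, process_trace


@pytest.fixture(scope="session")
def wt_trace():
    """One seeded wild-type recording (14-21.5 hAEL at 4 Hz) with ground truth."""
    return generate_trace(get_preset("wild_type"), frame_rate=4.0,
                          record_start=14.0, record_duration=7.5, seed=11)


@pytest.fixture(scope="session")
def wt_movement(wt_trace):
    trace, truth = wt_trace
    return process_trace(trace, hatch_time=truth.phase_boundaries[2],
                         config=PipelineConfig()), truth


def brute_rolling_mean(x, window):
    """Reference loop for the centred shrinking-window moving average."""
    x = np.asarray(x, dtype=float)
    half = window // 2
    return np.array([x[max(0, i - half): i + half + 1].mean() for i in range(x.size)])
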