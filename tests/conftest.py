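import numpy as np
import pytest

from rdfd import RRISeries, ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def short_scenario():
    """A 1-h drive with a 200-s trim, cheap enough for per-test generation."""
    return ScenarioConfig(duration_s=3600.0, trim_s=200.0,
                          fatigue_midpoint_s=1200.0)


@pytest.fixture
def steady_rr():
    """A metronomic 1-s R-R series spanning 0-7000 s."""
    times = np.arange(1.0, 7000.0, 1.0)
    return RRISeries(times=times, intervals=np.full(times.size, 1000.0))


def brute_force_window_stats(intervals):
    """Independent oracle for per-window (M, SDNN, RRVC)."""
    iv = np.asarray(intervals, dtype=float)
    m = iv.sum() / iv.size
    sdnn = (((iv - m) ** 2).sum() / (iv.size - 1)) ** 0.5
    return m, sdnn, sdnn / m
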