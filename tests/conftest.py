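import numpy as np
import pytest

from infantwear import AnalysisConfig, RRSeries


@pytest.fixture
def cfg():
    return AnalysisConfig()


def rr_from_intervals(rr_ms, start_time=None):
    """Build a self-consistent RRSeries from a plain interval list (ms)."""
    rr_ms = np.asarray(rr_ms, dtype=float)
    t_s = np.cumsum(rr_ms) / 1000.0
    return RRSeries(t_s, rr_ms, start_time=start_time).validate()


@pytest.fixture
def make_rr():
    return rr_from_intervals
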