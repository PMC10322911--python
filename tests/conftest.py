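import numpy as np
import pytest
from hypothesis import settings

import swrloop as sl

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def benchmark_session():
    """One paper-regime fixture session (seed 1), reused across tests."""
    return sl.synthesize_recording(sl.PAPER_REGIME, 1)


@pytest.fixture(scope="session")
def benchmark_scores():
    """Detection scoring over the full 10-seed pinned fixture."""
    return sl.run_benchmark()


@pytest.fixture(scope="session")
def short_session():
    """A 120 s mostly-NREM session for fast end-to-end tests."""
    cfg = sl.SessionConfig(
        duration_s=120.0,
        state=sl.StateConfig(mean_dwell_nrem_s=200.0, mean_dwell_rem_s=0.0,
                             mean_dwell_wake_s=0.0),
        artifact_rate_hz=0.0)
    return sl.synthesize_recording(cfg, 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
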