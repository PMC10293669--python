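import numpy as np
import pytest

from nosepoke import Phase, RunConfig, run_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def detection_log():
    """One simulated Detection-phase session with the default observer."""
    return run_session(RunConfig(phase=Phase.DETECTION, seed=7))


@pytest.fixture(scope="session")
def threshold_logs():
    """Five simulated threshold-detection sessions (one animal's week)."""
    return [
        run_session(RunConfig(phase=Phase.THRESHOLD_DETECTION, seed=200 + i))
        for i in range(5)
    ]
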