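import numpy as np
import pytest

from nvfuse.core import ChannelTimeSeries


def make_cts(data, rate=10.0, modality="eeg", t0=0.0):
    data = np.atleast_2d(np.asarray(data, float))
    return ChannelTimeSeries(
        data, rate, [f"ch{i}" for i in range(data.shape[0])], modality, t0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_montage():
    from nvfuse.simulate import make_montage

    return make_montage()


@pytest.fixture(scope="session")
def session_10db():
    """One simulated session at +10 dB, shared across read-only tests."""
    from nvfuse.simulate import simulate_session

    return simulate_session(seed=11, snr_db=10.0)
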