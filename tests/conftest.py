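import numpy as np
import pytest

from catrack.traces import ConditionedTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_conditioned(detrended, frame_rate_hz=10.0, f0_offset=0.0, noise_sd=1.0,
                     f0_raw=100.0, dff=None, neuron_id=0, session_id=0):
    """ConditionedTrace with explicit baseline/noise, bypassing the chain.

    Used by detector and binarization tests that need exact control over the
    threshold geometry.
    """
    detrended = np.asarray(detrended, dtype=np.float64)
    if dff is None:
        dff = (detrended - f0_offset) / f0_raw
    return ConditionedTrace(
        dff=np.asarray(dff, dtype=np.float64),
        detrended=detrended,
        f0_offset=f0_offset,
        f0_raw=f0_raw,
        noise_sd=noise_sd,
        quiescent_mask=np.ones(detrended.size, dtype=bool),
        frame_rate_hz=frame_rate_hz,
        neuron_id=neuron_id,
        session_id=session_id,
    )


@pytest.fixture
def conditioned_factory():
    return make_conditioned
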