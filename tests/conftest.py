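import numpy as np
import pytest

from megachan import ConditionLabel, CurrentTrace


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_trace(samples, fs=10_000.0, v_cis=-60.0, **kw):
    return CurrentTrace(samples=np.asarray(samples, float), sampling_rate=fs, v_cis=v_cis, **kw)


@pytest.fixture
def noise_trace(rng):
    """Unfiltered white-noise trace, SD 1 pA, 10 s at 10 kHz."""
    return make_trace(rng.standard_normal(100_000))


@pytest.fixture
def telegraph_trace():
    """Noise-free telegraph: 0 / -30 pA, 30% duty, 25 ms period, 10 s."""
    period = np.concatenate([np.zeros(175), np.full(75, -30.0)])
    return make_trace(np.tile(period, 400))


@pytest.fixture
def sim_condition():
    return ConditionLabel(ca_mm=3.0, bz423_mm=0.15)
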