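import numpy as np
import pytest

from nystlab.io import EyeTrace, SamplingSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(samples, rate=200.0, channel="R_V"):
    return EyeTrace(channel, np.asarray(samples, dtype=float), SamplingSpec(rate=rate))


@pytest.fixture
def sine_trace():
    """2 deg * sin(2*pi*0.5*t): per-cycle amplitude 4 deg, period 2 s."""
    rate = 200.0
    t = np.arange(int(10 * rate)) / rate
    return make_trace(2.0 * np.sin(2 * np.pi * 0.5 * t), rate=rate)


@pytest.fixture
def cohort():
    from nystlab.synthetic import generate_cohort

    return generate_cohort(seed=0)
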