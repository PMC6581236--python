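import numpy as np
import pytest

from pairflight.kinematics import AccelTrace

RATE = 200.0


def make_trace(z, rate=RATE, static_g=0.0):
    z = np.asarray(z, dtype=float) + static_g
    zeros = np.zeros_like(z)
    return AccelTrace(
        t=np.arange(len(z)) / rate, ax=zeros, ay=zeros, az=z, sample_rate_hz=rate
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
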