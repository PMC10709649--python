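import numpy as np
import pytest

from neuroei import PhaseSpec, SpectralSpec, TimeSeries, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_noise(rng):
    """5 s of seeded white noise at 1 kHz."""
    return TimeSeries(samples=rng.standard_normal(5000), fs=1000.0)


@pytest.fixture
def powerlaw_signal():
    """Deterministic surrogate with slope 1.5, f0=1 Hz, 5 s @ 1 kHz."""
    spec = SpectralSpec(slope=1.5)
    return generate(spec, PhaseSpec(seed=7))
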