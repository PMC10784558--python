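import numpy as np
import pytest

from lumigrain import (
    AcquisitionConfig,
    ClassProfile,
    DEFAULT_PROFILES,
    generate_signal,
)
from lumigrain.preprocess import moving_average, subtract_background

SW2015 = (2907.0, 0.724, 4.47)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def acq_clean():
    return AcquisitionConfig(noise_mode="none")


@pytest.fixture
def acq_poisson():
    return AcquisitionConfig(noise_mode="poisson")


@pytest.fixture
def archetype_signal(acq_clean):
    """Noise-free trace from the first reference parameter triple."""
    return generate_signal(SW2015, acq_clean)


@pytest.fixture
def noisy_signal(acq_poisson, rng):
    return generate_signal(SW2015, acq_poisson, rng)


@pytest.fixture
def preprocessed_signal(noisy_signal):
    return moving_average(subtract_background(noisy_signal, 9.0), 5)


@pytest.fixture
def profiles():
    return DEFAULT_PROFILES
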