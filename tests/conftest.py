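import numpy as np
import pytest

from dmorphons.fields import DisplacementField, Volume
from dmorphons.phantoms import random_velocity_field


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def smooth_field_factory(rng):
    """Factory for smooth random displacement fields (boundary-tapered)."""

    def make(shape=(32, 32), amplitude=2.0, smoothness=6.0):
        return random_velocity_field(shape, amplitude, smoothness, rng)

    return make


@pytest.fixture
def random_volume(rng):
    return Volume(rng.uniform(0.0, 1.0, size=(24, 24)))
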