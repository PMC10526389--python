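import numpy as np
import pytest

from mstate.microstate import MicrostateModel
from mstate.synthetic import make_planted_maps


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def planted_maps_30():
    """Four orthogonal, average-referenced, unit-GFP maps on 30 channels."""
    return make_planted_maps(30, 4, seed=7)


@pytest.fixture
def model_30(planted_maps_30):
    return MicrostateModel(maps=planted_maps_30, polarity_invariant=True)


def random_topography(rng, n_channels):
    """Non-degenerate random map."""
    v = rng.standard_normal(n_channels)
    while np.allclose(v - v.mean(), 0):
        v = rng.standard_normal(n_channels)
    return v
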