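import numpy as np
import pytest

from thzmargin import (ComplexIndex, SearchGrid, default_phantom_spec,
                       default_substrate, hz_to_omega)
from thzmargin.phantom import default_frequency_axis


@pytest.fixture
def substrate():
    return default_substrate()


@pytest.fixture
def grid():
    return SearchGrid()


@pytest.fixture
def omega550():
    return hz_to_omega(550e9)


@pytest.fixture
def freq_axis():
    return default_frequency_axis()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_phantom():
    """Noise-free, blur-free default phantom spec."""
    return default_phantom_spec()


def random_on_grid_index(rng, grid):
    nv = grid.n_values
    kv = grid.kappa_values
    return ComplexIndex(float(rng.choice(nv)), float(rng.choice(kv)))
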