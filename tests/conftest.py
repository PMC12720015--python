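import numpy as np
import pytest

from consplan.grids import BinaryRange, GridSpec
from consplan import synth


@pytest.fixture(scope="session")
def grid30():
    return GridSpec(30, 30)


@pytest.fixture(scope="session")
def stack30(grid30):
    return synth.generate_env_stack(grid30, n_layers=6, autocorr_range_km=5.0, seed=11)


@pytest.fixture(scope="session")
def species30(stack30):
    """A well-behaved virtual species on the 30x30 stack."""
    return synth.define_virtual_species(
        stack30,
        {"intercept": 0.0, "bio1": 2.0, "bio2": -1.5, "bio3": 1.0},
        target_prevalence=0.2,
        species_id="vsp1",
    )


def make_range(grid, cells, species_id="sp", scenario="current"):
    """BinaryRange from a list of flat cell indices."""
    mask = np.zeros(grid.n_cells, dtype=bool)
    mask[list(cells)] = True
    return BinaryRange(species_id, scenario, grid, mask.reshape(grid.shape))


@pytest.fixture
def range_factory():
    return make_range
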