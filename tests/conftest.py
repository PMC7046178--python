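import numpy as np
import pytest

from rangeshift.demography import (
    ANNUAL,
    TREE,
    PopulationState,
    locally_adapted_system,
    plastic_system,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_925)


@pytest.fixture
def la_system():
    return locally_adapted_system()


@pytest.fixture
def plastic():
    return plastic_system()


@pytest.fixture
def small_annual_state(la_system):
    """Empty annual state on a 4 x 6 grid with six genotypes."""
    return PopulationState.empty(ANNUAL, la_system, (4, 6))


@pytest.fixture
def small_tree_state(la_system):
    return PopulationState.empty(TREE, la_system, (4, 6))
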