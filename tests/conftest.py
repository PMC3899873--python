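import numpy as np
import pytest

from lumencpm import geometry
from lumencpm.core import Simulation
from lumencpm.params import EnergyParams, MechanismConfig


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down branched sprout used by the behavioural tests."""
    return geometry.GeometrySpec(width=150, height=150, cell_size=15,
                                 cap_size=(15, 8))


@pytest.fixture(scope="session")
def tiny_spec():
    """Very small sprout for invariant-checking runs."""
    return geometry.GeometrySpec(width=100, height=100, cell_size=9,
                                 cap_size=(9, 6))


@pytest.fixture()
def mixed_state():
    """20x20 fixture exercising all eight site types."""
    return geometry.build_fixture("oracle_mixed")


@pytest.fixture()
def mixed_sim(mixed_state):
    return Simulation(mixed_state, mech=MechanismConfig(seed=7))


def random_valid_proposal(state, rng):
    """A (source, target) Moore-neighbour pair valid for a copy attempt."""
    from lumencpm.params import ECM, VESICLE
    from lumencpm.state import MOORE

    tl = state.comp_type[state.lattice]
    rows, cols = np.nonzero(tl != ECM)
    while True:
        i = rng.integers(rows.size)
        sr, sc = int(rows[i]), int(cols[i])
        k = rng.integers(8)
        tr, tc = sr + int(MOORE[k, 0]), sc + int(MOORE[k, 1])
        s = state.lattice[sr, sc]
        d = state.lattice[tr, tc]
        if s == d or state.comp_type[d] == ECM or state.comp_type[s] == VESICLE:
            continue
        return (sr, sc), (tr, tc)
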