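import numpy as np
import pytest

from crystalhabit.data import optimized_cell, reported_cell
from crystalhabit.energetics import ForceFieldParams
from crystalhabit.lattice import MillerIndex

# the five morphologically important faces with their vacuum attachment energies
FIVE_FACES = [
    (MillerIndex(2, 0, 0), 250.08),
    (MillerIndex(1, 1, 0), 266.26),
    (MillerIndex(0, 0, 2), 365.24),
    (MillerIndex(1, 1, -1), 284.40),
    (MillerIndex(2, 0, -2), 185.29),
]


@pytest.fixture
def opt_cell():
    return optimized_cell()


@pytest.fixture
def rep_cell():
    return reported_cell()


@pytest.fixture
def lj_params():
    return ForceFieldParams(
        epsilon={"X": 0.3, "O": 0.2, "H": 0.01, "Ca": 0.25},
        sigma={"X": 3.0, "O": 3.15, "H": 1.0, "Ca": 3.2},
        vdw_cutoff=15.5,
        coulomb_method="direct_sum",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230118)
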