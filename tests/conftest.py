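import numpy as np
import pytest

from mtlattice import build_lattice
from mtlattice.lattice_synth import LatticeSpec


@pytest.fixture(scope="session")
def ideal13():
    """Unskewed 13-protofilament lattice, 12 dimers, no noise."""
    return build_lattice(LatticeSpec(n_pf=13))


@pytest.fixture(scope="session")
def ideal14():
    """Unskewed 14-protofilament lattice, 12 dimers, no noise."""
    return build_lattice(LatticeSpec(n_pf=14))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
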