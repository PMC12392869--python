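import numpy as np
import pytest

from binderforge.backbone import build_chain_from_torsions
from binderforge.blueprint import TorsionTriple
from binderforge.fixtures import make_idealized_motif, make_pseudo_target, make_topology_stats


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def topology_stats():
    return make_topology_stats(0)


@pytest.fixture(scope="session")
def motif():
    return make_idealized_motif()


@pytest.fixture(scope="session")
def pseudo_target():
    return make_pseudo_target(0)


@pytest.fixture
def helix8():
    """Ideal 8-residue α-helix backbone."""
    return build_chain_from_torsions([TorsionTriple(-57, -47, 180)] * 8)


@pytest.fixture
def mixed_torsions():
    """A 12-residue torsion list spanning all four trans ABEGO bins."""
    pattern = [(-120, 130), (-57, -47), (60, 35), (120, -130)]
    return [TorsionTriple(phi, psi, 180) for phi, psi in pattern * 3]
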