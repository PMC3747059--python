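import numpy as np
import pytest

from octabarrel.barrel import BarrelParams, build_loops, build_scaffold
from octabarrel.design import DesignConfig, design_sequence
from octabarrel.regions import classify_positions


@pytest.fixture(scope="session")
def params():
    return BarrelParams()


@pytest.fixture(scope="session")
def scaffold(params):
    return build_scaffold(params)


@pytest.fixture(scope="session")
def barrel(scaffold):
    """One closed default barrel conformation (216 residues)."""
    return build_loops(scaffold, rng_seed=11)


@pytest.fixture(scope="session")
def regions(barrel):
    return classify_positions(barrel)


@pytest.fixture(scope="session")
def designed(barrel, regions):
    """A quickly designed sequence on the session barrel."""
    cfg = DesignConfig(mc_steps=250, seed=5)
    return design_sequence(barrel, regions, cfg,
                           rng=np.random.default_rng([5, 1]))


def random_rigid_transform(rng):
    """Random rotation matrix + translation vector."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    return Q, t
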