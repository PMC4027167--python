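import numpy as np
import pytest

from napring.docking import RestraintR3
from napring.labels import build_label_ensemble
from napring.structure import Atom, Structure
from napring.synthesis import make_tetramer_geometry, make_toy_dimer, toy_label_sites


@pytest.fixture(scope="session")
def toy_dimer():
    return make_toy_dimer()


@pytest.fixture(scope="session")
def toy_sites():
    return toy_label_sites()


@pytest.fixture(scope="session")
def o_tetramer(toy_dimer):
    return make_tetramer_geometry("O", toy_dimer)


@pytest.fixture(scope="session")
def toy_ensembles(toy_dimer, toy_sites):
    """Subsampled label ensembles for all canonical sites (fast scoring)."""
    return {name: build_label_ensemble(toy_dimer, site, seed=i).subsample(80, 0)
            for i, (name, site) in enumerate(toy_sites.items())}


@pytest.fixture(scope="session")
def truth_restraints(toy_dimer, toy_ensembles, o_tetramer):
    """Zero-noise restraints generated from the 'O' ground-truth geometry."""
    from napring.labels import effective_r3_distance

    _, T = o_tetramer
    pairs = [("bridge", "bridge"), ("ear_A", "ear_A"), ("ear_A", "ear_B"),
             ("rim_A", "rim_A"), ("rim_A", "rim_B")]
    restraints = []
    for a, b in pairs:
        target = effective_r3_distance(toy_ensembles[a],
                                       toy_ensembles[b].transformed(T))
        restraints.append(RestraintR3(toy_ensembles[a], toy_ensembles[b],
                                      target, 0.0, label=f"{a}-{b}"))
    return restraints


def square_structure(side=10.0, chain="A"):
    """Four-atom square in the xy plane, handy for exact geometry checks."""
    pos = [(0, 0, 0), (side, 0, 0), (side, side, 0), (0, side, 0)]
    atoms = [Atom("CA", "C", i + 1, "GLY", chain, np.array(p, float), 12.011)
             for i, p in enumerate(pos)]
    return Structure(atoms)


@pytest.fixture
def square():
    return square_structure()


def random_rotation(seed=0):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q
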