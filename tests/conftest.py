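import numpy as np
import pytest

from molfuse.records import make_record, embed_conformer
from molfuse import synthetic


def embedded(smiles: str, seed: int = 0):
    return embed_conformer(make_record(smiles, [np.nan]), seed=seed)


@pytest.fixture(scope="session")
def benzene():
    return embedded("c1ccccc1")


@pytest.fixture(scope="session")
def ethanol():
    return embedded("CCO")


@pytest.fixture(scope="session")
def methane():
    return embedded("C")


@pytest.fixture(scope="session")
def fixture_molecules():
    """50 embedded fixture molecules (session-cached; embedding dominates)."""
    spec = synthetic.FixtureSpec(n_molecules=50, seed=123)
    return synthetic.make_dataset(spec).records


@pytest.fixture(scope="session")
def motif_dataset():
    """Motif-classification table used by several training tests."""
    return synthetic.make_dataset(synthetic.FixtureSpec(n_molecules=120, seed=7))


def random_rigid_motion(rng):
    """A uniformly random proper rotation plus a translation."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.normal(scale=5.0, size=3)
    return Q, t
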