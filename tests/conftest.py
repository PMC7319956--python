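import numpy as np
import pytest

from molpi import PIConfig, SynthConfig, fixture, featurize_set, gen_molecules


@pytest.fixture(scope="session")
def anisole():
    return fixture("anisole")


@pytest.fixture(scope="session")
def diatomics():
    return fixture("hbr"), fixture("f2")


@pytest.fixture(scope="session")
def synth_pool():
    """A moderate synthetic pool with PI features and oracle labels, shared
    across learning and active-learning tests (featurization dominates cost)."""
    from molpi import oracle_energy

    cfg = SynthConfig(seed=5, n_molecules=300)
    mols = gen_molecules(cfg)
    feats = featurize_set(mols, PIConfig())
    labels = {m.id: oracle_energy(m, cfg) for m in mols}
    return cfg, mols, feats, labels


def random_cloud(rng: np.random.Generator, n: int, scale: float = 2.0) -> np.ndarray:
    """Random 3-D point cloud with distinct pairwise distances (a.s.)."""
    return scale * rng.random((n, 3))
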