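import numpy as np
import pytest

from equiace.structures import AtomicConfiguration


def random_cluster(rng, n_atoms=6, elements=(1, 6, 8), spread=1.8, min_sep=0.95):
    """A random molecular cluster with a minimum pair separation."""
    for _ in range(200):
        pos = rng.normal(size=(n_atoms, 3)) * spread
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        if (d + 1e9 * np.eye(n_atoms)).min() >= min_sep:
            return AtomicConfiguration(pos, rng.choice(elements, size=n_atoms))
    raise RuntimeError("packing failed")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cluster_factory(rng):
    def factory(**kw):
        return random_cluster(rng, **kw)
    return factory
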