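import numpy as np
import pytest

import netboot as nb


@pytest.fixture(scope="session")
def ring10():
    """10-node ring, |w| = 0.25, half the edges negative."""
    return nb.chain_network(10, 0.25, 0.5, seed=42)


@pytest.fixture(scope="session")
def ring_data(ring10):
    """Moderate ordinal sample from the ring network."""
    return nb.simulate_dataset(ring10, 500, levels=4, seed=7)


@pytest.fixture(scope="session")
def fast_estimator():
    """Default pipeline estimator (polychoric + EBIC-glasso)."""
    return nb.make_ebicglasso_estimator()


@pytest.fixture(scope="session")
def small_boot(ring_data, fast_estimator):
    """A small nonparametric bootstrap shared across bootstrap tests."""
    return nb.nonparametric_boot(ring_data, fast_estimator, n_boot=60, seed=5)


def random_pd_correlation(p, rng):
    """Random well-conditioned correlation matrix."""
    a = rng.normal(size=(p, p + 3))
    s = a @ a.T + p * np.eye(p)
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)
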