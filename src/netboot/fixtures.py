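"""Synthetic demonstration data.

The tutorial workflow is demonstrated on a synthetic 17-item ordinal
dataset emulating a symptom-scale study: 17 items scored 0-3 by a few
hundred respondents, generated from a sparse positive-manifold
partial-correlation network with a ring-plus-shortcuts topology and
three deliberately strong edges.  It reproduces the qualitative shape
of such data (a handful of dominant edges, moderately stable strength
order) without being derived from any real dataset.
"""

from __future__ import annotations

import numpy as np

from .errors import NotRepresentableError
from .ggm import NetworkModel
from .netsim import simulate_dataset

__all__ = ["symptom_network", "symptom_fixture"]


def symptom_network(p: int = 17, seed: int | None = 0) -> NetworkModel:
    """Synthetic partial-correlation network with a positive manifold:
    a weak all-pairs background (symptom scales intercorrelate
    throughout), a ring of moderate edges with a few shortcuts, and
    three deliberately strong edges."""
    rng = np.random.default_rng(seed)
    w = np.full((p, p), 0.03)
    for i in range(p):
        j = (i + 1) % p
        w[i, j] = w[j, i] = 0.10
    # random shortcuts
    n_short = p // 2
    placed = 0
    while placed < n_short:
        i, j = rng.integers(0, p, size=2)
        if i == j or w[i, j] != 0.03:
            continue
        w[i, j] = w[j, i] = rng.uniform(0.06, 0.14)
        placed += 1
    # three dominant edges on the ring
    strong = rng.choice(p, size=3, replace=False)
    for i in strong:
        j = (i + 1) % p
        w[i, j] = w[j, i] = 0.35
    np.fill_diagonal(w, 0.0)
    net = NetworkModel(w, labels=[f"S{i + 1}" for i in range(p)], meta={"method": "synthetic"})
    if np.linalg.eigvalsh(np.eye(p) - net.weights)[0] <= 0:
        raise NotRepresentableError("synthetic network draw was not PD; change the seed")
    return net


def symptom_fixture(n: int = 359, seed: int | None = 0, levels: int = 4):
    """Synthetic ordinal dataset (default: 17 items, 4 levels, n = 359)
    drawn from :func:`symptom_network`."""
    net = symptom_network(seed=seed)
    data = simulate_dataset(net, n=n, levels=levels, seed=None if seed is None else seed + 1)
    return data, net
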