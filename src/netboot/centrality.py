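"""Weighted centrality indices: strength, closeness, betweenness.

All three indices use the absolute edge weight as the connection
strength, with shortest-path lengths defined as 1/|w|.  This makes the
indices invariant to edge signs, and gives the defining property of a
ring network with constant |w|: every node has exactly equal strength,
closeness, and betweenness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _fast
from .ggm import EDGE_EPS, NetworkModel

__all__ = ["CentralityTable", "shortest_path_distances", "centrality_table"]

INDICES = ("strength", "closeness", "betweenness")


def _length_matrix(weights: np.ndarray) -> np.ndarray:
    aw = np.abs(weights)
    with np.errstate(divide="ignore"):
        lengths = np.where(aw > EDGE_EPS, 1.0 / np.where(aw > EDGE_EPS, aw, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_path_distances(network: NetworkModel | np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distance matrix with edge length 1/|w|.

    Unreachable pairs are +inf; the diagonal is 0.
    """
    w = network.weights if isinstance(network, NetworkModel) else np.asarray(network)
    return _fast.dijkstra_all(_length_matrix(w))


def _centrality_vectors(weights: np.ndarray) -> np.ndarray:
    """(3, p) array of raw strength, closeness, betweenness.

    Internal fast path shared by the bootstrap loops; no container or
    validation overhead.
    """
    lengths = _length_matrix(weights)
    dist = _fast.dijkstra_all(lengths)
    strength = np.sum(np.abs(weights), axis=1)
    tot = np.sum(dist, axis=1)
    closeness = np.where(np.isfinite(tot) & (tot > 0), 1.0 / np.where(tot > 0, tot, 1.0), 0.0)
    btw = _fast.betweenness(lengths)
    return np.vstack([strength, closeness, btw])


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)  # population SD over nodes
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


@dataclass
class CentralityTable:
    """Raw and z-standardized centrality indices, one row per node."""

    labels: list[str]
    strength: np.ndarray
    closeness: np.ndarray
    betweenness: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.labels,
                "strength": self.strength,
                "closeness": self.closeness,
                "betweenness": self.betweenness,
                "z_strength": _zscore(self.strength),
                "z_closeness": _zscore(self.closeness),
                "z_betweenness": _zscore(self.betweenness),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def vector(self, index: str) -> np.ndarray:
        return getattr(self, index)


def centrality_table(network: NetworkModel) -> CentralityTable:
    """Strength (sum of |w|), closeness (inverse total shortest-path
    distance, 0 when any node is unreachable), and betweenness (Brandes
    counting over unordered pairs, fractional credit for tied shortest
    paths, endpoints excluded)."""
    if network.p < 2:
        raise ValueError("centrality requires at least 2 nodes")
    vec = _centrality_vectors(network.weights)
    return CentralityTable(
        labels=list(network.labels),
        strength=vec[0],
        closeness=vec[1],
        betweenness=vec[2],
    )
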