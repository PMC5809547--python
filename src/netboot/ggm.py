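"""Gaussian graphical model estimation.

The GGM represents each edge as a partial correlation: the correlation
of two variables after conditioning on every other variable, computable
from the inverse of the correlation matrix (the precision matrix).  To
cope with the quadratic growth of the parameter count relative to the
sample sizes typical of questionnaire data, the precision matrix is
estimated with the graphical lasso — an L1 penalty that sets many
partial correlations exactly to zero — and the penalty weight is chosen
by minimizing the Extended Bayesian Information Criterion (EBIC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fast
from .correlations import CorrelationEstimate, OrdinalDataset, nearest_pd, polychoric_matrix
from .errors import NotRepresentableError

__all__ = [
    "NetworkModel",
    "EbicSelection",
    "sample_pcor",
    "ebic_score",
    "estimate_ggm",
    "pcor_to_correlation",
    "param_count",
    "make_ebicglasso_estimator",
]

log = logging.getLogger(__name__)

#: |weight| above which an edge counts as present
EDGE_EPS = 1e-10


@dataclass
class NetworkModel:
    """A weighted undirected network of partial correlations.

    ``weights`` is symmetric with a zero diagonal; entry (i, j) is the
    partial correlation between nodes i and j given all other nodes.
    """

    weights: np.ndarray
    labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-8):
            raise ValueError("weights must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        if np.any(np.abs(w) >= 1.0):
            raise ValueError("partial correlations must have absolute value < 1")
        self.weights = w
        if self.labels is None:
            self.labels = [f"V{i + 1}" for i in range(w.shape[0])]
        grid = self.meta.get("lambda_grid")
        if grid is not None and len(grid) > 1 and not np.all(np.diff(grid) < 0):
            raise ValueError("lambda grid must be strictly decreasing")

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edge_vector(self) -> np.ndarray:
        """Upper-triangle weights in fixed (row-major) order."""
        return self.weights[np.triu_indices(self.p, 1)]

    def edge_pairs(self) -> list[tuple[str, str]]:
        iu, ju = np.triu_indices(self.p, 1)
        return [(self.labels[i], self.labels[j]) for i, j in zip(iu, ju)]

    def n_edges(self) -> int:
        return int(np.sum(np.abs(self.edge_vector()) > EDGE_EPS))

    # -- interchange -------------------------------------------------------

    def to_edgelist(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(self.p, 1)
        return pd.DataFrame(
            {
                "node_i": [self.labels[i] for i in iu],
                "node_j": [self.labels[j] for j in ju],
                "weight": self.weights[iu, ju],
            }
        )

    def to_edgelist_csv(self, path) -> None:
        self.to_edgelist().to_csv(path, index=False)

    @classmethod
    def from_edgelist(cls, frame: pd.DataFrame) -> "NetworkModel":
        labels = sorted(set(frame["node_i"]) | set(frame["node_j"]))
        index = {lab: i for i, lab in enumerate(labels)}
        w = np.zeros((len(labels), len(labels)))
        for _, row in frame.iterrows():
            i, j = index[row["node_i"]], index[row["node_j"]]
            w[i, j] = w[j, i] = row["weight"]
        return cls(w, labels)

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.labels)
        iu, ju = np.triu_indices(self.p, 1)
        for i, j in zip(iu, ju):
            if abs(self.weights[i, j]) > EDGE_EPS:
                g.add_edge(self.labels[i], self.labels[j], weight=float(self.weights[i, j]))
        nx.write_graphml(g, path)

    @classmethod
    def from_graphml(cls, path) -> "NetworkModel":
        import networkx as nx

        g = nx.read_graphml(path)
        labels = sorted(g.nodes)
        index = {lab: i for i, lab in enumerate(labels)}
        w = np.zeros((len(labels), len(labels)))
        for a, b, d in g.edges(data=True):
            w[index[a], index[b]] = w[index[b], index[a]] = d.get("weight", 0.0)
        return cls(w, labels)


@dataclass
class EbicSelection:
    """Per-lambda record of the EBIC model search."""

    lambdas: np.ndarray
    loglik: np.ndarray
    n_edges: np.ndarray
    ebic: np.ndarray
    selected: int

    def __post_init__(self) -> None:
        if self.selected != int(np.argmin(self.ebic)):
            raise ValueError("selected index must minimize EBIC")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambdas,
                "loglik": self.loglik,
                "n_edges": self.n_edges,
                "ebic": self.ebic,
            }
        )


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------


def _precision_to_pcor(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    w = -precision / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    return (w + w.T) / 2.0


def sample_pcor(corr: CorrelationEstimate | np.ndarray, labels=None) -> NetworkModel:
    """Unregularized partial correlations by direct matrix inversion:
    w_ij = -kappa_ij / sqrt(kappa_ii kappa_jj) with kappa the precision."""
    if isinstance(corr, CorrelationEstimate):
        matrix, labels, n = corr.matrix, corr.labels, corr.n
    else:
        matrix, n = np.asarray(corr, dtype=float), None
    try:
        precision = np.linalg.inv(matrix)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"correlation matrix is singular: {exc}") from exc
    meta = {"method": "pcor"}
    if n:
        meta["n"] = n
    return NetworkModel(_precision_to_pcor(precision), labels, meta)


def pcor_to_correlation(network: NetworkModel) -> np.ndarray:
    """Correlation matrix implied by a partial-correlation network.

    The implied precision has a unit diagonal and off-diagonals -w_ij;
    its inverse, rescaled to unit diagonal, is the correlation matrix a
    multivariate normal with this network would produce.  Round-tripping
    through :func:`sample_pcor` recovers the weights.
    """
    precision = np.eye(network.p) - network.weights
    try:
        np.linalg.cholesky(precision)  # cheap PD check
    except np.linalg.LinAlgError as exc:
        raise NotRepresentableError(
            "network has no Gaussian representation (implied precision not PD)"
        ) from exc
    inv = np.linalg.inv(precision)
    d = np.sqrt(np.diag(inv))
    corr = inv / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def param_count(p: int) -> int:
    """Number of free parameters of a p-node GGM on ordinal data:
    p thresholds plus p(p-1)/2 pairwise associations."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return p + p * (p - 1) // 2


# ---------------------------------------------------------------------------
# EBIC
# ---------------------------------------------------------------------------


def ebic_score(
    precision: np.ndarray, corr: CorrelationEstimate | np.ndarray, n: int, gamma: float = 0.5
) -> float:
    """EBIC of a precision matrix against a sample correlation matrix.

    -2 l + E log n + 4 E gamma log p, with l = n/2 (log det K - tr(S K))
    (constant terms dropped) and E the number of nonzero off-diagonal
    upper-triangle entries.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    S = corr.matrix if isinstance(corr, CorrelationEstimate) else np.asarray(corr)
    K = np.asarray(precision, dtype=float)
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0 or np.any(np.linalg.eigvalsh(K) <= 0):
        raise ValueError("precision matrix must be positive definite")
    p = K.shape[0]
    ll = n / 2.0 * (logdet - np.trace(S @ K))
    E = int(np.sum(np.abs(K[np.triu_indices(p, 1)]) > EDGE_EPS))
    return float(-2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def _ebic_terms(Ks: np.ndarray, S: np.ndarray, n: int, gamma: float):
    """Vectorized EBIC over a stack of precision matrices."""
    p = S.shape[0]
    iu = np.triu_indices(p, 1)
    sign, logdet = np.linalg.slogdet(Ks)
    trace = np.einsum("ij,kji->k", S, Ks)
    ll = n / 2.0 * (logdet - trace)
    E = (np.abs(Ks[:, iu[0], iu[1]]) > EDGE_EPS).sum(axis=1)
    ebic = -2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p)
    ebic = np.where(sign > 0, ebic, np.inf)
    return ll, E, ebic


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


def estimate_ggm(
    data_or_corr,
    n: int | None = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    ratio: float = 0.01,
    lambdas: np.ndarray | None = None,
    glasso_tol: float = 1e-5,
    **polychoric_kwargs,
) -> NetworkModel:
    """Regularized GGM: graphical-lasso path + EBIC selection.

    Accepts an :class:`OrdinalDataset` (routed through
    :func:`polychoric_matrix`) or a :class:`CorrelationEstimate` /
    correlation matrix with explicit ``n``.  The lasso is solved on a
    log-spaced grid of ``n_lambda`` penalties from lambda_max (the
    largest absolute off-diagonal input correlation, where the graph is
    empty) down to ``ratio * lambda_max``; the EBIC(gamma)-minimizing
    model is returned as a partial-correlation network.
    """
    if isinstance(data_or_corr, OrdinalDataset):
        corr = polychoric_matrix(data_or_corr, **polychoric_kwargs)
        method = f"EBICglasso/{corr.method}"
    elif isinstance(data_or_corr, CorrelationEstimate):
        corr = data_or_corr
        method = "EBICglasso"
    else:
        matrix = np.asarray(data_or_corr, dtype=float)
        if n is None:
            raise ValueError("sample size n is required with a raw correlation matrix")
        corr = CorrelationEstimate(matrix=matrix, n=n)
        method = "EBICglasso"
    n_eff = n if n is not None else corr.n
    if n_eff is None or n_eff <= 0:
        raise ValueError("sample size n is required and must be positive")

    S = corr.matrix
    p = S.shape[0]
    if n_eff <= p:
        log.warning("n (%d) <= p (%d): estimates rely fully on regularization", n_eff, p)
    if np.linalg.eigvalsh(S)[0] <= 0:
        S = nearest_pd(S)

    if lambdas is None:
        lam_max = float(np.max(np.abs(S - np.diag(np.diag(S)))))
        if lam_max <= 0:
            lambdas = np.array([0.0])
        else:
            lambdas = np.geomspace(lam_max, ratio * lam_max, n_lambda)
    else:
        lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]

    Ks = _fast.glasso_path(S, np.ascontiguousarray(lambdas), 200, glasso_tol)
    ll, E, ebic = _ebic_terms(Ks, S, n_eff, gamma)
    sel = int(np.argmin(ebic))
    selection = EbicSelection(
        lambdas=lambdas, loglik=ll, n_edges=E.astype(int), ebic=ebic, selected=sel
    )
    weights = _precision_to_pcor(Ks[sel])
    # soft-thresholded zeros survive the rescaling exactly
    meta = {
        "method": method,
        "gamma": gamma,
        "lambda": float(lambdas[sel]),
        "lambda_grid": lambdas,
        "n": int(n_eff),
        "selection": selection,
    }
    return NetworkModel(weights, corr.labels, meta)


def make_ebicglasso_estimator(
    gamma: float = 0.5,
    n_lambda: int = 100,
    ratio: float = 0.01,
    **kwargs,
):
    """An ``OrdinalDataset -> NetworkModel`` estimator with fixed settings,
    suitable for the bootstrap and simulation drivers."""

    def estimator(data: OrdinalDataset) -> NetworkModel:
        return estimate_ggm(data, gamma=gamma, n_lambda=n_lambda, ratio=ratio, **kwargs)

    estimator.__name__ = f"ebicglasso(gamma={gamma})"
    return estimator
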