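"""Bootstrap accuracy analysis for network estimates.

Two resampling schemes re-estimate the network many times and record
every edge weight and centrality index per replicate:

* nonparametric — rows resampled with replacement (always applicable,
  and the recommended scheme for ordinal data);
* parametric — new continuous cases drawn from the multivariate normal
  distribution implied by an estimated network (regularization biases
  this scheme toward zero; it is kept for power-analysis style use).

From the stored replicates the module builds quantile confidence
intervals for edge weights and the bootstrapped difference test: the
paired difference of two statistics across replicates, with a CI from
Hyndman-Fan type-6 quantiles, is significant when it excludes zero.
Bootstrapped CIs are deliberately never exposed as edge-vs-zero
significance tests, and no p-values are derived from the replicates —
only CI-based decisions at a user-chosen alpha, which can be no smaller
than 2/N_B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centrality import INDICES, _centrality_vectors
from .correlations import OrdinalDataset
from .errors import NetbootError
from .ggm import NetworkModel, make_ebicglasso_estimator, pcor_to_correlation

__all__ = [
    "BootstrapResult",
    "DifferenceTest",
    "quantile_type6",
    "boot_ci",
    "min_alpha",
    "nonparametric_boot",
    "parametric_boot",
    "edge_ci_table",
    "difference_test",
    "difference_matrix",
    "pair_count",
    "edge_difference_count",
    "bonferroni_alpha",
]


# ---------------------------------------------------------------------------
# quantiles and counts
# ---------------------------------------------------------------------------


def quantile_type6(values: np.ndarray, prob: float) -> float:
    """Hyndman-Fan type-6 sample quantile.

    With sorted values x_(1..n) and h = (n + 1) * prob: x_(1) if h <= 1,
    x_(n) if h >= n, otherwise linear interpolation between x_(floor h)
    and the next order statistic.  Type 6 gives wider intervals than
    numpy's default (type 7), which keeps bootstrap CIs from being
    anti-conservative.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("quantile of an empty vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("quantile requires finite values")
    x = np.sort(x)
    n = x.size
    h = (n + 1) * prob
    if h <= 1:
        return float(x[0])
    if h >= n:
        return float(x[-1])
    fl = int(math.floor(h))
    return float(x[fl - 1] + (h - fl) * (x[fl] - x[fl - 1]))


def boot_ci(values: np.ndarray, alpha: float, n_boot: int) -> tuple[float, float]:
    """[alpha/2, 1 - alpha/2] type-6 quantile CI of bootstrap replicates.

    At the attainable floor alpha = 2/N_B the CI is exactly the
    replicate range (the two most extreme bootstrap values).
    """
    if alpha <= min_alpha(n_boot) * (1 + 1e-12):
        x = np.asarray(values, dtype=float)
        if x.size == 0 or not np.all(np.isfinite(x)):
            raise ValueError("CI requires finite, non-empty replicates")
        return float(x.min()), float(x.max())
    return quantile_type6(values, alpha / 2), quantile_type6(values, 1 - alpha / 2)


def min_alpha(n_boot: int) -> float:
    """Smallest alpha for which N_B bootstrap replicates can form a CI:
    2/N_B, the level at which the CI spans the two most extreme values."""
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap samples")
    return 2.0 / n_boot


def pair_count(k: int) -> int:
    """Number of unordered pairs of k items: C(k, 2).  Counts both the
    possible edges of a k-node network and the pairwise centrality
    difference tests."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return k * (k - 1) // 2


def edge_difference_count(p: int) -> int:
    """Number of all-pairs edge-weight difference tests in a p-node
    network: C(C(p, 2), 2).  For p = 20 this is already 17,955."""
    return pair_count(pair_count(p))


def bonferroni_alpha(n_tests: int, alpha: float = 0.05) -> float:
    """The per-test level a Bonferroni correction would require.  Provided
    for reporting only: levels like 0.05/17,955 ~ 3e-6 are unattainable
    with any realistic number of bootstrap replicates, so corrected
    bootstrap tests are not offered."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Replicate-level edge weights and centralities from a bootstrap."""

    kind: str  # "nonparametric" | "parametric"
    n_boot: int
    edge_samples: np.ndarray  # (n_boot, n_edge_slots)
    centrality_samples: np.ndarray  # (n_boot, 3, p)
    sample_network: NetworkModel
    sample_centrality: np.ndarray  # (3, p)
    seed: int | None
    n_redrawn: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ValueError("a bootstrap needs at least 2 replicates")
        if self.edge_samples.shape[0] != self.n_boot:
            raise ValueError("edge_samples must have one row per replicate")
        if self.centrality_samples.shape[0] != self.n_boot:
            raise ValueError("centrality_samples must have one row per replicate")

    @property
    def labels(self) -> list[str]:
        return self.sample_network.labels

    @property
    def edge_pairs(self) -> list[tuple[str, str]]:
        return self.sample_network.edge_pairs()

    def _stat_matrix(self, kind: str) -> tuple[np.ndarray, np.ndarray, list]:
        """(replicate matrix, sample vector, ids) for a statistic kind."""
        if kind == "edge":
            return self.edge_samples, self.sample_network.edge_vector(), self.edge_pairs
        if kind in INDICES:
            k = INDICES.index(kind)
            return (
                self.centrality_samples[:, k, :],
                self.sample_centrality[k],
                list(self.labels),
            )
        raise ValueError(f"unknown statistic kind {kind!r}")


def _run_boot(
    draw_and_estimate, n_boot: int, kind: str, sample_network: NetworkModel, seed, note=""
) -> BootstrapResult:
    """Shared replicate loop: redraw failed replicates, abort past 10%."""
    p = sample_network.p
    n_edges = p * (p - 1) // 2
    edges = np.empty((n_boot, n_edges))
    cents = np.empty((n_boot, 3, p))
    max_fail = max(1, int(math.ceil(0.1 * n_boot)))
    failures = 0
    b = 0
    while b < n_boot:
        try:
            net = draw_and_estimate()
        except NetbootError as exc:  # degenerate resample etc. -> redraw
            failures += 1
            if failures > max_fail:
                raise RuntimeError(
                    f"{failures} bootstrap replicates failed (> 10% of N_B = {n_boot}); "
                    f"last error: {exc}"
                ) from exc
            continue
        edges[b] = net.weights[np.triu_indices(p, 1)]
        cents[b] = _centrality_vectors(net.weights)
        b += 1
    return BootstrapResult(
        kind=kind,
        n_boot=n_boot,
        edge_samples=edges,
        centrality_samples=cents,
        sample_network=sample_network,
        sample_centrality=_centrality_vectors(sample_network.weights),
        seed=seed,
        n_redrawn=failures,
        note=note,
    )


def nonparametric_boot(
    data: OrdinalDataset,
    estimator=None,
    n_boot: int = 1000,
    seed: int | None = None,
    sample_network: NetworkModel | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample n rows with replacement, re-run
    the estimator, record edge weights and centralities.

    Replicates on which the estimator fails (e.g. a resampled column
    loses all variation) are redrawn; more than 10% failures aborts.
    Deterministic given ``seed``.
    """
    if estimator is None:
        estimator = make_ebicglasso_estimator()
    if sample_network is None:
        sample_network = estimator(data)
    rng = np.random.default_rng(seed)
    n = data.n

    def draw():
        rows = rng.integers(0, n, size=n)
        return estimator(data.resample_rows(rows))

    return _run_boot(draw, n_boot, "nonparametric", sample_network, seed)


def parametric_boot(
    network: NetworkModel,
    n: int,
    n_boot: int = 1000,
    seed: int | None = None,
    estimator=None,
) -> BootstrapResult:
    """Parametric bootstrap: draw n multivariate-normal cases from the
    correlation structure implied by ``network`` and re-estimate.

    The draws are continuous even when the network came from ordinal
    data, and lasso shrinkage biases the replicates toward zero — for
    ordinal data prefer :func:`nonparametric_boot`.  The result carries
    a "continuous-data bootstrap" note.
    """
    if estimator is None:
        estimator = make_ebicglasso_estimator()
    corr = pcor_to_correlation(network)  # raises if not representable
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng(seed)
    p = network.p
    levels = ["continuous"] * p

    def draw():
        x = rng.standard_normal((n, p)) @ chol.T
        return estimator(OrdinalDataset(x, network.labels, levels))

    return _run_boot(
        draw, n_boot, "parametric", network, seed, note="continuous-data bootstrap"
    )


# ---------------------------------------------------------------------------
# CI tables
# ---------------------------------------------------------------------------


def edge_ci_table(result: BootstrapResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-edge bootstrap summary: sample value, replicate mean, and the
    [alpha/2, 1 - alpha/2] type-6 quantile CI.

    Rows are ordered by the sample edge weight (descending); exact ties
    — common because the lasso zeroes many edges — are broken by the
    bootstrap mean.
    """
    lo_a = min_alpha(result.n_boot)
    if alpha < lo_a:
        raise ValueError(
            f"alpha = {alpha} is below 2/N_B = {lo_a:.6g}; with {result.n_boot} "
            "replicates no wider CI than the replicate range exists"
        )
    sample = result.sample_network.edge_vector()
    boots = result.edge_samples
    mean = boots.mean(axis=0)
    cis = [boot_ci(boots[:, e], alpha, result.n_boot) for e in range(boots.shape[1])]
    lo = np.array([c[0] for c in cis])
    hi = np.array([c[1] for c in cis])
    pairs = result.edge_pairs
    table = pd.DataFrame(
        {
            "edge": [f"{a}--{b}" for a, b in pairs],
            "node_i": [a for a, _ in pairs],
            "node_j": [b for _, b in pairs],
            "sample": sample,
            "boot_mean": mean,
            "ci_lower": lo,
            "ci_upper": hi,
        }
    )
    return table.sort_values(
        ["sample", "boot_mean"], ascending=False, kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# difference tests
# ---------------------------------------------------------------------------


@dataclass
class DifferenceTest:
    """A bootstrapped difference test between two edges or two nodes."""

    kind: str
    id_a: object
    id_b: object
    estimate: float  # sample difference
    ci_lower: float
    ci_upper: float
    alpha: float
    significant: bool

    def __post_init__(self) -> None:
        if self.ci_lower > self.ci_upper:
            raise ValueError("CI bounds out of order")


def _resolve_id(ids: list, id_) -> int:
    if isinstance(id_, (int, np.integer)) and not isinstance(id_, bool):
        if 0 <= id_ < len(ids):
            return int(id_)
        raise ValueError(f"index {id_} out of range for {len(ids)} ids")
    if id_ in ids:
        return ids.index(id_)
    # edge ids may be given as "A--B" strings
    if isinstance(id_, str) and "--" in id_:
        a, b = id_.split("--", 1)
        for cand in ((a, b), (b, a)):
            if cand in ids:
                return ids.index(cand)
    raise ValueError(f"unknown id {id_!r}")


def difference_test(
    result: BootstrapResult, kind: str, id_a, id_b, alpha: float = 0.05
) -> DifferenceTest:
    """Test whether two edge weights or two centralities differ.

    Takes the paired difference of the two statistics within each
    bootstrap replicate and builds a type-6 quantile CI around the
    differences; significant iff zero lies outside the CI.  A zero-width
    CI at exactly zero (both statistics tied in every replicate, e.g.
    two lasso-zeroed edges) counts as containing zero.  No multiple-
    testing correction is applied.
    """
    if alpha < min_alpha(result.n_boot):
        raise ValueError(
            f"alpha = {alpha} is below 2/N_B = {min_alpha(result.n_boot):.6g}"
        )
    boots, sample, ids = result._stat_matrix(kind)
    ia = _resolve_id(ids, id_a)
    ib = _resolve_id(ids, id_b)
    if ia == ib:
        raise ValueError("the two ids must differ")
    d = boots[:, ia] - boots[:, ib]
    lo, hi = boot_ci(d, alpha, result.n_boot)
    significant = not (lo <= 0.0 <= hi)
    return DifferenceTest(
        kind=kind,
        id_a=ids[ia],
        id_b=ids[ib],
        estimate=float(sample[ia] - sample[ib]),
        ci_lower=lo,
        ci_upper=hi,
        alpha=alpha,
        significant=significant,
    )


@dataclass
class DifferenceMatrix:
    """All-pairs bootstrapped difference tests for one statistic kind."""

    kind: str
    alpha: float
    ids: list
    significant: np.ndarray  # boolean, symmetric, False diagonal
    n_tests: int

    def to_frame(self) -> pd.DataFrame:
        names = [f"{i[0]}--{i[1]}" if isinstance(i, tuple) else str(i) for i in self.ids]
        return pd.DataFrame(self.significant, index=names, columns=names)

    def to_json_dict(self) -> dict:
        pairs = []
        k = len(self.ids)
        for a in range(k):
            for b in range(a + 1, k):
                pairs.append(
                    {
                        "id_a": list(self.ids[a]) if isinstance(self.ids[a], tuple) else self.ids[a],
                        "id_b": list(self.ids[b]) if isinstance(self.ids[b], tuple) else self.ids[b],
                        "significant": bool(self.significant[a, b]),
                    }
                )
        return {"kind": self.kind, "alpha": self.alpha, "n_tests": self.n_tests, "pairs": pairs}


def difference_matrix(
    result: BootstrapResult,
    kind: str,
    alpha: float = 0.05,
    only_nonzero: bool = False,
) -> DifferenceMatrix:
    """All-pairs difference tests (uncorrected) plus the analytic test
    count.  ``only_nonzero`` restricts edge comparisons to edges that are
    nonzero in the sample network."""
    boots, sample, ids = result._stat_matrix(kind)
    if kind == "edge" and only_nonzero:
        keep = np.abs(sample) > 1e-10
        boots = boots[:, keep]
        sample = sample[keep]
        ids = [i for i, k_ in zip(ids, keep) if k_]
    k = len(ids)
    sig = np.zeros((k, k), dtype=bool)
    for a in range(k):
        for b in range(a + 1, k):
            lo, hi = boot_ci(boots[:, a] - boots[:, b], alpha, result.n_boot)
            sig[a, b] = sig[b, a] = not (lo <= 0.0 <= hi)
    return DifferenceMatrix(
        kind=kind, alpha=alpha, ids=ids, significant=sig, n_tests=pair_count(k)
    )
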