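"""Simulation designs for validating the accuracy methods.

The validation studies all start from a chain (ring) network of partial
correlations: every node tied to its two neighbours with constant
absolute weight, so all centralities are exactly equal.  Watts-Strogatz
rewiring moves edges with a given probability, grading the design from
"no true centrality differences" (rewiring 0) to "centralities differ"
(rewiring 1).  Multivariate-normal data are drawn from the implied
correlation matrix and discretized into ordinal categories at random
thresholds, then fed through the full pipeline: polychoric correlations
-> EBIC-glasso -> bootstrap / case-dropping -> CS-coefficient or
difference tests.

Three study drivers are provided:

* ``cs`` — distribution of the CS-coefficient per rewiring x sample
  size condition (null behaviour: CS stays low when centralities are
  truly equal);
* ``edge_diff`` — Type-I error of the edge-weight bootstrapped
  difference test among true-equal nonzero edges;
* ``centrality_diff`` — rejection rate of the centrality bootstrapped
  difference test over all node pairs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .bootstrap import difference_matrix, nonparametric_boot
from .correlations import OrdinalDataset
from .errors import NotRepresentableError
from .centrality import INDICES
from .ggm import NetworkModel, make_ebicglasso_estimator, pcor_to_correlation
from .stability import case_drop_boot, cs_coefficient, default_drop_levels

__all__ = [
    "SimulationDesign",
    "SimulationResult",
    "chain_network",
    "rewire_network",
    "simulate_dataset",
    "run_study",
]


# ---------------------------------------------------------------------------
# network generators
# ---------------------------------------------------------------------------


def chain_network(
    p: int = 10,
    weight: float = 0.25,
    prop_negative: float = 0.5,
    seed: int | None = None,
    closed: bool = True,
) -> NetworkModel:
    """Ring of p nodes: node i tied to its neighbours with partial
    correlation ``weight``; ceil(prop_negative * n_edges) randomly chosen
    edges are negated.  ``closed=False`` gives an open chain (p - 1
    edges) instead of the default ring."""
    if p < 3:
        raise ValueError("chain networks need at least 3 nodes")
    rng = np.random.default_rng(seed)
    w = np.zeros((p, p))
    n_edges = p if closed else p - 1
    edges = [(i, (i + 1) % p) for i in range(n_edges)]
    signs = np.ones(n_edges)
    k = int(np.ceil(prop_negative * n_edges))
    if k:
        signs[rng.choice(n_edges, size=k, replace=False)] = -1.0
    for (i, j), s in zip(edges, signs):
        w[i, j] = w[j, i] = s * weight
    net = NetworkModel(w, meta={"method": "chain", "weight": weight})
    _assert_representable(net)
    return net


def _assert_representable(net: NetworkModel) -> None:
    precision = np.eye(net.p) - net.weights
    if np.linalg.eigvalsh(precision)[0] <= 0:
        raise NotRepresentableError("generated network has no Gaussian representation")


def rewire_network(
    network: NetworkModel, prob: float, seed: int | None = None, max_retries: int = 100
) -> NetworkModel:
    """Watts-Strogatz rewiring: each edge independently with probability
    ``prob`` keeps one (randomly chosen) endpoint and moves the other to
    a uniformly chosen node, avoiding self-loops and duplicate edges.
    Weights (including signs) travel with their edge, so the edge count
    and the weight multiset are preserved.  A rewiring whose implied
    precision is not PD is redrawn, up to ``max_retries`` times."""
    if not 0 <= prob <= 1:
        raise ValueError("rewiring probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = network.p
    iu, ju = np.triu_indices(p, 1)
    base = [(int(i), int(j), network.weights[i, j]) for i, j in zip(iu, ju)
            if abs(network.weights[i, j]) > 0]
    for _retry in range(max_retries):
        edges = {(i, j) for i, j, _ in base}
        new_edges = []
        for i, j, wgt in base:
            edges.discard((i, j))
            if rng.random() < prob:
                keep = i if rng.random() < 0.5 else j
                placed = {(a, b) for a, b, _ in new_edges}
                candidates = [
                    v for v in range(p)
                    if v != keep
                    and (min(keep, v), max(keep, v)) != (i, j)  # must actually move
                    and (min(keep, v), max(keep, v)) not in edges
                    and (min(keep, v), max(keep, v)) not in placed
                ]
                if candidates:
                    other = int(rng.choice(candidates))
                    a, b = min(keep, other), max(keep, other)
                else:  # fully saturated node; keep the edge
                    a, b = i, j
            else:
                a, b = i, j
            new_edges.append((a, b, wgt))
            edges.add((a, b))
        w = np.zeros((p, p))
        for a, b, wgt in new_edges:
            w[a, b] = w[b, a] = wgt
        net = NetworkModel(w, network.labels, dict(network.meta, rewired=prob))
        try:
            _assert_representable(net)
        except NotRepresentableError:
            continue
        return net
    raise NotRepresentableError(
        f"no positive-definite rewiring found in {max_retries} attempts"
    )


def simulate_dataset(
    network: NetworkModel,
    n: int,
    levels: int = 4,
    seed: int | None = None,
    max_threshold_redraws: int = 1000,
) -> OrdinalDataset:
    """Draw n cases from the multivariate normal implied by ``network``
    and discretize each variable at ``levels - 1`` thresholds drawn
    i.i.d. standard normal (sorted).  Thresholds are redrawn for a
    variable until every category is observed, so downstream polychoric
    estimation always sees a full margin.  ``levels=0`` skips
    ordinalization and returns the continuous draws."""
    corr = pcor_to_correlation(network)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    x = rng.standard_normal((n, network.p)) @ chol.T
    if levels == 0:
        return OrdinalDataset(x, list(network.labels), ["continuous"] * network.p)
    if levels < 2:
        raise ValueError("levels must be 0 (continuous) or >= 2")
    out = np.empty_like(x)
    for j in range(network.p):
        for _redraw in range(max_threshold_redraws):
            thr = np.sort(rng.standard_normal(levels - 1))
            cats = np.searchsorted(thr, x[:, j])
            if np.unique(cats).size == levels:
                out[:, j] = cats
                break
        else:
            raise RuntimeError(
                f"could not find thresholds observing all {levels} categories "
                f"for variable {j} at n = {n}"
            )
    return OrdinalDataset(out, list(network.labels), ["ordinal"] * network.p)


# ---------------------------------------------------------------------------
# study designs
# ---------------------------------------------------------------------------


@dataclass
class SimulationDesign:
    """One validation-study configuration.

    The full-scale design (1,000 replicates, N_B = 1,000) reproduces the
    original studies; the defaults here are desk-scale (replicates = 100,
    N_B = 200) so a study completes on one CPU in minutes.
    """

    p: int = 10
    weight: float = 0.25
    prop_negative: float = 0.5
    rewire_probs: tuple = (0.0, 0.1, 0.5, 1.0)
    sample_sizes: tuple = (100, 250, 500, 1000, 2500, 5000)
    replicates: int = 100
    levels: int = 4
    n_boot: int = 200
    alphas: tuple = (0.05,)
    drop_levels: int = 10
    gamma: float = 0.5
    n_lambda: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for pr in self.rewire_probs:
            if not 0 <= pr <= 1:
                raise ValueError("rewiring probabilities must lie in [0, 1]")
        if not 0 <= self.prop_negative <= 1:
            raise ValueError("prop_negative must lie in [0, 1]")

    def n_datasets(self, study: str) -> int:
        conds = len(self.sample_sizes)
        if study in ("cs", "centrality_diff"):
            conds *= len(self.rewire_probs)
        return conds * self.replicates

    def design_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SimulationResult:
    """Replicate-level records plus per-condition summaries."""

    study: str
    design: SimulationDesign
    records: pd.DataFrame
    summary: pd.DataFrame
    seed: int | None = None

    def to_csv(self, path) -> None:
        out = self.summary.copy()
        out["study"] = self.study
        out["seed"] = self.seed
        out["design_hash"] = self.design.design_hash()
        out.to_csv(path, index=False)


def _mc_se(rates: np.ndarray) -> float:
    """Monte-Carlo standard error of a mean over replicate-level rates."""
    if rates.size < 2:
        return float("nan")
    return float(np.std(rates, ddof=1) / np.sqrt(rates.size))


def run_study(design: SimulationDesign, study: str) -> SimulationResult:
    """Run one validation study end to end.

    Every replicate runs the complete pipeline: generate (and possibly
    rewire) a chain network, simulate an ordinal dataset, estimate via
    polychoric + EBIC-glasso, then bootstrap / case-drop and test.
    Deterministic given ``design.seed``.
    """
    if study not in ("cs", "edge_diff", "centrality_diff"):
        raise ValueError(f"unknown study {study!r}")
    if study == "edge_diff":
        # the edge Type-I design compares true-equal nonzero edges: all
        # weights identical and positive, no rewiring
        if design.prop_negative != 0 or any(pr != 0 for pr in design.rewire_probs):
            raise ValueError(
                "edge_diff requires prop_negative = 0 and rewiring probability 0"
            )

    estimator = make_ebicglasso_estimator(gamma=design.gamma, n_lambda=design.n_lambda)
    root = np.random.SeedSequence(design.seed)
    records: list[dict] = []

    rewire_probs = design.rewire_probs if study != "edge_diff" else (0.0,)
    for pr in rewire_probs:
        for n in design.sample_sizes:
            for rep in range(design.replicates):
                child = np.random.SeedSequence(
                    entropy=root.entropy if root.entropy is not None else 0,
                    spawn_key=(int(pr * 1000), n, rep),
                )
                s_net, s_rew, s_data, s_boot = [
                    int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(4)
                ]
                net = chain_network(design.p, design.weight, design.prop_negative, seed=s_net)
                if pr > 0:
                    net = rewire_network(net, pr, seed=s_rew)
                data = simulate_dataset(net, n, levels=design.levels, seed=s_data)

                if study == "cs":
                    # the 95%-certainty proportion needs >= 20 replicates
                    # per drop level to be meaningful
                    cs_boot = max(design.n_boot, 20 * design.drop_levels)
                    cd = case_drop_boot(
                        data,
                        estimator,
                        levels=default_drop_levels(design.drop_levels),
                        n_boot=cs_boot,
                        seed=s_boot,
                    )
                    with warnings.catch_warnings():
                        # non-monotone qualifying proportions are routine
                        # Monte-Carlo noise at simulation scale
                        warnings.simplefilter("ignore", UserWarning)
                        cs = cs_coefficient(cd)
                    for idx in INDICES:
                        records.append(
                            dict(rewire=pr, n=n, replicate=rep, index=idx, cs=cs[idx])
                        )
                else:
                    boot = nonparametric_boot(
                        data, estimator, n_boot=design.n_boot, seed=s_boot
                    )
                    if study == "edge_diff":
                        true_edges = _true_edge_slots(net)
                        for alpha in design.alphas:
                            dm = difference_matrix(boot, "edge", alpha=alpha)
                            sub = dm.significant[np.ix_(true_edges, true_edges)]
                            k = len(true_edges)
                            rate = sub[np.triu_indices(k, 1)].mean()
                            records.append(
                                dict(
                                    rewire=pr, n=n, replicate=rep, alpha=alpha,
                                    rejection_rate=float(rate),
                                )
                            )
                    else:  # centrality_diff
                        for alpha in design.alphas:
                            for idx in INDICES:
                                dm = difference_matrix(boot, idx, alpha=alpha)
                                k = len(dm.ids)
                                rate = dm.significant[np.triu_indices(k, 1)].mean()
                                records.append(
                                    dict(
                                        rewire=pr, n=n, replicate=rep, alpha=alpha,
                                        index=idx, rejection_rate=float(rate),
                                    )
                                )

    rec = pd.DataFrame(records)
    if study == "cs":
        summary = (
            rec.groupby(["rewire", "n", "index"])["cs"]
            .agg(
                median_cs="median",
                prop_below_025=lambda c: float(np.mean(c < 0.25)),
                prop_below_05=lambda c: float(np.mean(c < 0.5)),
                replicates="size",
            )
            .reset_index()
        )
    else:
        keys = ["rewire", "n", "alpha"] + (["index"] if study == "centrality_diff" else [])
        summary = (
            rec.groupby(keys)["rejection_rate"]
            .agg(rejection_rate="mean", mc_se=_mc_se, replicates="size")
            .reset_index()
        )
    return SimulationResult(
        study=study, design=design, records=rec, summary=summary, seed=design.seed
    )


def _true_edge_slots(net: NetworkModel) -> list[int]:
    """Upper-triangle slot indices of edges nonzero in the true network."""
    vec = net.edge_vector()
    return list(np.nonzero(np.abs(vec) > 1e-12)[0])
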