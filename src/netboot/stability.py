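"""Centrality stability under case dropping.

Bootstrap CIs for centrality indices are biased, so instead of
intervals this module asks a stability question: if the network is
re-estimated on random subsets of the cases, how well does the order of
centralities survive?  The case-dropping (m-out-of-n) bootstrap draws
subsets with a fixed proportion of rows removed and correlates the
subset centralities with the full-sample ones.  The CS-coefficient
summarizes the resulting curves: the largest drop proportion at which,
with 95% certainty, that correlation is still at least 0.7.

Rules of thumb from simulation: a CS below 0.25 means the order of
centralities should not be interpreted; above 0.5 is preferable.  These
bands are reported, never enforced.

A node-dropping variant (columns instead of rows) runs through the same
code path; it is harder to interpret, because dropping many nodes
changes the network being estimated, not just the sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import INDICES, _centrality_vectors
from .correlations import OrdinalDataset
from .errors import NetbootError
from .ggm import make_ebicglasso_estimator

__all__ = [
    "CaseDropResult",
    "CSCoefficient",
    "default_drop_levels",
    "case_drop_boot",
    "cs_coefficient",
]

#: interpretation bands for the CS-coefficient (reported, not enforced)
CS_BANDS = {"minimum": 0.25, "preferred": 0.5}


def default_drop_levels(k: int = 10, max_level: float = 0.75) -> np.ndarray:
    """k equally spaced drop proportions from 0.1 up to ``max_level``
    (the cap keeps at least a quarter of the cases in every subset)."""
    return np.linspace(0.1, max_level, k)


@dataclass
class CaseDropResult:
    """Correlations between original and subset centralities, per drop
    level, replicate, and index."""

    levels: np.ndarray  # strictly increasing drop proportions
    correlations: np.ndarray  # (n_levels, reps, 3)
    indices: tuple = INDICES
    seed: int | None = None
    axis: str = "cases"
    n_undefined: int = 0  # zero-variance subset centralities, recorded as 0

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 1 or np.any(np.diff(self.levels) <= 0):
            raise ValueError("drop levels must be strictly increasing")
        c = self.correlations
        if c.shape[0] != self.levels.size or c.shape[2] != len(self.indices):
            raise ValueError("correlations must be (n_levels, reps, n_indices)")
        if np.any((c < -1 - 1e-9) | (c > 1 + 1e-9)):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def reps_per_level(self) -> int:
        return self.correlations.shape[1]

    def summary(self, cor_threshold: float = 0.7) -> pd.DataFrame:
        """Per-level summary: mean correlation, 2.5%/97.5% quantiles, and
        the proportion of replicates at or above the threshold."""
        rows = []
        for li, lev in enumerate(self.levels):
            for ki, idx in enumerate(self.indices):
                c = self.correlations[li, :, ki]
                rows.append(
                    {
                        "level": lev,
                        "index": idx,
                        "mean_cor": float(np.mean(c)),
                        "q2.5": float(np.quantile(c, 0.025)),
                        "q97.5": float(np.quantile(c, 0.975)),
                        "prop_above": float(np.mean(c >= cor_threshold)),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class CSCoefficient:
    """CS value per centrality index, with the defining constants."""

    values: dict[str, float]
    cor_threshold: float = 0.7
    certainty: float = 0.95
    bands: dict = field(default_factory=lambda: dict(CS_BANDS))

    def __getitem__(self, index: str) -> float:
        return self.values[index]

    def to_json_dict(self) -> dict:
        return {
            "cs": self.values,
            "cor_threshold": self.cor_threshold,
            "certainty": self.certainty,
            "interpretation_bands": self.bands,
        }


def _near_constant(x: np.ndarray) -> bool:
    # float noise in shortest-path sums can leave a spread of ~1e-16 on
    # vectors that are constant by construction
    return np.ptp(x) <= 1e-10 * max(1.0, float(np.max(np.abs(x))))


def _safe_corr(a: np.ndarray, b: np.ndarray, method: str) -> float | None:
    """Correlation of two centrality vectors; None when undefined."""
    if _near_constant(a) or _near_constant(b):
        return None
    if method == "spearman":
        from scipy.stats import rankdata

        a = rankdata(a)
        b = rankdata(b)
        if np.std(a) == 0 or np.std(b) == 0:
            return None
    return float(np.corrcoef(a, b)[0, 1])


def case_drop_boot(
    data: OrdinalDataset,
    estimator=None,
    levels: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    axis: str = "cases",
    cor_method: str = "pearson",
    sample_network=None,
) -> CaseDropResult:
    """Case-dropping subset bootstrap.

    For each drop proportion l, draws ceil((1 - l) n) rows without
    replacement, re-estimates the network, and correlates the subset
    centralities with the full-sample ones per index.  The ``n_boot``
    replicates are split evenly over the drop levels.  Subsets whose
    estimation fails are redrawn (capped); undefined correlations
    (zero-variance centralities, e.g. an empty subset network) are
    recorded as 0 — instability is not hidden by degenerate estimates.

    ``axis="nodes"`` drops columns instead of rows (node-dropping
    variant); correlations are then computed over the surviving nodes.
    """
    if estimator is None:
        estimator = make_ebicglasso_estimator()
    if levels is None:
        levels = default_drop_levels()
    levels = np.asarray(levels, dtype=float)
    if np.any(levels < 0) or np.any(levels >= 1):
        raise ValueError("drop levels must lie in [0, 1)")
    if axis not in ("cases", "nodes"):
        raise ValueError("axis must be 'cases' or 'nodes'")

    n, p = data.n, data.p
    total = n if axis == "cases" else p
    reps = max(1, n_boot // levels.size)
    rng = np.random.default_rng(seed)

    if sample_network is None:
        sample_network = estimator(data)
    orig = _centrality_vectors(sample_network.weights)

    corrs = np.empty((levels.size, reps, len(INDICES)))
    n_undefined = 0
    for li, lev in enumerate(levels):
        m = int(np.ceil((1.0 - lev) * total))
        if axis == "cases" and m < p + 1:
            raise ValueError(
                f"drop level {lev} leaves {m} cases; need at least p + 1 = {p + 1}"
            )
        if axis == "nodes" and m < 2:
            raise ValueError(f"drop level {lev} leaves fewer than 2 nodes")
        for r in range(reps):
            for _attempt in range(20):
                keep = rng.choice(total, size=m, replace=False)
                try:
                    if axis == "cases":
                        net = estimator(data.resample_rows(keep))
                        sub = _centrality_vectors(net.weights)
                        ref = orig
                    else:
                        keep = np.sort(keep)
                        net = estimator(data.select_columns(keep))
                        sub = _centrality_vectors(net.weights)
                        ref = orig[:, keep]
                except NetbootError:
                    continue
                break
            else:
                raise RuntimeError(
                    f"estimation failed for 20 consecutive subsets at drop level {lev}"
                )
            for ki in range(len(INDICES)):
                c = _safe_corr(ref[ki], sub[ki], cor_method)
                if c is None:
                    n_undefined += 1
                    c = 0.0
                corrs[li, r, ki] = np.clip(c, -1.0, 1.0)
    return CaseDropResult(
        levels=levels,
        correlations=corrs,
        seed=seed,
        axis=axis,
        n_undefined=n_undefined,
    )


def cs_coefficient(
    result: CaseDropResult, cor_threshold: float = 0.7, certainty: float = 0.95
) -> CSCoefficient:
    """CS(cor = ``cor_threshold``): per index, the largest tested drop
    level at which the proportion of replicates with correlation >=
    ``cor_threshold`` is at least ``certainty``; 0 when no level
    qualifies.

    Monte-Carlo noise can make the qualifying proportion non-monotone
    across levels; the literal maximum qualifying level is returned, with
    a warning when a smaller level failed.
    """
    if result.reps_per_level < 20:
        raise ValueError(
            f"CS requires >= 20 replicates per drop level, got {result.reps_per_level}"
        )
    values = {}
    for ki, idx in enumerate(result.indices):
        props = np.mean(result.correlations[:, :, ki] >= cor_threshold, axis=1)
        qualifying = props >= certainty
        if not np.any(qualifying):
            values[idx] = 0.0
            continue
        best = int(np.max(np.nonzero(qualifying)[0]))
        if not np.all(qualifying[: best + 1]):
            warnings.warn(
                f"qualifying proportion for {idx!r} is non-monotone across drop "
                "levels; CS uses the largest qualifying level",
                stacklevel=2,
            )
        values[idx] = float(result.levels[best])
    return CSCoefficient(values=values, cor_threshold=cor_threshold, certainty=certainty)
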