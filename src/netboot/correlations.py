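"""Input correlations for Gaussian graphical models.

Partial-correlation networks are estimated from a correlation matrix.
For ordinal item data (e.g. symptom scales scored 0-3) the appropriate
input is the polychoric correlation: the correlation of the latent
continuous normal variables assumed to underlie each pair of ordinal
variables.  This module implements the standard two-step estimator —
marginal thresholds from the cumulative category proportions, then a
one-dimensional maximum-likelihood search for the latent correlation of
each pair with thresholds held fixed — together with polyserial
(ordinal x continuous) and Pearson (continuous x continuous) dispatch,
and an eigenvalue-clipping repair for matrices that are not positive
definite (polychoric matrices assembled pairwise need not be).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import _fast
from .errors import ConvergenceError, DegenerateVariableError

__all__ = [
    "OrdinalDataset",
    "CorrelationEstimate",
    "estimate_thresholds",
    "polychoric_matrix",
    "nearest_pd",
    "read_table",
]

#: default smallest eigenvalue enforced by :func:`nearest_pd`
PD_FLOOR = 1e-6

#: latent correlations are constrained to [-RHO_MAX, RHO_MAX]
RHO_MAX = 0.999

#: a column is treated as ordinal iff integer-valued with at most this
#: many distinct observed values (overridable per column)
ORDINAL_MAX_LEVELS = 10


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class OrdinalDataset:
    """A cases-by-variables score table.

    Parameters
    ----------
    values : (n, p) array
        Observed scores; integer categories for ordinal columns, real
        numbers for continuous columns.  NaN marks a missing value.
    labels : sequence of str
        Variable (node) names.
    level : sequence of {"ordinal", "continuous"}
        Declared measurement level per column.
    """

    values: np.ndarray
    labels: list[str]
    level: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d (cases x variables) array")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValueError(f"need at least 2 cases and 2 variables, got {n} x {p}")
        self.labels = list(self.labels)
        self.level = list(self.level)
        if len(self.labels) != p or len(self.level) != p:
            raise ValueError("labels and level must have one entry per column")
        for lev in self.level:
            if lev not in ("ordinal", "continuous"):
                raise ValueError(f"unknown measurement level {lev!r}")
        for j in range(p):
            col = self.values[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0 or np.all(col == col[0]):
                raise DegenerateVariableError(
                    f"degenerate variable {self.labels[j]!r}: column is constant"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def resample_rows(self, rows: np.ndarray) -> "OrdinalDataset":
        """Dataset restricted to (or resampled over) the given row indices."""
        return OrdinalDataset(self.values[rows], self.labels, self.level)

    def select_columns(self, cols: np.ndarray) -> "OrdinalDataset":
        return OrdinalDataset(
            self.values[:, cols],
            [self.labels[c] for c in cols],
            [self.level[c] for c in cols],
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, level: dict[str, str] | None = None
    ) -> "OrdinalDataset":
        """Build a dataset from a DataFrame, auto-detecting ordinal columns.

        A column is treated as ordinal iff its observed values are all
        integers and it has at most ``ORDINAL_MAX_LEVELS`` distinct
        values; pass ``level={"col": "continuous"}`` to override.
        """
        values = frame.to_numpy(dtype=float)
        labels = [str(c) for c in frame.columns]
        levels = []
        for j, lab in enumerate(labels):
            if level is not None and lab in level:
                levels.append(level[lab])
                continue
            col = values[:, j]
            col = col[~np.isnan(col)]
            is_int = col.size > 0 and np.all(col == np.round(col))
            if is_int and np.unique(col).size <= ORDINAL_MAX_LEVELS:
                levels.append("ordinal")
            else:
                levels.append("continuous")
        return cls(values, labels, levels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.labels)


def read_table(path, level: dict[str, str] | None = None) -> OrdinalDataset:
    """Read a CSV/TSV file (header row of variable names; empty cells or
    "NA" are missing) into an :class:`OrdinalDataset`."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep, na_values=["NA"])
    return OrdinalDataset.from_frame(frame, level=level)


@dataclass
class CorrelationEstimate:
    """A p x p correlation matrix plus the marginal threshold estimates
    and the sample size that produced it."""

    matrix: np.ndarray
    thresholds: dict[str, np.ndarray] = field(default_factory=dict)
    n: int = 0
    method: str = "pearson"
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if self.labels is None:
            self.labels = [f"V{i + 1}" for i in range(self.matrix.shape[0])]

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(path)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------


def estimate_thresholds(column: np.ndarray) -> np.ndarray:
    """Marginal category thresholds of an ordinal score vector.

    Threshold k is the standard-normal quantile of the cumulative
    proportion of categories <= k; a column with K observed categories
    yields K - 1 strictly increasing finite values.  Thresholds depend
    only on category ranks, so any strictly monotone relabeling of the
    scores leaves them unchanged.
    """
    col = np.asarray(column, dtype=float)
    col = col[~np.isnan(col)]
    cats, counts = np.unique(col, return_counts=True)
    if cats.size < 2:
        raise DegenerateVariableError(
            "degenerate variable: fewer than 2 observed categories"
        )
    cum = np.cumsum(counts)[:-1] / col.size
    return special.ndtri(cum)


def _codes_and_thresholds(column: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Integer category codes (missing = -1), thresholds, category count."""
    col = np.asarray(column, dtype=float)
    mask = ~np.isnan(col)
    cats = np.unique(col[mask])
    codes = np.full(col.shape, -1, dtype=np.int64)
    codes[mask] = np.searchsorted(cats, col[mask])
    return codes, estimate_thresholds(col), cats.size


# ---------------------------------------------------------------------------
# positive-definiteness repair
# ---------------------------------------------------------------------------


def nearest_pd(matrix: np.ndarray, pd_floor: float = PD_FLOOR) -> np.ndarray:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``pd_floor`` and the result rescaled to a
    unit diagonal, iterating until the smallest eigenvalue respects the
    floor (rescaling can shrink it slightly).  A matrix that already
    satisfies the floor is returned unchanged.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("nearest_pd requires a symmetric square matrix")
    m = (m + m.T) / 2.0
    for _ in range(200):
        vals = np.linalg.eigvalsh(m)
        if vals[0] >= pd_floor:
            return m
        vals, vecs = np.linalg.eigh(m)
        vals = np.clip(vals, pd_floor, None)
        m = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(m))
        m = m / np.outer(d, d)
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 1.0)
    raise ConvergenceError("positive-definite repair did not converge")


# ---------------------------------------------------------------------------
# polyserial (ordinal x continuous)
# ---------------------------------------------------------------------------


def _polyserial_rho(z: np.ndarray, codes: np.ndarray, thr: np.ndarray) -> float:
    """Two-step ML polyserial correlation: continuous margin standardized,
    ordinal thresholds fixed, conditional ordinal likelihood maximized."""
    edges = np.concatenate(([-np.inf], thr, [np.inf]))
    lo = edges[codes]
    hi = edges[codes + 1]

    def negll(rho: float) -> float:
        s = np.sqrt(1.0 - rho * rho)
        pr = stats.norm.cdf((hi - rho * z) / s) - stats.norm.cdf((lo - rho * z) / s)
        return -np.sum(np.log(np.clip(pr, 1e-300, None)))

    res = optimize.minimize_scalar(
        negll, bounds=(-RHO_MAX, RHO_MAX), method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise ConvergenceError("polyserial likelihood optimization failed")
    return float(res.x)


# ---------------------------------------------------------------------------
# the full matrix
# ---------------------------------------------------------------------------


def polychoric_matrix(
    data: OrdinalDataset,
    continuity: bool = True,
    rho_max: float = RHO_MAX,
    pd_floor: float = PD_FLOOR,
    missing: str = "pairwise",
) -> CorrelationEstimate:
    """Correlation matrix of a mixed ordinal/continuous dataset.

    Ordinal-ordinal pairs get two-step polychoric correlations (thresholds
    fixed at their marginal estimates, latent rho maximizing the
    bivariate-normal contingency-table likelihood); continuous pairs the
    product-moment correlation; mixed pairs the two-step polyserial.
    The assembled matrix is passed through :func:`nearest_pd`.

    Parameters
    ----------
    continuity : bool
        Add 0.5 to every cell of a contingency table containing a zero
        before evaluating the likelihood (prevents boundary estimates).
    missing : {"pairwise", "listwise"}
        Pairwise-complete observations (default) or listwise deletion.
    """
    if missing == "listwise":
        keep = ~np.isnan(data.values).any(axis=1)
        if keep.sum() < 3:
            raise ValueError("fewer than 3 complete cases after listwise deletion")
        data = data.resample_rows(np.where(keep)[0])
    elif missing != "pairwise":
        raise ValueError("missing must be 'pairwise' or 'listwise'")

    p = data.p
    ord_idx = [j for j in range(p) if data.level[j] == "ordinal"]
    con_idx = [j for j in range(p) if data.level[j] == "continuous"]

    matrix = np.eye(p)
    thresholds: dict[str, np.ndarray] = {}

    codes: dict[int, np.ndarray] = {}
    thr: dict[int, np.ndarray] = {}
    ncat: dict[int, int] = {}
    for j in ord_idx:
        try:
            codes[j], thr[j], ncat[j] = _codes_and_thresholds(data.values[:, j])
        except DegenerateVariableError as exc:
            raise DegenerateVariableError(
                f"degenerate variable {data.labels[j]!r}: {exc}"
            ) from exc
        thresholds[data.labels[j]] = thr[j]

    # ordinal-ordinal block in one compiled pass
    if len(ord_idx) >= 2:
        k = len(ord_idx)
        maxk = max(ncat[j] for j in ord_idx)
        code_mat = np.stack([codes[j] for j in ord_idx], axis=1)
        ncat_vec = np.array([ncat[j] for j in ord_idx], dtype=np.int64)
        thr_mat = np.full((k, max(maxk - 1, 1)), np.nan)
        for a, j in enumerate(ord_idx):
            thr_mat[a, : ncat[j] - 1] = thr[j]
        block = _fast.polychoric_pairs(
            code_mat, ncat_vec, thr_mat, rho_max, continuity, _fast._GL_X, _fast._GL_W
        )
        if not np.all(np.isfinite(block)):
            bad = np.argwhere(~np.isfinite(np.triu(block, 1)))
            a, b = bad[0]
            raise ConvergenceError(
                "polychoric estimation failed for pair "
                f"({data.labels[ord_idx[a]]!r}, {data.labels[ord_idx[b]]!r})"
            )
        for a, ja in enumerate(ord_idx):
            for b in range(a + 1, k):
                jb = ord_idx[b]
                matrix[ja, jb] = matrix[jb, ja] = block[a, b]

    # continuous-continuous: pairwise-complete product-moment
    for a_i, ja in enumerate(con_idx):
        for jb in con_idx[a_i + 1 :]:
            x = data.values[:, ja]
            y = data.values[:, jb]
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 3:
                raise ValueError(
                    f"too few complete cases for pair ({data.labels[ja]!r}, {data.labels[jb]!r})"
                )
            r = np.corrcoef(x[ok], y[ok])[0, 1]
            matrix[ja, jb] = matrix[jb, ja] = float(np.clip(r, -rho_max, rho_max))

    # mixed: polyserial
    for ja in con_idx:
        for jb in ord_idx:
            x = data.values[:, ja]
            ok = ~np.isnan(x) & (codes[jb] >= 0)
            z = (x[ok] - np.mean(x[ok])) / np.std(x[ok])
            r = _polyserial_rho(z, codes[jb][ok], thr[jb])
            matrix[ja, jb] = matrix[jb, ja] = float(np.clip(r, -rho_max, rho_max))

    matrix = np.clip(matrix, -rho_max, rho_max)
    np.fill_diagonal(matrix, 1.0)
    matrix = nearest_pd(matrix, pd_floor=pd_floor)

    if not ord_idx:
        method = "pearson"
    elif not con_idx:
        method = "polychoric"
    else:
        method = "mixed"
    # effective n: average pairwise-complete count (equals n without missings)
    present = ~np.isnan(data.values)
    pair_n = present.astype(float).T @ present.astype(float)
    n_eff = int(round(pair_n[np.triu_indices(p, 1)].mean())) if p > 1 else data.n
    return CorrelationEstimate(
        matrix=matrix, thresholds=thresholds, n=n_eff, method=method, labels=list(data.labels)
    )
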