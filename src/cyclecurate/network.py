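"""Correlation networks with a permutation-calibrated edge threshold.

The workflow mirrors standard correlation-network practice: compute the full
Pearson correlation matrix over features, build an empirical null by
independently permuting each of a random subset of features across samples
(per-feature permutation preserves every feature's marginal distribution
while destroying co-variation), choose the smallest grid threshold that both
clears the null's upper quantile and keeps a floor fraction of features in
the graph, and admit an edge wherever r >= threshold (inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from cyclecurate.preprocess import ExpressionMatrix

__all__ = [
    "CorrelationResult",
    "NullDistribution",
    "ThresholdSelection",
    "WeightedGraph",
    "pairwise_correlation",
    "permutation_null",
    "select_threshold",
    "build_graph",
    "sample_graph",
]

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.30, 0.995, 0.01), 2))

# Features whose SD falls at or below this are treated as constant: a
# correlation computed from pure rounding residue is meaningless.
CONSTANT_SD_TOL = 1e-10


@dataclass
class CorrelationResult:
    """All-pairs Pearson correlations among non-constant features."""

    feature_ids: list[str]
    matrix: np.ndarray  # symmetric, unit diagonal
    n_samples: int
    constant_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.feature_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("correlation matrix shape does not match feature ids")

    def r(self, a: str, b: str) -> float:
        ia = self.feature_ids.index(a)
        ib = self.feature_ids.index(b)
        return float(self.matrix[ia, ib])

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.feature_ids), k=1)
        return self.matrix[iu]


def pairwise_correlation(matrix: ExpressionMatrix) -> CorrelationResult:
    """Pearson correlation between every pair of feature profiles.

    Constant features (zero variance across samples) have no defined
    correlation; they are excluded from the result and reported, with a
    warning, rather than propagated as NaN.  Requires at least 3 samples.
    """
    if matrix.n_samples < 3:
        raise ValueError(
            f"need >= 3 samples for correlation, got {matrix.n_samples}"
        )
    X = matrix.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > CONSTANT_SD_TOL
    constant = [str(f) for f, k in zip(matrix.feature_ids, keep) if not k]
    ids = [str(f) for f, k in zip(matrix.feature_ids, keep) if k]
    if constant:
        warnings.warn(
            f"excluding {len(constant)} constant feature(s) from correlation",
            stacklevel=2,
        )
    if len(ids) == 0:
        return CorrelationResult([], np.empty((0, 0)), matrix.n_samples, constant)
    R = np.corrcoef(X[keep])
    if R.ndim == 0:  # single feature
        R = np.ones((1, 1))
    R = np.clip(R, -1.0, 1.0)
    # snap rounding residue so exact affine relations give exactly |r| = 1
    R[np.abs(R - 1.0) < 1e-12] = 1.0
    R[np.abs(R + 1.0) < 1e-12] = -1.0
    np.fill_diagonal(R, 1.0)
    return CorrelationResult(ids, R, matrix.n_samples, constant)


@dataclass
class NullDistribution:
    """Sorted null correlations from per-feature sample permutation."""

    values: np.ndarray  # sorted ascending
    n_permuted_features: int
    seed: int

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.values, q))

    def exceedance(self, threshold: float) -> float:
        """Fraction of null correlations at or above ``threshold``."""
        idx = np.searchsorted(self.values, threshold, side="left")
        return float((self.values.size - idx) / self.values.size)

    def to_tsv(self, path: str | Path) -> None:
        pd.Series(self.values, name="null_r").to_csv(path, sep="\t", index=False)


def permutation_null(
    matrix: ExpressionMatrix, n_features: int = 2000, seed: int = 0
) -> NullDistribution:
    """Empirical null correlation distribution from permuted profiles.

    ``n_features`` features are drawn at random (all features, recorded, if
    the matrix holds fewer); each selected profile is independently permuted
    across samples and all pairwise correlations among the permuted profiles
    form the null.  Constant features are excluded first — permutation
    cannot make their correlation defined.
    """
    if n_features < 2:
        raise ValueError("n_features must be >= 2")
    rng = np.random.default_rng(seed)
    X = matrix.values.to_numpy(dtype=float)
    X = X[X.std(axis=1) > CONSTANT_SD_TOL]
    if X.shape[0] < 2:
        raise ValueError("need >= 2 non-constant features to build a null")
    n_take = min(n_features, X.shape[0])
    chosen = rng.choice(X.shape[0], size=n_take, replace=False)
    P = X[np.sort(chosen)].copy()
    for i in range(P.shape[0]):
        rng.shuffle(P[i])
    R = np.corrcoef(P)
    iu = np.triu_indices(n_take, k=1)
    values = np.sort(np.clip(R[iu], -1.0, 1.0))
    return NullDistribution(values, n_take, seed)


@dataclass
class ThresholdSelection:
    """A calibrated edge threshold with its retention diagnostics."""

    threshold: float
    null_quantile: float
    alpha: float
    node_floor: float
    meets_floor: bool
    diagnostics: pd.DataFrame  # columns: threshold, n_nodes, n_edges, node_fraction


def select_threshold(
    corr: CorrelationResult,
    null: NullDistribution,
    alpha: float = 1e-4,
    node_floor: float = 0.5,
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> ThresholdSelection:
    """Pick the lowest grid threshold that clears the null and keeps nodes.

    The selected value is the smallest grid threshold that (a) is at least
    the (1 - alpha) quantile of the permutation null and (b) keeps at least
    ``node_floor`` of the non-constant features connected to the graph.
    Edge counts fall monotonically along the grid, so this is also the
    admissible threshold with maximal node retention; if even that fails the
    floor, the same threshold is returned flagged ``meets_floor=False``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0.0 < node_floor <= 1.0:
        raise ValueError("node_floor must lie in (0, 1]")
    n = len(corr.feature_ids)
    if n == 0:
        raise ValueError("empty correlation set")

    q = null.quantile(1.0 - alpha)
    grid = sorted(float(g) for g in grid)
    R = corr.matrix.copy()
    np.fill_diagonal(R, -np.inf)
    best_partner = R.max(axis=1)  # node is retained iff best partner >= t

    rows = []
    iu = np.triu_indices(n, k=1)
    upper = corr.matrix[iu]
    for t in grid:
        n_nodes = int((best_partner >= t).sum())
        n_edges = int((upper >= t).sum())
        rows.append((t, n_nodes, n_edges, n_nodes / n))
    diagnostics = pd.DataFrame(
        rows, columns=["threshold", "n_nodes", "n_edges", "node_fraction"]
    )

    admissible = diagnostics[diagnostics["threshold"] >= q]
    if admissible.empty:
        raise ValueError(
            f"threshold grid (max {grid[-1]}) lies below the null quantile {q:.3f}"
        )
    ok = admissible[admissible["node_fraction"] >= node_floor]
    if not ok.empty:
        row = ok.iloc[0]
        meets = True
    else:
        row = admissible.loc[admissible["node_fraction"].idxmax()]
        meets = False
    return ThresholdSelection(
        float(row["threshold"]), q, alpha, node_floor, meets, diagnostics
    )


@dataclass
class WeightedGraph:
    """An undirected feature graph whose edges carry the admitting r.

    Only features participating in at least one edge are nodes; isolated
    features are dropped (node counts refer to graphed features).
    """

    graph: nx.Graph
    threshold: float

    def __post_init__(self) -> None:
        if any(self.graph.has_edge(v, v) for v in self.graph.nodes):
            raise ValueError("self-loops are not allowed")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def to_edgelist_tsv(self, path: str | Path) -> None:
        rows = sorted(
            (min(a, b), max(a, b), float(d["weight"]))
            for a, b, d in self.graph.edges(data=True)
        )
        pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_edgelist_tsv(cls, path: str | Path, threshold: float) -> "WeightedGraph":
        df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
        g = nx.Graph()
        for a, b, w in df.itertuples(index=False):
            g.add_edge(a, b, weight=float(w))
        return cls(g, threshold)

    def to_gml(self, path: str | Path) -> None:
        nx.write_gml(self.graph, str(path))


def build_graph(corr: CorrelationResult, threshold: float) -> WeightedGraph:
    """Admit an edge for every pair with r >= threshold (inclusive)."""
    if not -1.0 < threshold:
        raise ValueError("threshold must exceed -1")
    g = nx.Graph()
    R = corr.matrix
    ids = corr.feature_ids
    ii, jj = np.where(np.triu(R >= threshold, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(ids[i], ids[j], weight=float(R[i, j]))
    return WeightedGraph(g, float(threshold))


def sample_graph(matrix: ExpressionMatrix, threshold: float) -> WeightedGraph:
    """Sample-to-sample correlation graph (the transposed analysis)."""
    transposed = ExpressionMatrix(matrix.values.T)
    corr = pairwise_correlation(transposed)
    return build_graph(corr, threshold)
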