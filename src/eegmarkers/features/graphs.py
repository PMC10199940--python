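"""Time-series-to-network maps: quantile graphs and visibility graphs.

Quantile graph (QG)
    The series is coarse-grained into ``Q`` empirical quantile bins;
    each bin is a node, and a directed edge ``i -> j`` is weighted by
    the number of times a sample in bin ``i`` at time ``t`` is followed
    by a sample in bin ``j`` at time ``t + k``. Row-normalising the
    weighted adjacency ``A_k`` gives the Markov transition matrix
    ``W_k``. The network is summarised by the mean jump length

        Delta_k = (1/Q) * sum_ij W_k[i, j] * |i - j|,

    which is large for fast, erratic series and small for slow ones.

Visibility graph (VG)
    Each sample is a node; two samples are connected when the straight
    chord between them clears every intermediate sample (strict
    inequality). The graph always contains the path through adjacent
    samples, and a convex series yields the complete graph. The largest
    adjacency eigenvalue lambda_max, normalised between the path-graph
    minimum 2*cos(pi/(N+1)) and the complete-graph maximum N-1, gives

        c = (lambda_max - 2 cos(pi/(N+1))) / (N - 1 - 2 cos(pi/(N+1)))
        I = 4 c (1 - c)   in [0, 1],

    which vanishes at both extremes (perfectly regular and fully
    connected) and peaks for intermediate structural complexity.

Both constructions depend only on ranks / order geometry, so they are
invariant under shifting and positive scaling of the series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh

__all__ = [
    "TransitionGraph", "VisibilityAdjacency",
    "build_quantile_graph", "mean_jump_length", "default_quantile_count",
    "build_visibility_graph", "complexity_index",
]

_DENSE_EIG_LIMIT = 300  # use exact dense eigensolver below this size


@dataclass
class TransitionGraph:
    """Weighted directed quantile-transition network at lag ``k``."""

    Q: int
    k: int
    counts: np.ndarray      # A_k, (Q, Q) nonnegative integers
    transition: np.ndarray  # W_k, rows sum to 1 where counts row nonzero

    @property
    def jump_cost(self) -> np.ndarray:
        """Matrix P with entries |i - j|."""
        idx = np.arange(self.Q)
        return np.abs(idx[:, None] - idx[None, :]).astype(float)


def default_quantile_count(T: int) -> int:
    """Study rule of thumb Q = 2 * T**(1/3), rounded (20 at T = 1,024)."""
    return int(round(2.0 * T ** (1.0 / 3.0)))


def quantile_bins(series: np.ndarray, Q: int) -> np.ndarray:
    """Empirical quantile bin of each sample (0..Q-1).

    Bins are left-closed/right-open with the top bin closed; a value
    equal to an internal boundary belongs to the upper bin. Heavily
    tied series collapse deterministically onto fewer bins (a constant
    series occupies a single bin).
    """
    x = np.asarray(series, dtype=float)
    if Q < 2:
        raise ValueError("Q must be >= 2")
    boundaries = np.quantile(x, np.arange(1, Q) / Q)
    return np.searchsorted(boundaries, x, side="right")


def build_quantile_graph(series: np.ndarray, Q: int, k: int = 1) -> TransitionGraph:
    """Quantile-transition network of a series at lag ``k``."""
    x = np.asarray(series, dtype=float)
    T = len(x)
    if not 1 <= k < T:
        raise ValueError("lag k must satisfy 1 <= k < T")
    bins = quantile_bins(x, Q)
    counts = np.zeros((Q, Q), dtype=np.int64)
    np.add.at(counts, (bins[:-k], bins[k:]), 1)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        transition = np.where(row_sums > 0, counts / row_sums, 0.0)
    return TransitionGraph(Q=Q, k=k, counts=counts, transition=transition)


def mean_jump_length(graph: TransitionGraph) -> float:
    """Mean jump length Delta_k = (1/Q) tr(W_k P^T) of a quantile graph."""
    return float(np.sum(graph.transition * graph.jump_cost) / graph.Q)


@dataclass
class VisibilityAdjacency:
    """Symmetric 0/1 adjacency of a natural visibility graph."""

    n: int
    adjacency: sp.csr_matrix  # int8, symmetric, zero diagonal

    def to_dense(self) -> np.ndarray:
        return self.adjacency.toarray().astype(int)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)


def build_visibility_graph(series: np.ndarray) -> VisibilityAdjacency:
    """Natural visibility graph of a series.

    Nodes ``i < j`` are connected when every intermediate sample lies
    strictly below the chord between (i, x_i) and (j, x_j); adjacent
    samples are always connected. O(T^2) via a running slope maximum.
    """
    x = np.asarray(series, dtype=float)
    T = len(x)
    if T < 2:
        raise ValueError("series must have at least 2 samples")
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for i in range(T - 1):
        slopes = (x[i + 1:] - x[i]) / np.arange(1, T - i)
        visible = np.empty(T - i - 1, dtype=bool)
        visible[0] = True  # adjacent sample: no intermediates
        if len(slopes) > 1:
            running_max = np.maximum.accumulate(slopes)
            visible[1:] = slopes[1:] > running_max[:-1]
        js = i + 1 + np.flatnonzero(visible)
        rows.append(np.full(len(js), i, dtype=np.int64))
        cols.append(js)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    data = np.ones(len(r), dtype=np.int8)
    upper = sp.coo_matrix((data, (r, c)), shape=(T, T))
    adj = (upper + upper.T).tocsr()
    return VisibilityAdjacency(n=T, adjacency=adj)


def _largest_eigenvalue(adj: VisibilityAdjacency) -> float:
    A = adj.adjacency.astype(float)
    if adj.n <= _DENSE_EIG_LIMIT:
        return float(np.linalg.eigvalsh(A.toarray())[-1])
    v0 = np.ones(adj.n)
    vals = eigsh(A, k=1, which="LA", v0=v0, tol=1e-10,
                 return_eigenvectors=False)
    return float(vals[0])


def complexity_index(adj: VisibilityAdjacency) -> float:
    """Complexity index I = 4c(1-c) from the largest VG eigenvalue."""
    N = adj.n
    if N < 3:
        raise ValueError("complexity index needs at least 3 nodes")
    lam = _largest_eigenvalue(adj)
    lo = 2.0 * np.cos(np.pi / (N + 1))
    hi = float(N - 1)
    c = (lam - lo) / (hi - lo)
    c = min(max(c, 0.0), 1.0)  # guard tiny eigensolver round-off
    return float(4.0 * c * (1.0 - c))
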