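"""Multiscale cell-cell interaction graphs and their persistent Laplacians.

Spots are points in gene-expression space. A kNN graph at neighbor count k is
OR-symmetrized (an edge exists if either endpoint is among the other's k
nearest neighbors), which keeps every Laplacian symmetric positive
semi-definite with zero row sums. Decreasing k induces a nested filtration of
subgraphs; the unweighted Laplacian of each scale is a persistent Laplacian
L_k, and the zeta-weighted sum of the sequence is the accumulated spectral
graph L_P fed to topological PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

from .data_io import ExpressionMatrix

__all__ = [
    "CellGraph",
    "LaplacianFiltration",
    "knn_adjacency",
    "gaussian_weights",
    "graph_laplacian",
    "filtration_laplacian",
    "build_filtration",
    "accumulate",
    "count_components",
]

DEFAULT_SCALES = (15, 12, 9, 6)
COMPONENT_TOL = 1e-8


def _points(x: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Spots-as-rows array from either container or raw (N, features)."""
    if isinstance(x, ExpressionMatrix):
        return x.spots()
    return np.asarray(x, dtype=float)


def _pairwise(points: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        d = cdist(points, points)
    elif metric == "correlation":
        # correlation distance; constant rows give NaN -> treat as max distance
        d = cdist(points, points, metric="correlation")
        d = np.nan_to_num(d, nan=2.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class CellGraph:
    """Gaussian-weighted cell-cell interaction graph.

    ``adjacency`` is the symmetric weight matrix W with zero diagonal and
    entries in [0, 1]; ``k`` and ``eta`` record the neighbor count and kernel
    bandwidth used to build it.
    """

    adjacency: np.ndarray
    k: int
    eta: float
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        w = np.asarray(self.adjacency, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(w, w.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if w.min() < 0 or w.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        self.adjacency = w


@dataclass
class LaplacianFiltration:
    """Ordered persistent Laplacians over kNN scales with zeta weights."""

    scales: list[int]
    laplacians: list[np.ndarray]
    zeta: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.scales) != len(self.laplacians):
            raise ValueError("one Laplacian per scale required")
        if any(a <= b for a, b in zip(self.scales, self.scales[1:])):
            raise ValueError("scales must be strictly decreasing")

    @property
    def p(self) -> int:
        return len(self.scales)

    def accumulated(self, zeta: np.ndarray | None = None) -> np.ndarray:
        z = self.zeta if zeta is None else zeta
        if z is None:
            z = np.ones(self.p)
        return accumulate(self, np.asarray(z, dtype=float))


def knn_adjacency(
    x: ExpressionMatrix | np.ndarray, k: int, metric: str = "euclidean"
) -> np.ndarray:
    """Binary OR-symmetrized kNN adjacency; ties broken by ascending index.

    Entry (i, j) is 1 iff i is among j's k nearest neighbors or vice versa;
    the diagonal is zero. Duplicate points are allowed, with the stable
    (distance, index) ordering resolving ties deterministically.
    """
    pts = _points(x)
    n = pts.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} out of range for N={n}")
    d = _pairwise(pts, metric)
    a = np.zeros((n, n), dtype=int)
    idx = np.arange(n)
    for j in range(n):
        order = np.argsort(d[j], kind="stable")  # stable: ties by index
        neigh = order[order != j][:k]
        a[neigh, j] = 1
    a = np.maximum(a, a.T)  # OR rule
    np.fill_diagonal(a, 0)
    return a


def gaussian_weights(
    x: ExpressionMatrix | np.ndarray,
    adjacency: np.ndarray,
    eta: float | None = None,
    metric: str = "euclidean",
    k: int = 0,
) -> CellGraph:
    """Gaussian kernel weights W_ij = exp(-||x_i - x_j||^2 / eta) on edges.

    With ``eta`` unset, the bandwidth is the median of squared edge distances
    (median heuristic); if every edge distance is zero the bandwidth falls
    back to 1, which still yields weight 1 on each edge.
    """
    pts = _points(x)
    a = np.asarray(adjacency)
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    d2 = _pairwise(pts, metric) ** 2
    edge_mask = a > 0
    if eta is None:
        ed = d2[np.triu(edge_mask, 1)]
        eta = float(np.median(ed)) if ed.size else 1.0
        if eta <= 0:
            eta = 1.0
    if eta <= 0:
        raise ValueError("eta must be positive")
    w = np.where(edge_mask, np.exp(-d2 / eta), 0.0)
    np.fill_diagonal(w, 0.0)
    return CellGraph(adjacency=w, k=k, eta=eta, metric=metric)


def graph_laplacian(g: CellGraph | np.ndarray) -> np.ndarray:
    """Weighted graph Laplacian L = D - W with D the diagonal of row sums."""
    w = g.adjacency if isinstance(g, CellGraph) else np.asarray(g, dtype=float)
    return np.diag(w.sum(axis=1)) - w


def filtration_laplacian(
    x: ExpressionMatrix | np.ndarray, k: int, metric: str = "euclidean"
) -> np.ndarray:
    """Unweighted persistent Laplacian of the kNN graph at scale k.

    Off-diagonal entries are -1 on edges of the OR-symmetrized kNN graph and 0
    otherwise; the diagonal holds the vertex degree so every row sums to zero.
    """
    a = knn_adjacency(x, k, metric=metric)
    return graph_laplacian(a.astype(float))


def build_filtration(
    x: ExpressionMatrix | np.ndarray,
    scales: tuple[int, ...] | list[int] = DEFAULT_SCALES,
    metric: str = "euclidean",
    weighted: bool = False,
    eta: float | None = None,
) -> LaplacianFiltration:
    """Persistent Laplacians at each kNN scale (largest first).

    ``weighted=True`` swaps in the Gaussian-kernel weighted Laplacian at each
    scale; the default is the unweighted form consumed by the accumulated
    spectral graph.
    """
    scales = sorted(set(int(s) for s in scales), reverse=True)
    laps = []
    for k in scales:
        if weighted:
            a = knn_adjacency(x, k, metric=metric)
            g = gaussian_weights(x, a, eta=eta, metric=metric, k=k)
            laps.append(graph_laplacian(g))
        else:
            laps.append(filtration_laplacian(x, k, metric=metric))
    return LaplacianFiltration(scales=list(scales), laplacians=laps)


def accumulate(filtration: LaplacianFiltration, zeta: np.ndarray) -> np.ndarray:
    """Accumulated spectral graph L_P = sum_k zeta_k L_k."""
    z = np.asarray(zeta, dtype=float)
    if z.shape != (filtration.p,):
        raise ValueError(
            f"zeta length {z.shape} does not match p={filtration.p} scales"
        )
    if np.any(z < 0):
        raise ValueError("zeta weights must be non-negative")
    lp = np.zeros_like(filtration.laplacians[0])
    for zk, lk in zip(z, filtration.laplacians):
        lp = lp + zk * lk
    return lp


def count_components(l: np.ndarray, tol: float = COMPONENT_TOL) -> int:
    """Connected components as the zero-eigenvalue multiplicity (Betti-0).

    Counts eigenvalues below ``tol * lambda_max`` (lambda_max of an empty
    graph treated as 1). For a valid graph Laplacian this equals the number
    of connected components.
    """
    l = np.asarray(l, dtype=float)
    if not np.allclose(l, l.T, atol=1e-10):
        raise ValueError("Laplacian must be symmetric")
    ev = scipy.linalg.eigvalsh(l)
    lam_max = ev[-1] if ev[-1] > 0 else 1.0
    return int(np.sum(ev < tol * lam_max))
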