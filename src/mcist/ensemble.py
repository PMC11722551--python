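"""Ensemble consensus clustering over zeta-combinations.

Each combination of filtration scales yields one concatenated feature matrix
(topological PCA block + spatial block); each is clustered with either a
full-covariance Gaussian mixture (the model-based-clustering role, with the
cluster count fixed to the annotation count) or Leiden community detection
with its resolution tuned to the requested cluster count. The co-association
matrix records how often each pair of spots lands in the same cluster across
the ensemble; average-linkage agglomerative clustering of 1 - C at the
requested count gives the consensus spatial domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.mixture import GaussianMixture

from .data_io import LabelVector
from .spatial import SpatialEmbedding

__all__ = [
    "ZetaCombination",
    "EnsembleResult",
    "enumerate_combinations",
    "concat_features",
    "cluster_features",
    "coassociation",
    "consensus_cluster",
    "nmi",
    "ari",
]


@dataclass
class ZetaCombination:
    """Binary on/off weights over the filtration scales; largest scale on."""

    zeta: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.zeta, dtype=float)
        if z.ndim != 1 or not np.all(np.isin(z, (0.0, 1.0))):
            raise ValueError("zeta must be a binary vector")
        if z[0] != 1:
            raise ValueError("the largest scale must be on (zeta[0] = 1)")
        self.zeta = z


@dataclass
class EnsembleResult:
    """Per-combination labelings, co-association matrix, consensus labels."""

    combo_labels: list[LabelVector]
    coassoc: np.ndarray
    consensus: LabelVector
    n_clusters: int


def enumerate_combinations(p: int) -> list[ZetaCombination]:
    """All 2^(p-1) binary zeta vectors with the first (largest) scale on.

    Lexicographic order; with the default four scales this gives the eight
    connectivity combinations of the ensemble.
    """
    if p < 1:
        raise ValueError("need at least one scale")
    combos = []
    for bits in range(2 ** (p - 1)):
        tail = [(bits >> (p - 2 - i)) & 1 for i in range(p - 1)]
        combos.append(ZetaCombination(np.array([1] + tail, dtype=float)))
    return combos


def concat_features(
    q: np.ndarray,
    z: SpatialEmbedding | np.ndarray,
    scale_blocks: bool = True,
) -> np.ndarray:
    """Concatenate an expression-space embedding with a spatial embedding.

    With ``scale_blocks`` (default) each block is column-wise z-scored and
    zero-variance columns are dropped, so neither block dominates by scale.
    """
    q = np.asarray(q, dtype=float)
    zmat = z.z if isinstance(z, SpatialEmbedding) else np.asarray(z, dtype=float)
    if q.shape[0] != zmat.shape[0]:
        raise ValueError(f"row mismatch: {q.shape[0]} vs {zmat.shape[0]}")
    blocks = []
    for block in (q, zmat):
        if scale_blocks:
            mu = block.mean(axis=0)
            sd = block.std(axis=0)
            keep = sd > 1e-12
            block = (block[:, keep] - mu[keep]) / sd[keep]
        blocks.append(block)
    return np.hstack(blocks)


def cluster_features(
    f: np.ndarray,
    n_clusters: int,
    method: str = "gaussian_mixture",
    seed: int = 0,
) -> LabelVector:
    """Cluster a feature matrix into exactly ``n_clusters`` groups.

    ``gaussian_mixture`` fits a full-covariance mixture with the component
    count fixed (5 restarts, best likelihood kept). ``leiden_graph`` builds a
    kNN graph of the features and bisects the Leiden resolution until the
    community count matches (at most 30 iterations, nearest achieved
    otherwise). Both are seeded and reproducible.
    """
    f = np.asarray(f, dtype=float)
    n = f.shape[0]
    if n_clusters < 1 or n_clusters > n:
        raise ValueError(f"cannot form {n_clusters} clusters from {n} spots")
    if method == "gaussian_mixture":
        if n_clusters == n:
            return LabelVector(np.arange(n))
        gm = GaussianMixture(
            n_components=n_clusters,
            covariance_type="full",
            n_init=5,
            random_state=seed,
            reg_covar=1e-4,
        )
        return LabelVector(gm.fit_predict(f))
    if method == "leiden_graph":
        return _leiden_fixed_k(f, n_clusters, seed)
    raise ValueError(f"unknown clustering method {method!r}")


def _leiden_fixed_k(f: np.ndarray, n_clusters: int, seed: int) -> LabelVector:
    import igraph
    import leidenalg

    from .graphs import knn_adjacency

    n = f.shape[0]
    k = min(15, n - 1)
    a = knn_adjacency(f, k)
    edges = np.argwhere(np.triu(a, 1) > 0)
    g = igraph.Graph(n=n, edges=[tuple(e) for e in edges])

    def run(res: float) -> np.ndarray:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=res,
            seed=seed,
            n_iterations=-1,  # iterate to convergence
        )
        return np.asarray(part.membership)

    lo, hi = 1e-4, 50.0
    best, best_gap = run(1.0), None
    best_gap = abs(len(np.unique(best)) - n_clusters)
    if best_gap == 0:
        return LabelVector(best)
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        lab = run(mid)
        nc = len(np.unique(lab))
        gap = abs(nc - n_clusters)
        if gap < best_gap:
            best, best_gap = lab, gap
        if nc == n_clusters:
            return LabelVector(lab)
        if nc < n_clusters:
            lo = mid
        else:
            hi = mid
    return LabelVector(best)  # nearest achieved count


def coassociation(labelings: list[LabelVector | np.ndarray]) -> np.ndarray:
    """Co-association matrix: fraction of labelings pairing spots together."""
    if not labelings:
        raise ValueError("need at least one labeling")
    arrs = [
        lab.labels if isinstance(lab, LabelVector) else np.asarray(lab)
        for lab in labelings
    ]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("labelings differ in length")
    c = np.zeros((n, n))
    for a in arrs:
        c += (a[:, None] == a[None, :]).astype(float)
    c /= len(arrs)
    np.fill_diagonal(c, 1.0)
    return c


def consensus_cluster(coassoc: np.ndarray, n_clusters: int) -> LabelVector:
    """Average-linkage agglomerative clustering of 1 - C cut at n_clusters."""
    c = np.asarray(coassoc, dtype=float)
    n = c.shape[0]
    if n_clusters > n:
        raise ValueError(f"cannot cut {n} spots into {n_clusters} clusters")
    dist = 1.0 - c
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    model = AgglomerativeClustering(
        n_clusters=n_clusters, metric="precomputed", linkage="average"
    )
    return LabelVector(model.fit_predict(dist))


def _as_array(lab: LabelVector | np.ndarray) -> np.ndarray:
    return lab.labels if isinstance(lab, LabelVector) else np.asarray(lab)


def nmi(a: LabelVector | np.ndarray, b: LabelVector | np.ndarray) -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    a, b = _as_array(a), _as_array(b)
    if len(a) != len(b):
        raise ValueError("labelings differ in length")
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def ari(a: LabelVector | np.ndarray, b: LabelVector | np.ndarray) -> float:
    """Adjusted Rand index via the pair-counting closed form."""
    a, b = _as_array(a), _as_array(b)
    if len(a) != len(b):
        raise ValueError("labelings differ in length")
    return float(adjusted_rand_score(a, b))
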