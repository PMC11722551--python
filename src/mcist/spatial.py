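"""Spatial representations paired with the expression-space embeddings.

Deep spatial encoders (graph attention autoencoders, deep graph infomax,
contrastive graph learning) are consumed as precomputed embedding files. For
a self-contained pipeline a spatially-smoothed PCA baseline is provided: the
expression profile of each spot is blended with the average of its spatial
kNN neighbors, then reduced with ordinary PCA over spots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data_io import ExpressionMatrix, SpatialCoords

logger = logging.getLogger("mcist")

__all__ = ["SpatialEmbedding", "load_embedding", "spatial_knn", "smoothed_pca_embedding"]


@dataclass
class SpatialEmbedding:
    """N x d latent representation of spots, row-aligned to barcodes."""

    z: np.ndarray
    source: str = "external"  # "external" | "smoothed_pca"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("embedding must be 2-D")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("embedding contains NaN/Inf")

    @property
    def d(self) -> int:
        return self.z.shape[1]


def load_embedding(path: str, barcodes: list[str]) -> SpatialEmbedding:
    """Load an embedding CSV and align rows to ``barcodes``.

    If the first column is non-numeric it is treated as a barcode column and
    rows are realigned; otherwise the file is accepted positionally when the
    row count matches N (with a logged warning).
    """
    df = pd.read_csv(path)
    first = df.iloc[:, 0]
    if first.dtype == object or str(df.columns[0]).lower() in ("barcode", "barcodes"):
        df = df.set_index(df.columns[0])
        df.index = df.index.astype(str)
        missing = [b for b in barcodes if b not in df.index]
        if missing:
            raise ValueError(f"embedding missing {len(missing)} barcodes")
        z = df.loc[barcodes].to_numpy(dtype=float)
    else:
        if len(df) != len(barcodes):
            raise ValueError(
                f"embedding has {len(df)} rows for {len(barcodes)} barcodes and "
                "no barcode column"
            )
        logger.warning("load_embedding: no barcode column, accepting rows positionally")
        z = df.to_numpy(dtype=float)
    return SpatialEmbedding(z, source="external")


def spatial_knn(coords: SpatialCoords | np.ndarray, k_sp: int) -> np.ndarray:
    """OR-symmetrized kNN adjacency on 2-D spot coordinates."""
    from .graphs import knn_adjacency

    xy = coords.xy if isinstance(coords, SpatialCoords) else np.asarray(coords, float)
    return knn_adjacency(xy, k_sp, metric="euclidean")


def smoothed_pca_embedding(
    x: ExpressionMatrix,
    coords: SpatialCoords,
    k_sp: int = 6,
    alpha: float = 0.5,
    d: int = 32,
) -> SpatialEmbedding:
    """Spatially-smoothed PCA baseline embedding.

    Each spot's profile becomes ``(1 - alpha) * x_j + alpha * mean(neighbor
    profiles)`` over the spatial kNN graph, followed by PCA over spots down
    to ``d`` components. ``alpha=0`` is plain PCA. Deterministic.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if d >= min(x.n_genes, x.n_spots):
        raise ValueError(f"d={d} too large for matrix {x.values.shape}")
    a = spatial_knn(coords, k_sp).astype(float)
    deg = a.sum(axis=1)
    a_rn = a / np.where(deg > 0, deg, 1.0)[:, None]  # row-normalized
    # column j of X @ a_rn.T is the mean profile of j's neighbors
    x_smooth = (1.0 - alpha) * x.values + alpha * (x.values @ a_rn.T)
    pca = PCA(n_components=d, svd_solver="full")
    z = pca.fit_transform(x_smooth.T)
    return SpatialEmbedding(z, source="smoothed_pca")
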