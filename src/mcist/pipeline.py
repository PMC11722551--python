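"""End-to-end orchestration of the multiscale ensemble pipeline.

One run: build the kNN filtration of the expression-space interaction graph
at the configured scales, enumerate the zeta on/off combinations (largest
scale always on), fit one topological PCA embedding per combination,
concatenate each with the spatial embedding, cluster every concatenation per
seed, pool all labelings into a co-association matrix, and cut its
average-linkage dendrogram at the requested domain count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, LabelVector, SpatialCoords
from .ensemble import (
    EnsembleResult,
    ari,
    cluster_features,
    coassociation,
    concat_features,
    consensus_cluster,
    enumerate_combinations,
    nmi,
)
from .graphs import DEFAULT_SCALES, build_filtration
from .rsi import select_by_rsi
from .spatial import SpatialEmbedding, smoothed_pca_embedding
from .tpca import TpcaConfig, embed_all_combinations

logger = logging.getLogger("mcist")

__all__ = ["RunConfig", "run_mcist", "run_mcist_multi", "run_rsi_mode", "evaluate"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``scales`` are the kNN filtration scales (strictly decreasing);
    ``seeds`` drive the per-combination clusterings — each combination is
    clustered once per seed and all labelings pool into one co-association
    matrix. ``n_clusters`` is the annotation count and is required.
    """

    n_clusters: int
    scales: tuple[int, ...] = DEFAULT_SCALES
    tpca: TpcaConfig = field(default_factory=TpcaConfig)
    method: str = "gaussian_mixture"  # or "leiden_graph"
    seeds: tuple[int, ...] = (0,)
    embedding_source: str = "smoothed_pca"  # or "external"
    k_sp: int = 6
    alpha: float = 0.5
    d: int = 32
    all_combos: bool = False
    rsi_mode: bool = False

    def __post_init__(self) -> None:
        if any(a <= b for a, b in zip(self.scales, self.scales[1:])):
            raise ValueError("scales must be strictly decreasing")
        if not self.seeds:
            raise ValueError("need at least one seed")


def _effective_scales(scales: tuple[int, ...], n: int) -> list[int]:
    kept = [k for k in scales if k <= n - 1]
    if len(kept) < len(scales):
        logger.warning(
            "pipeline: truncating scales %s to %s for N=%d", scales, kept, n
        )
    if not kept:
        raise ValueError(f"no valid scales for N={n}")
    return kept


def _combos(p: int, all_combos: bool) -> list[np.ndarray]:
    if all_combos:
        out = []
        for bits in range(1, 2**p):
            out.append(
                np.array([(bits >> (p - 1 - i)) & 1 for i in range(p)], dtype=float)
            )
        return out
    return [c.zeta for c in enumerate_combinations(p)]


def _prepare(
    x: ExpressionMatrix,
    coords: SpatialCoords,
    cfg: RunConfig,
    embedding: SpatialEmbedding | None,
) -> tuple[list[np.ndarray], SpatialEmbedding, list[np.ndarray]]:
    """Shared front half: embeddings per combination plus the spatial block."""
    if x.n_spots != coords.xy.shape[0]:
        raise ValueError("expression and coordinates are not aligned")
    scales = _effective_scales(cfg.scales, x.n_spots)
    logger.info(
        "pipeline: N=%d spots, M=%d genes, scales=%s", x.n_spots, x.n_genes, scales
    )
    filtration = build_filtration(x, scales)
    combos = _combos(len(scales), cfg.all_combos)
    tcfg = cfg.tpca
    if tcfg.m >= min(x.n_genes, x.n_spots):
        tcfg = TpcaConfig(
            m=min(x.n_genes, x.n_spots) - 1,
            beta=tcfg.beta,
            gamma=tcfg.gamma,
            max_iter=tcfg.max_iter,
            tol=tcfg.tol,
            seed=tcfg.seed,
            scale_frobenius=tcfg.scale_frobenius,
        )
    qs = embed_all_combinations(x, filtration, combos, tcfg)
    logger.info("pipeline: fitted %d tPCA embeddings (m=%d)", len(qs), tcfg.m)
    if embedding is None:
        d = min(cfg.d, min(x.n_genes, x.n_spots) - 1)
        embedding = smoothed_pca_embedding(x, coords, cfg.k_sp, cfg.alpha, d)
    return qs, embedding, combos


def run_mcist(
    x: ExpressionMatrix,
    coords: SpatialCoords,
    cfg: RunConfig,
    embedding: SpatialEmbedding | None = None,
) -> EnsembleResult:
    """Full ensemble run producing consensus spatial domains."""
    qs, embedding, _ = _prepare(x, coords, cfg, embedding)
    return _ensemble_from_embeddings(qs, embedding, cfg)


def _ensemble_from_embeddings(
    qs: list[np.ndarray],
    embedding: SpatialEmbedding,
    cfg: RunConfig,
    seeds: tuple[int, ...] | None = None,
) -> EnsembleResult:
    seeds = seeds if seeds is not None else cfg.seeds
    labelings: list[LabelVector] = []
    for q in qs:
        feats = concat_features(q, embedding)
        for seed in seeds:
            labelings.append(
                cluster_features(feats, cfg.n_clusters, cfg.method, seed)
            )
    c = coassociation(labelings)
    consensus = consensus_cluster(c, cfg.n_clusters)
    logger.info(
        "pipeline: consensus over %d labelings -> %d domains",
        len(labelings),
        consensus.n_clusters,
    )
    return EnsembleResult(
        combo_labels=labelings,
        coassoc=c,
        consensus=consensus,
        n_clusters=cfg.n_clusters,
    )


def run_mcist_multi(
    x: ExpressionMatrix,
    coords: SpatialCoords,
    cfg: RunConfig,
    embedding: SpatialEmbedding | None = None,
) -> list[EnsembleResult]:
    """Multi-seed protocol: one independent consensus per seed in cfg.seeds.

    The deterministic front half (filtration, tPCA embeddings, spatial
    embedding) is computed once and shared; only the clustering stage is
    re-seeded. Downstream metrics are then reported as mean +/- sd over the
    seed list.
    """
    qs, embedding, _ = _prepare(x, coords, cfg, embedding)
    return [
        _ensemble_from_embeddings(qs, embedding, cfg, seeds=(seed,))
        for seed in cfg.seeds
    ]


def run_rsi_mode(
    x: ExpressionMatrix,
    coords: SpatialCoords,
    cfg: RunConfig,
    embedding: SpatialEmbedding | None = None,
) -> tuple[np.ndarray, LabelVector]:
    """Single-embedding route: pick one tPCA embedding by RSI, cluster it.

    Each candidate is clustered alone (first seed of the list); the Residue-
    Similarity Index of each (embedding, labeling) pair selects the winner,
    whose labeling is returned alongside the embedding.
    """
    qs, _, _ = _prepare(x, coords, cfg, embedding)
    seed = cfg.seeds[0]
    labelings = [cluster_features(q, cfg.n_clusters, cfg.method, seed) for q in qs]
    idx = select_by_rsi(qs, labelings)
    logger.info("pipeline: RSI selected embedding %d of %d", idx, len(qs))
    return qs[idx], labelings[idx]


def evaluate(
    results: list[EnsembleResult] | list[LabelVector],
    truth: LabelVector | np.ndarray,
) -> dict:
    """NMI and ARI per seed plus mean and sd, as a JSON-ready record."""
    labels = [
        r.consensus if isinstance(r, EnsembleResult) else r for r in results
    ]
    tl = truth.labels if isinstance(truth, LabelVector) else np.asarray(truth)
    per_nmi = [nmi(lab, tl) for lab in labels]
    per_ari = [ari(lab, tl) for lab in labels]
    return {
        "nmi": per_nmi,
        "ari": per_ari,
        "nmi_mean": float(np.mean(per_nmi)),
        "nmi_sd": float(np.std(per_nmi)),
        "ari_mean": float(np.mean(per_ari)),
        "ari_sd": float(np.std(per_ari)),
        "n_runs": len(labels),
    }
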