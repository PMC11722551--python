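"""Downstream analysis of detected spatial domains.

Differential expression between two domains uses the two-sided Welch
(unequal-variance) t-test per gene with Welch-Satterthwaite degrees of
freedom, keeping genes at raw p <= alpha (no multiplicity correction by
default; Benjamini-Hochberg is available). The significant genes feed a gene
co-expression network — edges between gene pairs with |Pearson r| at or
above a threshold — whose largest connected component is the coherent
expression program reported for enrichment analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph
import scipy.stats

from .data_io import ExpressionMatrix, LabelVector

__all__ = ["DegResult", "CoexpressionNetwork", "deg_welch", "coexpression_lcc", "build_coexpression_network"]


@dataclass
class DegResult:
    """Genes differentially expressed between two domains (p <= alpha)."""

    genes: list[str]
    t_stats: np.ndarray
    p_values: np.ndarray
    direction: np.ndarray  # +1 if up in group_a, -1 if down


@dataclass
class CoexpressionNetwork:
    genes: list[str]
    edges: list[tuple[str, str, float]]
    threshold: float


def deg_welch(
    x: ExpressionMatrix,
    labels: LabelVector | np.ndarray,
    group_a: int,
    group_b: int,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> DegResult:
    """Per-gene Welch's t-test between two spot groups.

    Genes with zero variance in both groups are excluded (the statistic is
    undefined); the boundary is inclusive, p exactly equal to ``alpha`` is
    reported. ``bh_correct`` switches the cutoff to Benjamini-Hochberg
    adjusted p-values.
    """
    lab = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    if len(lab) != x.n_spots:
        raise ValueError("labels length does not match spot count")
    ma, mb = lab == group_a, lab == group_b
    if group_a not in lab or group_b not in lab:
        raise ValueError("unknown group label")
    if ma.sum() < 2 or mb.sum() < 2:
        raise ValueError("both groups need at least 2 spots")
    xa, xb = x.values[:, ma], x.values[:, mb]
    var_a, var_b = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    testable = (var_a > 0) | (var_b > 0)
    t = np.full(x.n_genes, np.nan)
    p = np.full(x.n_genes, np.nan)
    if testable.any():
        res = scipy.stats.ttest_ind(
            xa[testable], xb[testable], axis=1, equal_var=False
        )
        t[testable] = res.statistic
        p[testable] = res.pvalue
    pcrit = p.copy()
    if bh_correct:
        idx = np.where(testable)[0]
        pcrit[idx] = _bh_adjust(p[idx])
    sig = testable & (pcrit <= alpha)
    order = np.where(sig)[0]
    return DegResult(
        genes=[x.gene_ids[i] for i in order],
        t_stats=t[order],
        p_values=p[order],
        direction=np.sign(t[order]).astype(int),
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return adj


def build_coexpression_network(
    x: ExpressionMatrix,
    genes: list[str],
    threshold: float = 0.5,
    spot_mask: np.ndarray | None = None,
) -> CoexpressionNetwork:
    """Thresholded Pearson co-expression network over the selected genes.

    Constant genes have undefined correlation and stay isolated. ``spot_mask``
    optionally restricts the correlation to a subset of spots.
    """
    pos = {g: i for i, g in enumerate(x.gene_ids)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ValueError(f"unknown genes: {missing[:5]}")
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    sub = x.values[[pos[g] for g in genes]]
    if spot_mask is not None:
        sub = sub[:, np.asarray(spot_mask, bool)]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(sub)
    r = np.nan_to_num(r, nan=0.0)  # constant genes: no edges
    np.fill_diagonal(r, 0.0)
    edges = []
    k = len(genes)
    for i in range(k):
        for j in range(i + 1, k):
            if abs(r[i, j]) >= threshold:
                edges.append((genes[i], genes[j], float(r[i, j])))
    return CoexpressionNetwork(genes=list(genes), edges=edges, threshold=threshold)


def coexpression_lcc(
    x: ExpressionMatrix,
    genes: list[str],
    threshold: float = 0.5,
    spot_mask: np.ndarray | None = None,
) -> list[str]:
    """Largest connected component of the gene co-expression network.

    Singleton components are ignored; with no edges the list is empty. Size
    ties are broken by the lexicographically smallest sorted gene-id set.
    Returned genes are sorted.
    """
    net = build_coexpression_network(x, genes, threshold, spot_mask)
    if not net.edges:
        return []
    idx = {g: i for i, g in enumerate(net.genes)}
    k = len(net.genes)
    rows = [idx[a] for a, b, _ in net.edges]
    cols = [idx[b] for a, b, _ in net.edges]
    adj = scipy.sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(k, k)
    )
    n_comp, comp = scipy.sparse.csgraph.connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for g, c in zip(net.genes, comp):
        groups.setdefault(int(c), []).append(g)
    candidates = [sorted(v) for v in groups.values() if len(v) > 1]
    if not candidates:
        return []
    best_size = max(len(gs) for gs in candidates)
    return min(gs for gs in candidates if len(gs) == best_size)
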