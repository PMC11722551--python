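"""Expression-matrix, coordinate, embedding and label I/O plus preprocessing.

Internally the expression matrix is always genes x spots (``X`` with ``M``
genes and ``N`` spots); file readers auto-transpose and log the decision.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("mcist")

__all__ = [
    "ExpressionMatrix",
    "SpatialCoords",
    "LabelVector",
    "read_expression",
    "write_expression_mtx",
    "read_coords",
    "read_labels",
    "preprocess",
    "align_by_barcode",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x spots expression matrix with aligned identifiers.

    Parameters
    ----------
    values
        Dense ``(M, N)`` array of counts or normalized expression; finite,
        non-negative for counts (negative entries are rejected on read but
        tolerated here so that centred/transformed matrices can round-trip
        through the same container).
    gene_ids
        Length-``M`` gene identifiers. Duplicates are kept and disambiguated
        with a numeric suffix.
    barcodes
        Length-``N`` spot/cell barcodes; must be unique.
    """

    values: np.ndarray
    gene_ids: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 1 or n < 2:
            raise ValueError(f"need M >= 1 genes and N >= 2 spots, got {m} x {n}")
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.barcodes) != n:
            raise ValueError(f"{len(self.barcodes)} barcodes for {n} columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains NaN/Inf entries")
        if len(set(self.barcodes)) != n:
            raise ValueError("duplicate barcodes")
        self.gene_ids = _disambiguate(list(map(str, self.gene_ids)))
        self.barcodes = list(map(str, self.barcodes))

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]

    def spots(self) -> np.ndarray:
        """Spots-as-rows view ``(N, M)`` used by graph construction."""
        return self.values.T


@dataclass
class SpatialCoords:
    """2-D spot coordinates with barcodes aligned to rows."""

    xy: np.ndarray
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("coordinates must be an (N, 2) matrix")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates contain NaN/Inf")
        if len(self.barcodes) != self.xy.shape[0]:
            raise ValueError("barcode count does not match coordinate rows")
        self.barcodes = list(map(str, self.barcodes))


@dataclass
class LabelVector:
    """Integer cluster/domain labels for N spots.

    Labels are remapped to contiguous non-negative integers in order of first
    appearance; ``names`` optionally maps each integer back to a string.
    """

    labels: np.ndarray
    names: dict[int, str] | None = field(default=None)

    def __post_init__(self) -> None:
        raw = np.asarray(self.labels)
        if raw.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        uniq, inverse = np.unique(raw, return_inverse=True)
        # preserve order of first appearance rather than sorted order
        first = {v: np.argmax(raw == v) for v in uniq}
        order = sorted(range(len(uniq)), key=lambda i: first[uniq[i]])
        rank = np.empty(len(uniq), dtype=int)
        rank[order] = np.arange(len(uniq))
        self.labels = rank[inverse]
        if self.names is None and raw.dtype.kind in "UOS":
            self.names = {int(rank[i]): str(uniq[i]) for i in range(len(uniq))}

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def _disambiguate(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}.{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_id_file(path: str) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None)
    return df.iloc[:, 0].astype(str).tolist()


def read_expression(path: str, fmt: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from ``mtx``, ``csv`` or ``h5ad``.

    ``mtx`` expects sibling ``features.tsv`` and ``barcodes.tsv`` files (first
    column used); orientation is auto-detected from the identifier files.
    ``csv`` expects a header row of barcodes and a first column of gene ids.
    ``h5ad`` stores spots as observations and is transposed to genes x spots.
    """
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {".mtx": "mtx", ".csv": "csv", ".h5ad": "h5ad"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    if fmt == "mtx":
        d = os.path.dirname(path)
        fpath = os.path.join(d, "features.tsv")
        if not os.path.exists(fpath):
            fpath = os.path.join(d, "genes.tsv")
        bpath = os.path.join(d, "barcodes.tsv")
        if not os.path.exists(fpath) or not os.path.exists(bpath):
            raise FileNotFoundError(
                f"mtx input requires sibling features.tsv/barcodes.tsv next to {path}"
            )
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        genes = _read_id_file(fpath)
        barcodes = _read_id_file(bpath)
        if mat.shape == (len(genes), len(barcodes)):
            pass
        elif mat.shape == (len(barcodes), len(genes)):
            logger.info("read_expression: transposing %s to genes x spots", path)
            mat = mat.T
        else:
            raise ValueError(
                f"matrix shape {mat.shape} matches neither ({len(genes)} genes, "
                f"{len(barcodes)} barcodes) orientation"
            )
    elif fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        mat = df.to_numpy(dtype=float)
        genes = df.index.astype(str).tolist()
        barcodes = df.columns.astype(str).tolist()
    elif fmt == "h5ad":
        import anndata

        ad = anndata.read_h5ad(path)
        x = ad.X
        if scipy.sparse.issparse(x):
            x = x.toarray()
        mat = np.asarray(x, dtype=float).T  # AnnData is spots x genes
        logger.info("read_expression: transposed h5ad %s to genes x spots", path)
        genes = ad.var_names.astype(str).tolist()
        barcodes = ad.obs_names.astype(str).tolist()
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if np.any(mat < 0):
        raise ValueError("expression matrix has negative entries")
    return ExpressionMatrix(mat, genes, barcodes)


def write_expression_mtx(x: ExpressionMatrix, path: str) -> None:
    """Write ``x`` as Matrix Market plus sibling features.tsv/barcodes.tsv."""
    d = os.path.dirname(path) or "."
    os.makedirs(d, exist_ok=True)
    sp = scipy.sparse.coo_matrix(x.values)
    if np.allclose(x.values, np.round(x.values)):
        scipy.io.mmwrite(path, sp.astype(int))
    else:
        scipy.io.mmwrite(path, sp)
    pd.Series(x.gene_ids).to_csv(
        os.path.join(d, "features.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(x.barcodes).to_csv(
        os.path.join(d, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def read_coords(path: str) -> SpatialCoords:
    """Read spot coordinates from TSV/CSV with columns (barcode, x, y)."""
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise ValueError("coordinate file needs (barcode, x, y) columns")
    return SpatialCoords(
        df.iloc[:, 1:3].to_numpy(dtype=float), df.iloc[:, 0].astype(str).tolist()
    )


def write_coords(coords: SpatialCoords, path: str) -> None:
    pd.DataFrame(
        {"barcode": coords.barcodes, "x": coords.xy[:, 0], "y": coords.xy[:, 1]}
    ).to_csv(path, sep="\t", index=False)


def read_labels(path: str, barcodes: list[str] | None = None) -> LabelVector:
    """Read labels from CSV with a barcode column; realigned to ``barcodes``."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("label file needs (barcode, label) columns")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str))
    if barcodes is not None:
        missing = [b for b in barcodes if b not in ser.index]
        if missing:
            raise ValueError(f"labels missing for {len(missing)} barcodes")
        ser = ser.loc[barcodes]
    return LabelVector(ser.to_numpy())


def write_labels(labels: LabelVector, barcodes: list[str], path: str) -> None:
    names = labels.names or {}
    pd.DataFrame(
        {
            "barcode": barcodes,
            "domain": [names.get(int(v), int(v)) for v in labels.labels],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess(
    x: ExpressionMatrix,
    normalize: bool = True,
    log1p: bool = True,
    n_hvg: int | None = None,
) -> ExpressionMatrix:
    """Standard preprocessing: depth normalization, log1p, HVG selection.

    ``normalize`` rescales each spot so its total count equals the median
    library size; ``log1p`` applies ``log(1 + .)``; ``n_hvg`` keeps the top
    genes by dispersion (variance / mean, constant genes last). Deterministic;
    with everything off the input is returned unchanged.
    """
    if n_hvg is not None and n_hvg > x.n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds number of genes {x.n_genes}")
    if not normalize and not log1p and n_hvg is None:
        return x
    vals = x.values.copy()
    if normalize:
        depth = vals.sum(axis=0)
        target = float(np.median(depth))
        safe = np.where(depth > 0, depth, 1.0)
        vals = vals * (target / safe)
    genes = x.gene_ids
    if n_hvg is not None:
        # dispersion on the (depth-normalized) count scale, as is standard
        # for variance-stabilized HVG ranking; log-scale var/mean would
        # penalize high-mean genes
        mean = vals.mean(axis=1)
        var = vals.var(axis=1)
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
        # stable sort descending: ties keep original gene order
        order = np.argsort(-disp, kind="stable")[:n_hvg]
        order = np.sort(order)  # keep genomic ordering of the retained genes
        vals = vals[order]
        genes = [genes[i] for i in order]
    if log1p:
        vals = np.log1p(vals)
    return ExpressionMatrix(vals, genes, x.barcodes)


def align_by_barcode(
    x: ExpressionMatrix,
    coords: SpatialCoords,
    embedding: np.ndarray | None = None,
    embedding_barcodes: list[str] | None = None,
) -> tuple[ExpressionMatrix, SpatialCoords, np.ndarray | None]:
    """Restrict all inputs to the common barcodes, in ``x``'s barcode order."""
    cset = set(coords.barcodes)
    keep = [b for b in x.barcodes if b in cset]
    if embedding is not None:
        ebar = embedding_barcodes if embedding_barcodes is not None else x.barcodes
        eset = set(ebar)
        keep = [b for b in keep if b in eset]
    if not keep:
        raise ValueError("no barcodes in common")
    xi = [x.barcodes.index(b) for b in keep] if keep != x.barcodes else None
    if xi is not None:
        x = ExpressionMatrix(x.values[:, xi], x.gene_ids, keep)
    cpos = {b: i for i, b in enumerate(coords.barcodes)}
    coords = SpatialCoords(coords.xy[[cpos[b] for b in keep]], keep)
    emb = None
    if embedding is not None:
        epos = {b: i for i, b in enumerate(ebar)}
        emb = np.asarray(embedding)[[epos[b] for b in keep]]
    return x, coords, emb
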