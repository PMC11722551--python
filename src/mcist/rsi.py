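"""Residue-Similarity Index: label-aware embedding quality without ground truth.

For an embedding f (N x m) and a labeling, each sample i in class c gets

* a residue  R_i = sum_{j not in c} ||f_i - f_j||_2, max-normalized over
  samples — large when the classes sit far apart;
* a similarity S_i = mean_{j in c, j != i} (1 - ||f_i - f_j||_2 / d_max),
  with d_max the maximum pairwise distance — large when the class is tight.

The RSI score is the mean of (R_i + S_i) / 2. Both parts are normalized by
data-dependent maxima, so the score is invariant to rigid transformations
and global scaling of the embedding. It correlates with clustering accuracy
and is used to pick one embedding among candidates when no annotation exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import LabelVector

__all__ = ["RsiScore", "rsi_score", "select_by_rsi"]


@dataclass
class RsiScore:
    value: float
    per_sample_residue: np.ndarray
    per_sample_similarity: np.ndarray


def rsi_score(f: np.ndarray, labels: LabelVector | np.ndarray) -> RsiScore:
    """Residue-Similarity Index of an embedding under a labeling.

    Requires at least two classes. Degenerate inputs are defined rather than
    rejected: singleton classes get similarity 1, and if every point is
    identical (d_max = 0) similarities are 1 and residues 0, giving 0.5.
    """
    f = np.asarray(f, dtype=float)
    lab = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    n = f.shape[0]
    if len(lab) != n:
        raise ValueError("labels length does not match embedding rows")
    classes = np.unique(lab)
    if len(classes) < 2:
        raise ValueError("RSI needs at least two classes")
    d = squareform(pdist(f))
    d_max = float(d.max())

    same = lab[:, None] == lab[None, :]
    residue_raw = (d * ~same).sum(axis=1)
    r_max = float(residue_raw.max())
    residue = residue_raw / r_max if r_max > 0 else np.zeros(n)

    similarity = np.ones(n)
    if d_max > 0:
        for i in range(n):
            mates = same[i].copy()
            mates[i] = False
            if mates.any():
                similarity[i] = float(np.mean(1.0 - d[i, mates] / d_max))
    value = float(np.mean(0.5 * (residue + similarity)))
    return RsiScore(value, residue, similarity)


def select_by_rsi(
    embeddings: list[np.ndarray],
    labelings: list[LabelVector | np.ndarray],
) -> int:
    """Index of the embedding maximizing RSI; ties go to the lowest index."""
    if not embeddings:
        raise ValueError("no candidate embeddings")
    if len(embeddings) != len(labelings):
        raise ValueError("need one labeling per embedding")
    scores = [rsi_score(f, lab).value for f, lab in zip(embeddings, labelings)]
    return int(np.argmax(scores))  # argmax takes the first maximum
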