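"""Topological PCA: graph-regularized sparse PCA with L2,1 norms.

The objective couples a robust L2,1 reconstruction term, an L2,1 sparsity
penalty on the projected data Q, and a trace penalty gamma * Tr(Q' L_P Q)
that pulls spots connected in the accumulated multiscale interaction graph
toward each other in the embedding:

    min_{U,Q}  ||X - U Q'||_{2,1} + beta ||Q||_{2,1} + gamma Tr(Q' L_P Q)
    s.t.       Q'Q = I_m

where X is genes x spots (M x N), U is M x m loadings and Q is N x m. The
orthogonality constraint sits on Q because the optimal Q of the pure trace
term is an eigenvector matrix of the symmetric Laplacian.

Solver: alternating minimization with iteratively reweighted least squares
(IRLS) surrogates for both L2,1 terms. Given Q (orthonormal) the optimal
loadings are U = X Q for any row reweighting, so each iteration reduces to a
symmetric eigenproblem: Q <- m lowest eigenvectors of

    S = -X' D_rec X + beta D_q + gamma L_P

with D_rec(ii) = 1 / (2 ||(X - U Q')_{i.}||_2 + eps) over gene rows and
D_q(ii) = 1 / (2 ||Q_{i.}||_2 + eps) over spots. A step is accepted only if
the true objective does not increase, so the recorded trace is monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .data_io import ExpressionMatrix
from .graphs import LaplacianFiltration, accumulate

__all__ = ["TpcaConfig", "TpcaFit", "tpca_objective", "fit_tpca", "embed_all_combinations"]

_IRLS_EPS = 1e-8


@dataclass
class TpcaConfig:
    """Hyperparameters of the topological PCA fit.

    ``beta`` weighs the sparsity of Q, ``gamma`` the multiscale graph
    regularization; defaults place slightly more emphasis on the graph term
    than on sparsity, after scaling X to unit Frobenius norm
    (``scale_frobenius``). ``m`` is the embedding dimension.
    """

    m: int = 32
    beta: float = 0.1
    gamma: float = 1.0
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    scale_frobenius: bool = True

    def __post_init__(self) -> None:
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be non-negative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class TpcaFit:
    """Result of a topological PCA fit.

    ``q`` (N x m) is the orthonormal projected-data matrix used as the
    embedding; ``u`` (M x m) the gene loadings; ``objective_trace`` the
    objective value per accepted iteration (non-increasing).
    """

    u: np.ndarray
    q: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    config: TpcaConfig | None = field(default=None, repr=False)


def _l21(a: np.ndarray) -> float:
    return float(np.linalg.norm(a, axis=1).sum())


def tpca_objective(
    x: ExpressionMatrix | np.ndarray,
    u: np.ndarray,
    q: np.ndarray,
    lp: np.ndarray,
    beta: float,
    gamma: float,
) -> float:
    """Evaluate ||X - UQ'||_{2,1} + beta ||Q||_{2,1} + gamma Tr(Q' L_P Q)."""
    xv = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    q = np.asarray(q, dtype=float)
    lp = np.asarray(lp, dtype=float)
    m_, n_ = xv.shape
    if u.shape[0] != m_ or q.shape[0] != n_ or u.shape[1] != q.shape[1]:
        raise ValueError(
            f"shape mismatch: X {xv.shape}, U {u.shape}, Q {q.shape}"
        )
    if lp.shape != (n_, n_):
        raise ValueError(f"L_P must be {n_} x {n_}, got {lp.shape}")
    rec = _l21(xv - u @ q.T)
    return rec + beta * _l21(q) + gamma * float(np.trace(q.T @ lp @ q))


def _init_q(xv: np.ndarray, m: int, seed: int) -> np.ndarray:
    """Right singular vectors of X (deterministic truncated SVD init)."""
    n = xv.shape[1]
    if min(xv.shape) <= 512:
        _, _, vt = np.linalg.svd(xv, full_matrices=False)
        q = vt[:m].T
    else:
        from sklearn.utils.extmath import randomized_svd

        _, _, vt = randomized_svd(xv, n_components=m, random_state=seed)
        q = vt.T
    # orthonormalize defensively and fix column signs
    q, _ = np.linalg.qr(q)
    return _fix_signs(q[:, :m])


def _fix_signs(q: np.ndarray) -> np.ndarray:
    """Force the largest-magnitude entry of each column positive."""
    q = q.copy()
    for j in range(q.shape[1]):
        i = np.argmax(np.abs(q[:, j]))
        if q[i, j] < 0:
            q[:, j] = -q[:, j]
    return q


def fit_tpca(
    x: ExpressionMatrix | np.ndarray,
    lp: np.ndarray,
    cfg: TpcaConfig | None = None,
) -> TpcaFit:
    """Fit topological PCA by IRLS alternating minimization.

    ``lp`` is the (N x N) accumulated spectral graph; it must be symmetric
    PSD up to tolerance. Initialization is the truncated SVD of X, so the fit
    is deterministic for a given input. Iterations stop when the relative
    objective change drops below ``cfg.tol``, when a step would increase the
    objective (IRLS stationarity), or at ``cfg.max_iter``.
    """
    cfg = cfg or TpcaConfig()
    xv = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    lp = np.asarray(lp, dtype=float)
    m_, n_ = xv.shape
    if not 1 <= cfg.m < min(m_, n_):
        raise ValueError(f"m={cfg.m} out of range for X {xv.shape}")
    if lp.shape != (n_, n_):
        raise ValueError(f"L_P must be {n_} x {n_}, got {lp.shape}")
    if not np.allclose(lp, lp.T, atol=1e-8):
        raise ValueError("L_P must be symmetric")
    evmin = scipy.linalg.eigvalsh(lp, subset_by_index=[0, 0])[0]
    scale = np.abs(lp).max() if np.abs(lp).max() > 0 else 1.0
    if evmin < -1e-6 * scale:
        raise ValueError("L_P is not positive semi-definite")

    if cfg.scale_frobenius:
        fro = np.linalg.norm(xv)
        if fro > 0:
            xv = xv / fro

    mdim = cfg.m
    q = _init_q(xv, mdim, cfg.seed)
    u = xv @ q
    obj = tpca_objective(xv, u, q, lp, cfg.beta, cfg.gamma)
    trace = [obj]
    converged = False
    for _ in range(cfg.max_iter):
        # IRLS weights at the current iterate
        res_rows = np.linalg.norm(xv - u @ q.T, axis=1)
        d_rec = 1.0 / (2.0 * res_rows + _IRLS_EPS)
        q_rows = np.linalg.norm(q, axis=1)
        d_q = 1.0 / (2.0 * q_rows + _IRLS_EPS)
        # surrogate matrix; with U = X Q the reconstruction surrogate is
        # Tr(X' D_rec X) - Tr(Q' X' D_rec X Q), so only the quadratic term
        # matters for the Q-update
        s = -(xv.T * d_rec) @ xv + cfg.beta * np.diag(d_q) + cfg.gamma * lp
        s = 0.5 * (s + s.T)
        _, vec = scipy.linalg.eigh(s, subset_by_index=[0, mdim - 1])
        q_new = _fix_signs(vec)
        u_new = xv @ q_new
        obj_new = tpca_objective(xv, u_new, q_new, lp, cfg.beta, cfg.gamma)
        if obj_new > obj + 1e-12 * max(1.0, abs(obj)):
            converged = True  # IRLS stationary point: step rejected
            break
        q, u = q_new, u_new
        trace.append(obj_new)
        if obj > 0 and (obj - obj_new) / max(obj, 1e-300) < cfg.tol:
            obj = obj_new
            converged = True
            break
        obj = obj_new
    return TpcaFit(
        u=u, q=q, objective_trace=np.asarray(trace), converged=converged, config=cfg
    )


def embed_all_combinations(
    x: ExpressionMatrix | np.ndarray,
    filtration: LaplacianFiltration,
    combos: list[np.ndarray],
    cfg: TpcaConfig | None = None,
) -> list[np.ndarray]:
    """One tPCA embedding Q per zeta-combination, fitted independently.

    Every combination is fitted with the same configuration and seed, so two
    identical combinations yield identical embeddings.
    """
    if not combos:
        raise ValueError("need at least one zeta combination")
    cfg = cfg or TpcaConfig()
    out = []
    for z in combos:
        lp = accumulate(filtration, np.asarray(z, dtype=float))
        out.append(fit_tpca(x, lp, cfg).q)
    return out
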