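"""Log-Euclidean Gaussian kernel on the SPD manifold.

The Gaussian kernel built on the log-Euclidean metric,

    kappa(P, Q) = exp(-||log P - log Q||_F^2 / (2 sigma^2)),

is positive definite for every sigma > 0 (the LEM squared distance is
negative definite), so it embeds the manifold in a reproducing-kernel
Hilbert space where linear subspace learning applies. The AIRM-based
Gaussian kernel lacks this guarantee and is deliberately not offered.

Matrix logarithms are computed once per matrix and reused across all
pairs, so a Gram matrix costs one eigendecomposition per matrix.
"""

from __future__ import annotations

import warnings

import numpy as np

from .spd_core import sym_logm

__all__ = ["le_gaussian_kernel", "gram_matrix", "median_bandwidth", "log_stack"]


def log_stack(mats) -> np.ndarray:
    """Stack matrix logs of an SPD set into an (n, d, d) array."""
    mats = list(mats)
    if not mats:
        raise ValueError("empty set")
    return np.stack([sym_logm(np.asarray(m, float)) for m in mats])


def le_gaussian_kernel(P: np.ndarray, Q: np.ndarray, sigma: float) -> float:
    """Kernel value for one SPD pair; in (0, 1], symmetric in its arguments."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d2 = np.linalg.norm(sym_logm(P) - sym_logm(Q), "fro") ** 2
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _sq_dists(logs_a: np.ndarray, logs_b: np.ndarray) -> np.ndarray:
    """Pairwise squared Frobenius distances between two stacks of logs."""
    na, d, _ = logs_a.shape
    fa = logs_a.reshape(na, d * d)
    fb = logs_b.reshape(logs_b.shape[0], d * d)
    sq = (
        np.sum(fa**2, axis=1)[:, None]
        + np.sum(fb**2, axis=1)[None, :]
        - 2.0 * fa @ fb.T
    )
    return np.clip(sq, 0.0, None)


def gram_matrix(A, B=None, sigma: float = 1.0, *, logs_a=None, logs_b=None) -> np.ndarray:
    """Kernel Gram matrix between two SPD sets.

    When ``B`` is None (or is ``A``) the result is symmetric and
    positive semi-definite. Precomputed log stacks can be passed via
    ``logs_a`` / ``logs_b`` to amortise eigendecompositions.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    la = log_stack(A) if logs_a is None else np.asarray(logs_a)
    if la.shape[0] == 0:
        raise ValueError("empty set")
    if B is None and logs_b is None:
        lb, same = la, True
    else:
        lb = log_stack(B) if logs_b is None else np.asarray(logs_b)
        same = lb is la
        if lb.shape[0] == 0:
            raise ValueError("empty set")
    if la.shape[1] != lb.shape[1]:
        raise ValueError("dimension mismatch between sets")
    K = np.exp(-_sq_dists(la, lb) / (2.0 * sigma**2))
    if same:
        K = 0.5 * (K + K.T)
    return K


def median_bandwidth(mats, *, logs=None, max_pairs: int = 500, seed: int = 0) -> float:
    """Median-heuristic bandwidth: the median pairwise LEM distance.

    For sets with more than ``max_pairs`` pairs, a seeded subsample of
    pairs is used. Degenerate sets (all distances zero) fall back to
    sigma = 1.0 with a warning.
    """
    logs = log_stack(mats) if logs is None else np.asarray(logs)
    n = logs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 matrices for the median heuristic")
    n_pairs = n * (n - 1) // 2
    iu, ju = np.triu_indices(n, k=1)
    if n_pairs > max_pairs:
        rng = np.random.default_rng(seed)
        pick = rng.choice(n_pairs, size=max_pairs, replace=False)
        iu, ju = iu[pick], ju[pick]
    d = logs.shape[1]
    flat = logs.reshape(n, d * d)
    dists = np.linalg.norm(flat[iu] - flat[ju], axis=1)
    med = float(np.median(dists))
    if med <= 0:
        warnings.warn("all pairwise distances are zero; falling back to sigma=1.0", stacklevel=2)
        return 1.0
    return med
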