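"""Geometry of the symmetric positive definite (SPD) manifold.

Multichannel EEG trials are summarised by trace-normalised spatial
covariance matrices, which live on the curved manifold of SPD matrices.
This module provides the covariance descriptor, the affine-invariant
Riemannian metric (AIRM) and the log-Euclidean metric (LEM), the
logarithmic/exponential maps between the manifold and its tangent
spaces, the iterative Karcher (Frechet) mean, and the weighted
half-vectorisation used to flatten tangent matrices into feature
vectors of length d(d+1)/2.

All matrix logarithms and exponentials go through a single symmetric
eigendecomposition, ``U diag(f(lambda)) U^T``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "EEGTrial",
    "MeanConfig",
    "covariance",
    "sym_logm",
    "sym_expm",
    "sym_sqrtm",
    "sym_invsqrtm",
    "log_map",
    "exp_map",
    "airm_distance",
    "lem_distance",
    "riemannian_mean",
    "tangent_vectorize",
    "is_spd",
    "check_spd",
]

_SYM_RTOL = 1e-10


@dataclass
class EEGTrial:
    """A single EEG recording: a channels x samples matrix plus metadata.

    Parameters
    ----------
    data : ndarray, shape (c, t)
        Raw signal, channels along rows, in microvolts.
    fs : float
        Sampling rate in Hz.
    id : str
        Opaque trial identifier.
    """

    data: np.ndarray
    fs: float
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trial data must be a 2-D channels x samples matrix")
        c, t = self.data.shape
        if c < 2:
            raise ValueError(f"trial {self.id!r}: need at least 2 channels, got {c}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"trial {self.id!r}: non-finite entries")
        if t < c:
            warnings.warn(
                f"trial {self.id!r}: fewer samples ({t}) than channels ({c}); "
                "covariance will be rank-deficient",
                stacklevel=2,
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class MeanConfig:
    """Settings for the iterative Riemannian-mean solver.

    ``eps`` is the Frobenius-norm change between successive estimates
    at which iteration stops; ``max_iter`` caps the iteration count.
    ``init`` selects the starting point: the arithmetic mean of the set
    (default, fewer iterations) or the identity matrix.
    """

    max_iter: int = 100
    eps: float = 1e-8
    init: str = "arithmetic"  # or "identity"

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.init not in ("arithmetic", "identity"):
            raise ValueError("init must be 'arithmetic' or 'identity'")


def _as_square(m: np.ndarray, name: str = "matrix") -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    return m


def _check_symmetric(m: np.ndarray, name: str = "matrix") -> np.ndarray:
    m = _as_square(m, name)
    scale = max(np.abs(m).max(), 1.0)
    if np.abs(m - m.T).max() > 1e-8 * scale:
        raise ValueError(f"{name} is not symmetric")
    return 0.5 * (m + m.T)


def is_spd(m: np.ndarray, rtol: float = _SYM_RTOL) -> bool:
    """True when ``m`` is symmetric (to tolerance) with all eigenvalues > 0."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        return False
    scale = max(np.abs(m).max(), 1.0)
    if np.abs(m - m.T).max() > rtol * scale * 100:
        return False
    try:
        w = linalg.eigvalsh(0.5 * (m + m.T))
    except linalg.LinAlgError:
        return False
    return bool(w.min() > 0)


def check_spd(m: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate and symmetrise an SPD matrix; raise ValueError otherwise."""
    m = _check_symmetric(m, name)
    w = linalg.eigvalsh(m)
    if w.min() <= 0:
        raise ValueError(f"{name} is not positive definite (min eigenvalue {w.min():.3e})")
    return m


def covariance(trial: EEGTrial | np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    """Trace-normalised spatial covariance ``X X^T / Tr(X X^T)`` of a trial.

    Normalising by the total variance puts every trial's descriptor on
    the trace-one slice of the SPD cone, removing amplitude scale.
    Rank-deficient covariances (t < c, flat channels) are regularised by
    adding ``jitter * I / d`` and renormalising the trace to one.

    Returns a d x d SPD matrix with unit trace.
    """
    X = trial.data if isinstance(trial, EEGTrial) else np.asarray(trial, dtype=float)
    if X.ndim != 2:
        raise ValueError("trial must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("trial has non-finite entries")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    C = X @ X.T
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("degenerate trial: zero total variance")
    P = C / tr
    P = 0.5 * (P + P.T)
    d = P.shape[0]
    w = linalg.eigvalsh(P)
    if w.min() < 1e-12:  # trace is 1, so this is relative to the trace
        P = P + (jitter / d) * np.eye(d)
        P = P / np.trace(P)
    return P


def _eig_apply(m: np.ndarray, fn) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of a symmetric matrix."""
    w, U = linalg.eigh(0.5 * (m + m.T))
    return (U * fn(w)) @ U.T


def sym_logm(P: np.ndarray) -> np.ndarray:
    """Principal matrix logarithm of an SPD matrix via eigendecomposition.

    Eigenvalues are floored at ``1e-14 * lambda_max`` before the log so
    near-singular inputs do not produce -inf.
    """
    w, U = linalg.eigh(0.5 * (np.asarray(P, float) + np.asarray(P, float).T))
    if w.max() <= 0:
        raise ValueError("matrix is not positive definite")
    w = np.clip(w, 1e-14 * w.max(), None)
    return (U * np.log(w)) @ U.T


def sym_expm(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (always SPD)."""
    return _eig_apply(S, np.exp)


def sym_sqrtm(P: np.ndarray) -> np.ndarray:
    return _eig_apply(check_spd(P), np.sqrt)


def sym_invsqrtm(P: np.ndarray) -> np.ndarray:
    return _eig_apply(check_spd(P), lambda w: 1.0 / np.sqrt(w))


def _sqrt_pair(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(P^{1/2}, P^{-1/2}) from one eigendecomposition."""
    w, U = linalg.eigh(check_spd(P))
    s = np.sqrt(w)
    return (U * s) @ U.T, (U / s) @ U.T


def log_map(P: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Logarithmic map of ``P`` into the tangent space at ``ref``.

    ``S = ref^{1/2} log(ref^{-1/2} P ref^{-1/2}) ref^{1/2}`` — the
    tangent (symmetric) matrix whose geodesic through ``ref`` reaches
    ``P`` at unit time.
    """
    P = check_spd(P, "P")
    h, hi = _sqrt_pair(ref)
    inner = hi @ P @ hi
    S = h @ sym_logm(0.5 * (inner + inner.T)) @ h
    return 0.5 * (S + S.T)


def exp_map(S: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Exponential map: shoot the tangent matrix ``S`` at ``ref`` back onto the manifold."""
    S = _check_symmetric(S, "tangent matrix")
    h, hi = _sqrt_pair(ref)
    inner = hi @ S @ hi
    P = h @ sym_expm(0.5 * (inner + inner.T)) @ h
    return 0.5 * (P + P.T)


def _check_same_dim(P: np.ndarray, Q: np.ndarray) -> None:
    if P.shape != Q.shape:
        raise ValueError(f"dimension mismatch: {P.shape} vs {Q.shape}")


def airm_distance(P: np.ndarray, Q: np.ndarray) -> float:
    """Affine-invariant Riemannian (geodesic) distance between two SPD matrices.

    ``||log(P^{-1/2} Q P^{-1/2})||_F = sqrt(sum_i log^2 lambda_i)`` with
    ``lambda_i`` the eigenvalues of ``P^{-1} Q``; invariant under any
    congruence ``P -> A P A^T`` with invertible ``A``.
    """
    P = check_spd(P, "P")
    Q = check_spd(Q, "Q")
    _check_same_dim(P, Q)
    # generalized eigenvalues of (Q, P) are the eigenvalues of P^{-1} Q
    w = linalg.eigvalsh(Q, P)
    w = np.clip(w, 1e-300, None)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def lem_distance(P: np.ndarray, Q: np.ndarray) -> float:
    """Log-Euclidean distance ``||log(P) - log(Q)||_F``."""
    P = check_spd(P, "P")
    Q = check_spd(Q, "Q")
    _check_same_dim(P, Q)
    return float(np.linalg.norm(sym_logm(P) - sym_logm(Q), "fro"))


def riemannian_mean(
    mats, cfg: MeanConfig | None = None
) -> tuple[np.ndarray, dict]:
    """Karcher mean of a set of SPD matrices under the AIRM.

    Iterates: map every matrix to the tangent space at the current
    estimate, take the arithmetic mean there, and shoot it back with the
    exponential map; stop when the estimate moves by less than
    ``cfg.eps`` in Frobenius norm.

    Returns
    -------
    mean : ndarray
        The (approximate) Karcher mean.
    info : dict
        ``n_iter`` and ``converged``; a non-converged run returns the
        last iterate with ``converged=False`` and emits a warning.
    """
    cfg = cfg or MeanConfig()
    mats = [check_spd(np.asarray(m, float), f"set[{i}]") for i, m in enumerate(mats)]
    if not mats:
        raise ValueError("cannot average an empty set")
    d = mats[0].shape[0]
    for m in mats[1:]:
        if m.shape[0] != d:
            raise ValueError("dimension mismatch within set")
    if len(mats) == 1:
        return mats[0].copy(), {"n_iter": 0, "converged": True}

    C = np.mean(mats, axis=0) if cfg.init == "arithmetic" else np.eye(d)
    converged = False
    it = 0
    # A damped tangent-average step: the undamped iteration map has
    # contraction modes approaching -1 on widely spread sets, giving slow
    # sign-alternating convergence. Half steps map every mode lambda in
    # (-1, 1] to the non-negative rate 1 - (1-lambda)/2, so convergence is
    # monotone for any input set, at worst twice the iteration count of the
    # full-step scheme on easy sets. Extra damping kicks in if the
    # Riemannian gradient norm ever grows.
    step = 0.5
    prev_grad = np.inf
    damp = 0.75
    for it in range(1, cfg.max_iter + 1):
        h, hi = _sqrt_pair(C)
        S = np.zeros((d, d))
        for P in mats:
            inner = hi @ P @ hi
            S += sym_logm(0.5 * (inner + inner.T))
        S /= len(mats)
        grad = np.linalg.norm(S, "fro")
        if grad > prev_grad:
            step = max(step * damp, 0.1)
        prev_grad = grad
        C_next = h @ sym_expm(step * S) @ h
        C_next = 0.5 * (C_next + C_next.T)
        delta = np.linalg.norm(C_next - C, "fro")
        C = C_next
        if delta < cfg.eps:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Riemannian mean did not converge in {cfg.max_iter} iterations", stacklevel=2
        )
    return C, {"n_iter": it, "converged": converged}


# weighted half-vectorization -------------------------------------------------

def _triu_indices(d: int):
    return np.triu_indices(d)


def tangent_vectorize(P: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Weighted half-vectorisation of ``log_map(P, ref)``.

    Off-diagonal entries are scaled by sqrt(2) so the Euclidean norm of
    the vector equals the Frobenius norm of the tangent matrix. Length
    is ``d(d+1)/2`` (e.g. 7021 for 118 channels, 66 for an 11 x 11
    frame covariance).
    """
    S = log_map(P, ref)
    return vectorize_symmetric(S)


def vectorize_symmetric(S: np.ndarray) -> np.ndarray:
    """Half-vectorise a symmetric matrix with sqrt(2) off-diagonal weights."""
    S = _check_symmetric(S, "tangent matrix")
    d = S.shape[0]
    i, j = _triu_indices(d)
    v = S[i, j].copy()
    v[i != j] *= np.sqrt(2.0)
    return v
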