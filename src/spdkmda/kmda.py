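"""KMDA: kernel-based manifold domain adaptation on SPD descriptors.

The learner receives labeled source covariance matrices and unlabeled
target ones. After Riemannian alignment of the source onto the target,
all matrices are embedded in an RKHS by the log-Euclidean Gaussian
kernel, and a projection W over the kernel columns is learned from the
generalized eigenproblem

    Theta w = lambda Psi w,

where Theta = blockdiag(alpha * St, beta * Sb) collects what should be
preserved (target variance St, source between-class scatter Sb) and
Psi = sum_c (mu * K Mc K + beta * Sw^(c)) + rho * I collects what
should be shrunk (class-conditional MMD between domains, source
within-class scatter), with a small ridge rho for invertibility.
Target pseudo-labels — initialised by MDRM and refined by kNN on the
embedded features — define the class-conditional MMD matrices Mc, and
the eigenproblem/relabel cycle repeats until the pseudo-labels stop
changing or the iteration cap T is reached.

Ordering convention everywhere: target block first, then source, so
the joint Gram is K = [[Kt, Kts], [Kst, Ks]].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .alignment import riemannian_align
from .classifiers import knn_predict, mdrm_fit, mdrm_predict
from .manifold_kernel import gram_matrix, log_stack, median_bandwidth
from .spd_core import MeanConfig

logger = logging.getLogger(__name__)

__all__ = [
    "DomainDataset",
    "KMDAParams",
    "KMDAModel",
    "scatter_target",
    "scatter_source",
    "conditional_mmd_matrix",
    "assemble_objective",
    "solve_projection",
    "embed",
    "fit",
    "predict",
]


@dataclass
class DomainDataset:
    """Unlabeled target SPD set plus labeled source SPD set (target first)."""

    target: list
    source: list
    source_labels: np.ndarray

    def __post_init__(self) -> None:
        self.target = [np.asarray(m, float) for m in self.target]
        self.source = [np.asarray(m, float) for m in self.source]
        self.source_labels = np.asarray(self.source_labels)
        if len(self.target) < 1:
            raise ValueError("target set is empty")
        if len(self.source) != len(self.source_labels):
            raise ValueError("source set and labels must align")
        if np.unique(self.source_labels).size < 2:
            raise ValueError("source must contain at least 2 classes")
        d = self.target[0].shape[0]
        if any(m.shape[0] != d for m in self.target + self.source):
            raise ValueError("dimension mismatch across the dataset")

    @property
    def n_target(self) -> int:
        return len(self.target)

    @property
    def n_source(self) -> int:
        return len(self.source)

    @property
    def dim(self) -> int:
        return self.target[0].shape[0]


@dataclass
class KMDAParams:
    """Trade-off and solver parameters.

    alpha weights the target-variance term, beta the source
    discriminative scatter, mu the class-conditional MMD; k is the
    subspace dimension (None means k = d, the SPD matrix size), T the
    pseudo-label refinement cap, sigma the kernel bandwidth ("auto" =
    median heuristic on the pooled aligned set), rho the denominator
    ridge (None = 1e-3 * tr(Psi_0)/N).
    """

    alpha: float = 1.0
    beta: float = 0.1
    mu: float = 1.0
    k: int | None = None
    T: int = 15
    sigma: float | str = "auto"
    rho: float | None = None
    knn_k: int = 3

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.mu <= 0:
            raise ValueError("alpha and mu must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.rho is not None and self.rho < 0:
            raise ValueError("rho must be >= 0")
        if isinstance(self.sigma, str):
            if self.sigma != "auto":
                raise ValueError("sigma must be a positive number or 'auto'")
        elif self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class KMDAModel:
    """Fitted KMDA state: projection, kernel context and embeddings."""

    W: np.ndarray  # (N, k)
    train_logs: np.ndarray  # (N, d, d) matrix logs of target+source (aligned)
    sigma: float
    rho: float
    n_target: int
    source_embeddings: np.ndarray  # (Ns, k), standardized
    embed_mean: np.ndarray  # (k,) per-dimension standardization over train
    embed_std: np.ndarray  # (k,)
    source_labels: np.ndarray
    target_pseudo_labels: np.ndarray
    target_mean: np.ndarray  # alignment reference for new data
    source_mean: np.ndarray
    iteration_log: list = field(default_factory=list)
    converged: bool = True
    knn_k: int = 3


def scatter_target(Kt: np.ndarray) -> np.ndarray:
    """Target variance scatter ``St = Kt Ht Kt^T`` with the centering matrix Ht."""
    Kt = np.asarray(Kt, float)
    nt = Kt.shape[0]
    if Kt.shape != (nt, nt):
        raise ValueError("Kt must be square")
    Ht = np.eye(nt) - np.full((nt, nt), 1.0 / nt)
    St = Kt @ Ht @ Kt.T
    return 0.5 * (St + St.T)


def scatter_source(Ks: np.ndarray, y) -> tuple[np.ndarray, dict]:
    """Between-class scatter Sb and per-class within-class scatters Sw^(c).

    Treats the kernel columns of Ks as feature vectors:
    Sb = sum_c Ns^(c) (m^(c) - m)(m^(c) - m)^T over class-mean columns,
    Sw^(c) = Ks^(c) Hs^(c) Ks^(c)^T on the class-c column block.
    """
    Ks = np.asarray(Ks, float)
    y = np.asarray(y)
    ns = Ks.shape[0]
    if Ks.shape != (ns, ns) or y.shape[0] != ns:
        raise ValueError("Ks must be Ns x Ns with matching labels")
    classes = np.unique(y)
    m_all = Ks.mean(axis=1)
    Sb = np.zeros((ns, ns))
    Sw = {}
    for c in classes:
        cols = Ks[:, y == c]
        nc = cols.shape[1]
        mc = cols.mean(axis=1)
        diff = mc - m_all
        Sb += nc * np.outer(diff, diff)
        Hc = np.eye(nc) - np.full((nc, nc), 1.0 / nc)
        Swc = cols @ Hc @ cols.T
        Sw[c] = 0.5 * (Swc + Swc.T)
    if classes.size < 2:
        import warnings

        warnings.warn("single-class source: between-class scatter is zero", stacklevel=2)
        Sb[:] = 0.0
    return 0.5 * (Sb + Sb.T), Sw


def conditional_mmd_matrix(y_s, y_t_pseudo, c) -> np.ndarray:
    """Class-conditional MMD coefficient matrix Mc (target-first, N x N).

    Entries: 1/Nt(c)^2 for target-target pairs of class c, 1/Ns(c)^2 for
    source-source pairs, -1/(Ns(c) Nt(c)) for cross pairs, 0 otherwise,
    so Tr(Z Mc Z^T) on embeddings Z equals the squared distance between
    the class-c embedded means of the two domains.
    """
    y_s = np.asarray(y_s)
    y_t = np.asarray(y_t_pseudo)
    nt, ns = y_t.shape[0], y_s.shape[0]
    n = nt + ns
    in_t = np.concatenate([y_t == c, np.zeros(ns, bool)])
    in_s = np.concatenate([np.zeros(nt, bool), y_s == c])
    ntc, nsc = int(in_t.sum()), int(in_s.sum())
    if nsc == 0:
        raise ValueError(f"class {c!r} absent from source")
    M = np.zeros((n, n))
    if ntc == 0:
        return M  # caller decides to skip; keeps shape contract
    M[np.ix_(in_t, in_t)] = 1.0 / ntc**2
    M[np.ix_(in_s, in_s)] = 1.0 / nsc**2
    M[np.ix_(in_t, in_s)] = -1.0 / (nsc * ntc)
    M[np.ix_(in_s, in_t)] = -1.0 / (nsc * ntc)
    return M


def _embed_block(mat: np.ndarray, n: int, offset: int) -> np.ndarray:
    out = np.zeros((n, n))
    m = mat.shape[0]
    out[offset : offset + m, offset : offset + m] = mat
    return out


def assemble_objective(
    St: np.ndarray,
    Sb: np.ndarray,
    Sw_map: dict,
    K: np.ndarray,
    Mc_list,
    params: KMDAParams,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Build the numerator Theta and denominator Psi of the trace ratio.

    Theta = blockdiag(alpha*St, beta*Sb);
    Psi = sum_c (mu * K Mc K + beta * Sw^(c) in the source block) + rho*I.
    If Psi is not positive definite at the default ridge, rho is grown
    tenfold up to three times before giving up.

    Returns (Theta, Psi, rho_used).
    """
    K = np.asarray(K, float)
    n = K.shape[0]
    nt = St.shape[0]
    ns = Sb.shape[0]
    if nt + ns != n:
        raise ValueError("block sizes inconsistent with the Gram matrix")
    Theta = np.zeros((n, n))
    Theta[:nt, :nt] = params.alpha * St
    Theta[nt:, nt:] = params.beta * Sb
    Theta = 0.5 * (Theta + Theta.T)

    Psi0 = np.zeros((n, n))
    for Mc in Mc_list:
        Psi0 += params.mu * (K @ Mc @ K)
    for Swc in Sw_map.values():
        Psi0 += params.beta * _embed_block(Swc, n, nt)
    Psi0 = 0.5 * (Psi0 + Psi0.T)

    rho = params.rho if params.rho is not None else 1e-3 * max(np.trace(Psi0), 1.0) / n
    for attempt in range(4):
        Psi = Psi0 + rho * np.eye(n)
        wmin = linalg.eigvalsh(Psi)[0]
        if wmin > 0:
            return Theta, Psi, rho
        if attempt < 3:
            logger.warning("Psi indefinite (min eig %.3e); growing ridge to %.3e", wmin, rho * 10)
            rho *= 10.0
    raise ValueError("Psi remained indefinite after ridge escalation")


def solve_projection(Theta: np.ndarray, Psi: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k leading generalized eigenvectors of Theta w = lambda Psi w.

    Columns are Psi-orthonormal (W^T Psi W = I) and carry a
    deterministic sign: the largest-magnitude entry of each column is
    positive.

    Returns (W, eigenvalues) with eigenvalues in descending order.
    """
    Theta = np.asarray(Theta, float)
    Psi = np.asarray(Psi, float)
    n = Theta.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    evals, evecs = linalg.eigh(Theta, Psi)
    order = np.argsort(evals)[::-1][:k]
    W = evecs[:, order]
    lam = evals[order]
    for j in range(W.shape[1]):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return W, lam


def embed(W: np.ndarray, K_cols: np.ndarray) -> np.ndarray:
    """Project kernel columns into the subspace: z = W^T K_cols, shape (k, m)."""
    W = np.asarray(W, float)
    K_cols = np.asarray(K_cols, float)
    if K_cols.ndim == 1:
        K_cols = K_cols[:, None]
    if K_cols.shape[0] != W.shape[0]:
        raise ValueError("kernel column row-count must match training size")
    return W.T @ K_cols


def _mmd_value(W: np.ndarray, K: np.ndarray, Mc_list) -> float:
    """Sum over classes of Tr(W^T K Mc K W): the class-conditional MMD."""
    total = 0.0
    Z = K @ W  # (N, k)
    for Mc in Mc_list:
        total += float(np.trace(Z.T @ Mc @ Z))
    return total


def fit(
    data: DomainDataset,
    params: KMDAParams | None = None,
    mean_cfg: MeanConfig | None = None,
    target_labels=None,
) -> KMDAModel:
    """Run the full KMDA pipeline on an SPD transfer problem.

    Alignment -> kernel Gram -> MDRM pseudo-labels -> iterate
    (generalized eigenproblem, embedding, kNN relabel) until the
    pseudo-labels are stable or T iterations have run.

    Passing ``target_labels`` switches to the supervised-target
    variant: the given labels replace the MDRM initialisation and a
    single subspace/embedding round is run (no pseudo-label
    refinement).
    """
    params = params or KMDAParams()
    mean_cfg = mean_cfg or MeanConfig()
    if target_labels is not None:
        target_labels = np.asarray(target_labels)
        if target_labels.shape[0] != data.n_target:
            raise ValueError("target_labels must match the target set size")

    ra = riemannian_align(data.source, data.target, mean_cfg)
    train = list(data.target) + list(ra.aligned_source)
    nt, ns = data.n_target, data.n_source
    n = nt + ns
    logs = log_stack(train)

    sigma = (
        median_bandwidth(train, logs=logs)
        if isinstance(params.sigma, str)
        else float(params.sigma)
    )
    K = gram_matrix(train, sigma=sigma, logs_a=logs)
    Kt = K[:nt, :nt]
    Ks = K[nt:, nt:]

    y_s = data.source_labels
    classes = np.unique(y_s)
    k_dim = params.k if params.k is not None else data.dim
    if not (1 <= k_dim <= n):
        raise ValueError(f"subspace dimension k={k_dim} outside [1, {n}]")

    if target_labels is not None:
        y_t = target_labels
        n_rounds = 1
    else:
        # pseudo-label initialisation by MDRM on the aligned source
        mdrm = mdrm_fit(ra.aligned_source, y_s, mean_cfg)
        y_t = mdrm_predict(mdrm, data.target)
        n_rounds = params.T

    # label-independent scatters are fixed across iterations
    St = scatter_target(Kt)
    Sb, Sw = scatter_source(Ks, y_s)

    log_rows = []
    converged = False
    W = None
    rho_used = np.nan
    z_s = None
    for it in range(1, n_rounds + 1):
        Mc_list = []
        for c in classes:
            Mc = conditional_mmd_matrix(y_s, y_t, c)
            if not np.any(Mc):
                logger.info("iteration %d: class %r absent from pseudo-labels; skipped", it, c)
            Mc_list.append(Mc)
        Theta, Psi, rho_used = assemble_objective(St, Sb, Sw, K, Mc_list, params)
        W, lam = solve_projection(Theta, Psi, k_dim)
        Z = embed(W, K)  # (k, N)
        # standardize each embedded dimension over the training pool: the
        # generalized eigenvectors carry arbitrary per-direction scales
        # (Psi-orthonormality) that would otherwise dominate the kNN metric
        z_mean = Z.mean(axis=1)
        z_std = np.maximum(Z.std(axis=1), 1e-12)
        Zn = (Z - z_mean[:, None]) / z_std[:, None]
        z_t, z_s = Zn[:, :nt].T, Zn[:, nt:].T
        y_t_new = knn_predict(z_s, y_s, z_t, k=params.knn_k)
        n_changed = int(np.sum(y_t_new != y_t))
        log_rows.append(
            {
                "iteration": it,
                "objective": float(np.sum(lam)),
                "mmd": _mmd_value(W, K, Mc_list),
                "n_changed": n_changed,
                "rho": rho_used,
            }
        )
        y_t = y_t_new
        if n_changed == 0:
            converged = True
            break

    return KMDAModel(
        W=W,
        train_logs=logs,
        sigma=sigma,
        rho=rho_used,
        n_target=nt,
        source_embeddings=z_s,
        embed_mean=z_mean,
        embed_std=z_std,
        source_labels=y_s,
        target_pseudo_labels=y_t,
        target_mean=ra.target_mean,
        source_mean=ra.source_mean,
        iteration_log=log_rows,
        converged=converged,
        knn_k=params.knn_k,
    )


def predict(model: KMDAModel, mats) -> np.ndarray:
    """Classify new SPD matrices already expressed in the target's frame.

    Kernel columns against the stored training set are embedded with
    the fitted W and voted on by kNN against the stored source
    embeddings. The training set is not re-aligned.
    """
    mats = [np.asarray(m, float) for m in mats]
    if len(mats) == 0:
        return np.asarray([], dtype=model.source_labels.dtype)
    d = model.train_logs.shape[1]
    if any(m.shape[0] != d for m in mats):
        raise ValueError("dimension mismatch with the trained model")
    new_logs = log_stack(mats)
    K_cols = gram_matrix(
        None, None, sigma=model.sigma, logs_a=model.train_logs, logs_b=new_logs
    )  # (N, m)
    Z = embed(model.W, K_cols)
    Zn = (Z - model.embed_mean[:, None]) / model.embed_std[:, None]
    return knn_predict(model.source_embeddings, model.source_labels, Zn.T, k=model.knn_k)
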