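"""Classifiers used around the KMDA subspace: MDRM and a deterministic kNN.

MDRM (minimum distance to Riemannian mean) fits one Karcher mean per
class and assigns a test matrix to the geodesically nearest class mean.
It needs no tuning and is the standard pseudo-label initialiser on SPD
data. The kNN operates on embedded (Euclidean) feature vectors with a
fully specified tie-break so repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spd_core import MeanConfig, airm_distance, lem_distance, riemannian_mean

__all__ = ["MDRMModel", "mdrm_fit", "mdrm_predict", "knn_predict"]


@dataclass
class MDRMModel:
    class_means: dict  # label -> SPD ndarray
    metric: str = "airm"  # or "lem"


def mdrm_fit(mats, labels, cfg: MeanConfig | None = None, metric: str = "airm") -> MDRMModel:
    """One Karcher mean per class.

    Raises if any requested class has no samples (empty classes cannot
    define a mean).
    """
    if metric not in ("airm", "lem"):
        raise ValueError("metric must be 'airm' or 'lem'")
    cfg = cfg or MeanConfig()
    labels = np.asarray(labels)
    mats = [np.asarray(m, float) for m in mats]
    if len(mats) != len(labels):
        raise ValueError("labels and matrices must align")
    classes = np.unique(labels)
    if classes.size < 1:
        raise ValueError("no samples")
    means = {}
    for c in classes:
        members = [m for m, y in zip(mats, labels) if y == c]
        if not members:
            raise ValueError(f"class {c!r} has no samples")
        if len(members) == 1:
            means[c] = members[0].copy()
        else:
            means[c], _ = riemannian_mean(members, cfg)
    return MDRMModel(class_means=means, metric=metric)


def mdrm_predict(model: MDRMModel, mats) -> np.ndarray:
    """Nearest-class-mean labels; ties go to the lowest label (sorted order)."""
    dist = airm_distance if model.metric == "airm" else lem_distance
    classes = sorted(model.class_means.keys())
    d0 = model.class_means[classes[0]].shape[0]
    out = []
    for P in mats:
        P = np.asarray(P, float)
        if P.shape[0] != d0:
            raise ValueError("dimension mismatch with fitted class means")
        dists = [dist(P, model.class_means[c]) for c in classes]
        # argmin on a list keeps the first (lowest-label) minimum
        out.append(classes[int(np.argmin(dists))])
    return np.asarray(out)


def knn_predict(train_z: np.ndarray, train_y, test_z: np.ndarray, k: int = 3) -> np.ndarray:
    """k-nearest-neighbour vote on embedded features (Euclidean metric).

    Tie-break order: majority vote, then smallest mean distance to the
    tied class's neighbours, then lowest label in sorted order.
    """
    train_z = np.atleast_2d(np.asarray(train_z, float))
    test_z = np.atleast_2d(np.asarray(test_z, float))
    train_y = np.asarray(train_y)
    n = train_z.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if k > n:
        raise ValueError(f"k={k} exceeds training size {n}")
    if test_z.shape[0] == 0:
        return np.asarray([], dtype=train_y.dtype)
    if train_z.shape[1] != test_z.shape[1]:
        raise ValueError("feature dimension mismatch")

    d2 = (
        np.sum(test_z**2, axis=1)[:, None]
        + np.sum(train_z**2, axis=1)[None, :]
        - 2.0 * test_z @ train_z.T
    )
    d2 = np.clip(d2, 0.0, None)
    out = []
    for row in d2:
        # stable partial sort: among equal distances, lower train index wins
        nn = np.argsort(row, kind="stable")[:k]
        votes, dists = {}, {}
        for idx in nn:
            y = train_y[idx]
            votes[y] = votes.get(y, 0) + 1
            dists.setdefault(y, []).append(row[idx])
        best = sorted(
            votes,
            key=lambda y: (-votes[y], float(np.mean(dists[y])), _label_key(y)),
        )[0]
        out.append(best)
    return np.asarray(out)


def _label_key(y):
    # labels may be ints or strings; sort numerically when possible
    try:
        return (0, float(y), "")
    except (TypeError, ValueError):
        return (1, 0.0, str(y))
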