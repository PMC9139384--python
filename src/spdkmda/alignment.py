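"""Riemannian alignment (RA) of a source SPD set onto a target set.

Cross-subject EEG covariance matrices differ systematically (electrode
placement, head geometry, session effects). RA removes the first-order
part of that shift by whitening every source matrix with the source
Karcher mean and recoloring it with the target Karcher mean:

    P_i' = (M_s)^{-1/2} P_i (M_s)^{-1/2}        (whiten)
    P_i'' = (M_t)^{1/2}  P_i' (M_t)^{1/2}       (recolor)

Both stages are congruence transforms, so the aligned matrices stay
SPD, and because the AIRM Karcher mean is congruence-equivariant the
aligned source mean lands exactly on the target mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spd_core import MeanConfig, _sqrt_pair, check_spd, riemannian_mean

__all__ = ["AlignmentResult", "riemannian_align", "recenter"]


@dataclass
class AlignmentResult:
    """Aligned source set plus the two Karcher means used."""

    aligned_source: list[np.ndarray]
    source_mean: np.ndarray
    target_mean: np.ndarray


def _set_mean(mats: list[np.ndarray], cfg: MeanConfig) -> np.ndarray:
    if len(mats) == 1:
        # degenerate set: its Karcher mean is the single element
        return check_spd(mats[0])
    mean, _ = riemannian_mean(mats, cfg)
    return mean


def recenter(mats, old_mean: np.ndarray, new_mean: np.ndarray) -> list[np.ndarray]:
    """Congruence-transport a set from one Karcher mean to another."""
    _, old_isq = _sqrt_pair(old_mean)
    new_sq, _ = _sqrt_pair(new_mean)
    T = new_sq @ old_isq
    out = []
    for P in mats:
        Q = T @ np.asarray(P, float) @ T.T
        out.append(0.5 * (Q + Q.T))
    return out


def riemannian_align(source, target, cfg: MeanConfig | None = None) -> AlignmentResult:
    """Whiten the source by its Karcher mean, recolor by the target's.

    Parameters
    ----------
    source, target : sequence of SPD ndarray
        Same dimension; the target may be unlabeled and small.
    cfg : MeanConfig, optional
        Settings for the two Karcher-mean solves.

    Returns
    -------
    AlignmentResult
        ``aligned_source`` has the same length and order as ``source``
        and its Karcher mean coincides with ``target_mean`` up to the
        mean-solver tolerance.
    """
    cfg = cfg or MeanConfig()
    source = [check_spd(np.asarray(m, float), f"source[{i}]") for i, m in enumerate(source)]
    target = [check_spd(np.asarray(m, float), f"target[{i}]") for i, m in enumerate(target)]
    if not source or not target:
        raise ValueError("source and target sets must be non-empty")
    d = source[0].shape[0]
    if any(m.shape[0] != d for m in source + target):
        raise ValueError("dimension mismatch between source and target sets")

    source_mean = _set_mean(source, cfg)
    target_mean = _set_mean(target, cfg)
    aligned = recenter(source, source_mean, target_mean)
    return AlignmentResult(aligned_source=aligned, source_mean=source_mean, target_mean=target_mean)
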