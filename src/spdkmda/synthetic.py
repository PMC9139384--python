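"""Seeded generators of SPD transfer problems and EEG-like raw trials.

The transfer generator emulates the cross-subject situation the
adaptation pipeline assumes: each class has an SPD prototype, samples
scatter around it by tangent-space Gaussian noise, and the target
domain sees every prototype through an unknown congruence transform
``P -> A P A^T`` plus fresh noise — so the marginal and conditional
distributions of source and target differ, while Riemannian alignment
can undo the congruence part exactly.

The raw-trial generator produces band-limited oscillations (10 Hz mu,
22 Hz beta) with class-dependent channel gains plus white noise, enough
to exercise the bandpass/Welch/E-frame stages; it does not attempt
physiological realism (no volume conduction, no artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmda import DomainDataset
from .spd_core import EEGTrial, exp_map, sym_expm

__all__ = ["TransferSpec", "sample_spd_set", "make_transfer_problem", "make_eeg_trials"]


@dataclass
class TransferSpec:
    """Parameters of a synthetic SPD transfer problem.

    class_sep is the AIRM distance scale between class prototypes,
    dispersion the tangent-noise standard deviation, shift_strength the
    magnitude of the hidden congruence transform between domains.
    """

    d: int = 6
    n_classes: int = 2
    n_source_per_class: int = 40
    n_target_per_class: int = 40
    class_sep: float = 2.0
    dispersion: float = 0.15
    shift_strength: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 2 or self.n_classes < 2:
            raise ValueError("need d >= 2 and at least 2 classes")
        if min(self.n_source_per_class, self.n_target_per_class) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.class_sep, self.dispersion, self.shift_strength) < 0:
            raise ValueError("class_sep, dispersion, shift_strength must be >= 0")


def _random_symmetric(d: int, rng: np.random.Generator) -> np.ndarray:
    """Symmetric matrix with i.i.d. standard-normal independent entries."""
    S = np.zeros((d, d))
    iu = np.triu_indices(d)
    S[iu] = rng.standard_normal(len(iu[0]))
    S = S + np.triu(S, 1).T
    return S


def _unit_symmetric(d: int, rng: np.random.Generator) -> np.ndarray:
    S = _random_symmetric(d, rng)
    return S / np.linalg.norm(S, "fro")


def sample_spd_set(prototype: np.ndarray, n: int, dispersion: float, rng) -> list[np.ndarray]:
    """Draw n SPD matrices around a prototype by tangent-space Gaussian noise.

    Each sample is ``exp_map(S, prototype)`` with S a symmetric matrix
    of independent zero-mean Gaussian entries scaled by ``dispersion``;
    the exponential map guarantees every output is SPD.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    prototype = np.asarray(prototype, float)
    d = prototype.shape[0]
    out = []
    for _ in range(n):
        S = dispersion * _random_symmetric(d, rng)
        out.append(exp_map(S, prototype))
    return out


def _class_prototypes(spec: TransferSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Prototypes at mutual AIRM distance ~ class_sep, via tangent rays from I.

    For two classes the rays are antipodal (exact commuting-case
    distance class_sep); for more classes, independent random unit
    directions give approximately class_sep / sqrt(2) * sqrt(2) spacing.
    """
    d, l = spec.d, spec.n_classes
    if l == 2:
        V = _unit_symmetric(d, rng)
        half = 0.5 * spec.class_sep
        return [sym_expm(half * V), sym_expm(-half * V)]
    dirs = [_unit_symmetric(d, rng) for _ in range(l)]
    scale = spec.class_sep / np.sqrt(2.0)
    return [sym_expm(scale * V) for V in dirs]


def make_transfer_problem(spec: TransferSpec) -> tuple[DomainDataset, np.ndarray]:
    """Build a labeled-source / unlabeled-target SPD transfer problem.

    Returns the dataset (target first, source labels attached) plus the
    hidden ground-truth target labels for evaluation only. Deterministic
    for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    protos = _class_prototypes(spec, rng)

    source, y_s = [], []
    for c, proto in enumerate(protos):
        source.extend(sample_spd_set(proto, spec.n_source_per_class, spec.dispersion, rng))
        y_s.extend([c] * spec.n_source_per_class)

    # hidden congruence shift applied to the target's view of each prototype;
    # G is scaled to Frobenius norm d/2 so that at the default
    # shift_strength the domains move further apart than the class
    # separation — enough to measurably degrade a source-only classifier —
    # while the conditioning of A stays mild enough for stable numerics
    G = (spec.d / 2.0) * _unit_symmetric(spec.d, rng)
    A = sym_expm(spec.shift_strength * G)

    target, y_t = [], []
    for c, proto in enumerate(protos):
        shifted = A @ proto @ A.T
        shifted = 0.5 * (shifted + shifted.T)
        target.extend(sample_spd_set(shifted, spec.n_target_per_class, spec.dispersion, rng))
        y_t.extend([c] * spec.n_target_per_class)

    # descriptors from real trials are trace-normalized; the generator
    # emits the same population so kernel distances behave comparably
    source = [m / np.trace(m) for m in source]
    target = [m / np.trace(m) for m in target]

    data = DomainDataset(target=target, source=source, source_labels=np.asarray(y_s))
    return data, np.asarray(y_t)


def make_eeg_trials(
    n_per_class: int = 10,
    n_channels: int = 22,
    fs: float = 250.0,
    duration_s: float = 3.0,
    n_classes: int = 2,
    noise: float = 0.5,
    seed: int = 0,
) -> tuple[list[EEGTrial], np.ndarray]:
    """EEG-like raw trials: 10 Hz and 22 Hz oscillations with class-dependent gains.

    Class c modulates which channels carry strong mu (10 Hz) versus
    beta (22 Hz) power, mimicking lateralised ERD/ERS; white noise is
    added at the given amplitude. Returns trials and their labels.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    trials, labels = [], []
    gains = rng.uniform(0.5, 1.5, size=(n_classes, n_channels, 2))
    # class-dependent emphasis: even classes boost mu on the first half
    # of the montage, odd classes boost beta on the second half
    for c in range(n_classes):
        half = n_channels // 2
        if c % 2 == 0:
            gains[c, :half, 0] *= 2.0
        else:
            gains[c, half:, 1] *= 2.0
    for c in range(n_classes):
        for i in range(n_per_class):
            phases = rng.uniform(0, 2 * np.pi, size=(n_channels, 2))
            x = (
                gains[c, :, 0:1] * np.sin(2 * np.pi * 10.0 * t[None, :] + phases[:, 0:1])
                + gains[c, :, 1:2] * np.sin(2 * np.pi * 22.0 * t[None, :] + phases[:, 1:2])
                + noise * rng.standard_normal((n_channels, t.size))
            )
            trials.append(EEGTrial(data=x, fs=fs, id=f"c{c}_t{i:03d}"))
            labels.append(c)
    return trials, np.asarray(labels)
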