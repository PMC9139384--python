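"""E-frames: 2D band-power frames from multichannel EEG trials.

With many electrodes (60, 118 channels) the trial covariance matrix —
and even its half-vectorised tangent vector — becomes too
high-dimensional for the available sample sizes. An E-frame sidesteps
this: a trial is cut into sliding-window segments, each channel's
8-30 Hz (mu + beta rhythm) band power is estimated by Welch's method,
and the per-channel powers are arranged on a small square grid that
mirrors the scalp layout of the montage. Grid cells without a mapped
electrode carry the average power of all channels. The covariance of
the resulting frame sequence is a g x g SPD descriptor (5 x 5 for the
standard 22-electrode montage) in place of a c x c one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .spd_core import EEGTrial, covariance

__all__ = [
    "ElectrodeLayout",
    "FrameSequence",
    "layout_22",
    "preprocess_bandpass",
    "trial_to_frames",
    "frames_covariance",
]


@dataclass
class ElectrodeLayout:
    """Mapping from electrode index (0-based) to a cell of a g x g grid."""

    grid_side: int
    cells: dict  # electrode index -> (row, col)

    def __post_init__(self) -> None:
        g = self.grid_side
        if g < 2:
            raise ValueError("grid_side must be >= 2")
        self.cells = {int(k): (int(r), int(c)) for k, (r, c) in self.cells.items()}
        seen = set()
        for e, (r, c) in self.cells.items():
            if not (0 <= r < g and 0 <= c < g):
                raise ValueError(f"electrode {e}: cell ({r},{c}) outside {g}x{g} grid")
            if (r, c) in seen:
                raise ValueError(f"cell ({r},{c}) assigned to more than one electrode")
            seen.add((r, c))

    @classmethod
    def from_json(cls, path) -> "ElectrodeLayout":
        with open(path) as fh:
            cfg = json.load(fh)
        return cls(grid_side=cfg["grid_side"], cells={int(k): tuple(v) for k, v in cfg["cells"].items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"grid_side": self.grid_side, "cells": {str(k): list(v) for k, v in self.cells.items()}},
                fh,
                indent=2,
            )


def layout_22() -> ElectrodeLayout:
    """The shipped 5 x 5 grid for a 22-electrode motor-imagery montage.

    Electrode 0 sits at (0,2); electrodes 1-5, 7-11 and 13-17 fill rows
    1-3; electrode 19 sits at (4,2). The remaining electrodes
    (6, 12, 18, 20, 21) and all unmapped cells take the average power.
    """
    cells = {0: (0, 2), 19: (4, 2)}
    for j, e in enumerate(range(1, 6)):
        cells[e] = (1, j)
    for j, e in enumerate(range(7, 12)):
        cells[e] = (2, j)
    for j, e in enumerate(range(13, 18)):
        cells[e] = (3, j)
    return ElectrodeLayout(grid_side=5, cells=cells)


@dataclass
class FrameSequence:
    """A list of g x g power frames cut from one trial."""

    frames: list  # of (g, g) ndarray
    trial_id: str = ""
    band: tuple = (8.0, 30.0)
    window_s: float = 1.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("frame sequence is empty")
        self.frames = [np.asarray(f, float) for f in self.frames]
        for f in self.frames:
            if not np.all(np.isfinite(f)) or np.any(f < 0):
                raise ValueError("frames must be finite and non-negative (powers)")


def preprocess_bandpass(trial: EEGTrial, order: int = 6, band=(8.0, 30.0)) -> EEGTrial:
    """Linear detrend then zero-phase Butterworth bandpass, per channel.

    Forward-backward filtering doubles the effective order and cancels
    phase distortion; the default 6th-order 8-30 Hz band isolates the
    mu and beta rhythms carrying motor-imagery ERD/ERS.
    """
    low, high = band
    if not (0 < low < high):
        raise ValueError("band must satisfy 0 < low < high")
    if trial.fs <= 2 * high:
        raise ValueError(f"band edge {high} Hz at or beyond Nyquist for fs={trial.fs}")
    x = sps.detrend(trial.data, axis=1, type="linear")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=trial.fs, output="sos")
    y = sps.sosfiltfilt(sos, x, axis=1)
    return EEGTrial(data=y, fs=trial.fs, id=trial.id)


def _band_power(x: np.ndarray, fs: float, band, window_samples: int) -> float:
    """Welch band power of a 1-D segment: integral of the PSD over the band."""
    nperseg = min(256, window_samples)
    f, pxx = sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, window="hann")
    mask = (f >= band[0]) & (f <= band[1])
    if not np.any(mask):
        return 0.0
    return float(np.trapezoid(pxx[mask], f[mask]))


def trial_to_frames(
    trial: EEGTrial,
    layout: ElectrodeLayout,
    window_s: float = 1.0,
    overlap: float = 0.5,
    band=(8.0, 30.0),
) -> FrameSequence:
    """Slice a trial into windows and map per-channel band powers onto the grid.

    Each window yields one frame: the Welch band power of channel j
    fills the grid cell the layout assigns to electrode j, and every
    cell without an electrode is filled with the mean power over all
    channels. M = floor((t - w) / step) + 1 frames are produced with
    step = w * (1 - overlap).
    """
    c, t = trial.data.shape
    w = int(round(window_s * trial.fs))
    if w < 32:
        raise ValueError("window too short: need at least 32 samples")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    if t < w:
        raise ValueError(f"trial length {t} shorter than one window ({w} samples)")
    if layout.cells and max(layout.cells) >= c:
        raise ValueError(
            f"layout references electrode {max(layout.cells)} but trial has {c} channels"
        )
    step = max(1, int(round(w * (1.0 - overlap))))
    n_frames = (t - w) // step + 1
    g = layout.grid_side
    frames = []
    for m in range(n_frames):
        seg = trial.data[:, m * step : m * step + w]
        powers = np.array([_band_power(seg[ch], trial.fs, band, w) for ch in range(c)])
        vbar = powers.mean()
        frame = np.full((g, g), vbar)
        for e, (r, col) in layout.cells.items():
            frame[r, col] = powers[e]
        frames.append(frame)
    return FrameSequence(
        frames=frames, trial_id=trial.id, band=tuple(band), window_s=window_s, overlap=overlap
    )


def frames_covariance(fs: FrameSequence, jitter: float = 1e-10) -> np.ndarray:
    """Trace-normalised covariance of a frame sequence.

    Frames are concatenated column-wise into a g x (g*M) matrix and the
    standard normalised covariance is taken, yielding a g x g SPD
    descriptor regardless of the channel count of the original trial.
    """
    F = np.hstack(fs.frames)
    return covariance(F, jitter=jitter)
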