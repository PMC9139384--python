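"""E-frames: shrinking a 22-channel trial to a 5 x 5 SPD descriptor.

Generates EEG-like oscillatory trials, bandpasses them to the 8-30 Hz
mu/beta range, slices them into windows, maps per-channel band powers
onto the scalp-layout grid, and takes the covariance of the frame
sequence — a 5 x 5 descriptor instead of 22 x 22.
"""

import numpy as np

from spdkmda import frames_covariance, layout_22, preprocess_bandpass, trial_to_frames
from spdkmda.synthetic import make_eeg_trials

trials, labels = make_eeg_trials(n_per_class=2, n_channels=22, seed=0)
trial = preprocess_bandpass(trials[0], order=6, band=(8.0, 30.0))

layout = layout_22()
seq = trial_to_frames(trial, layout, window_s=1.0, overlap=0.5, band=(8.0, 30.0))
print(f"trial {trial.data.shape} -> {len(seq.frames)} frames of {seq.frames[0].shape}")

P = frames_covariance(seq)
print(f"frame-sequence covariance: {P.shape}, trace {np.trace(P):.4f}, "
      f"min eigenvalue {np.linalg.eigvalsh(P).min():.2e} (SPD)")
c = trial.data.shape[0]
print(f"tangent-vector length falls from {c*(c+1)//2} (raw covariance) "
      f"to {5*6//2} (E-frame covariance)")
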