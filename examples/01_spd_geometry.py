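"""Covariance descriptors and the geometry of the SPD manifold.

Builds two toy EEG trials, turns them into trace-normalised covariance
descriptors, and compares the two Riemannian distances the package
uses, then averages a small set with the Karcher mean.
"""

import numpy as np

from spdkmda import EEGTrial, airm_distance, covariance, lem_distance, riemannian_mean

rng = np.random.default_rng(0)

# two 8-channel trials with different spatial correlation structure
mix_a = rng.standard_normal((8, 8))
mix_b = mix_a + 0.5 * rng.standard_normal((8, 8))
trial_a = EEGTrial(mix_a @ rng.standard_normal((8, 500)), fs=250.0, id="a")
trial_b = EEGTrial(mix_b @ rng.standard_normal((8, 500)), fs=250.0, id="b")

P, Q = covariance(trial_a), covariance(trial_b)
print(f"descriptor shape {P.shape}, trace {np.trace(P):.6f} (always 1 after normalisation)")
print(f"AIRM distance P->Q: {airm_distance(P, Q):.4f}")
print(f"LEM  distance P->Q: {lem_distance(P, Q):.4f}")
# the two metrics agree exactly only for commuting matrices; on real
# descriptors they are close but not equal

mean, info = riemannian_mean([P, Q, covariance(trial_a)])
print(f"Karcher mean of 3 descriptors converged in {info['n_iter']} iterations")
print(f"mean is equidistant-ish: d(mean,P)={airm_distance(mean, P):.4f}, "
      f"d(mean,Q)={airm_distance(mean, Q):.4f}")
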