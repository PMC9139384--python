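# Methods

## Descriptors and manifold geometry

A trial `X ∈ R^{c×t}` becomes the trace-normalised covariance
`P = XXᵀ/Tr(XXᵀ)`, an SPD matrix with unit trace. Trace normalisation
removes amplitude scale, which varies with impedance and gain and
carries no task information. If the smallest eigenvalue falls below
`1e-12` of the trace (rank-deficient trials, `t < c`), `jitter·I/d`
(default `1e-10`) is added and the trace renormalised; covariance
descriptors are therefore always strictly SPD.

Two geodesic distances are provided. The affine-invariant metric
(AIRM) `δ(P,Q) = ‖log(P^{-1/2} Q P^{-1/2})‖_F = sqrt(Σ log² λᵢ(P⁻¹Q))`
is invariant under congruences `P ↦ APAᵀ` and is used wherever that
invariance matters (alignment, MDRM, Karcher means). The log-Euclidean
metric (LEM) `δ(P,Q) = ‖log P − log Q‖_F` costs one eigendecomposition
per matrix instead of per pair and — crucially — yields a positive
definite Gaussian kernel, so it backs the RKHS embedding. The two agree
exactly on commuting matrices.

All matrix logs/exps go through symmetric eigendecomposition
`U diag(f(λ)) Uᵀ`, with eigenvalues floored at `1e-14·λ_max` before the
logarithm.

### Karcher mean

The Riemannian mean minimises `Σᵢ δ²(M, Pᵢ)` and is computed by the
classic tangent-average iteration: log-map all matrices at the current
estimate, average, exp-map back. Two numerical choices differ from the
textbook scheme:

- **Initialisation** at the arithmetic mean rather than the identity —
  it starts far closer to the solution for realistic sets (an
  identity-start flag is kept for comparison; both converge to the same
  fixed point).
- **Half steps.** The undamped iteration map can have contraction modes
  arbitrarily close to −1 on widely spread sets, which shows up as slow
  sign-alternating convergence or a limit cycle. Stepping half-way maps
  every mode `λ ∈ (−1, 1]` to the non-negative rate `1 − (1−λ)/2`, so
  convergence is monotone for any input at the cost of roughly doubling
  the iteration count on easy sets. If the Riemannian gradient norm
  ever grows, the step is damped further by 0.75× (floor 0.1).

Defaults: `eps = 1e-8` on the Frobenius change between estimates,
`max_iter = 100`. Extremely eccentric sets (AIRM diameter ≫ class
scales, e.g. strong simulated shifts with high dispersion) can still
exhaust the budget; the solver then returns the last iterate — already
accurate to ~1e-7 — with a warning flag rather than failing.

## Riemannian alignment

Source descriptors are whitened by the source Karcher mean and
recolored by the target's. Because both stages are congruences and the
AIRM mean is congruence-equivariant, the aligned source mean coincides
with the target mean to solver tolerance — the transport is exact, not
approximate. A singleton target set uses its one matrix as the mean
without iterating. Alignment is idempotent up to solver tolerance.

## Kernel and subspace learning

The log-Euclidean Gaussian kernel
`κ(P,Q) = exp(−‖log P − log Q‖²_F / 2σ²)` is positive definite for all
σ > 0 because the squared LEM distance is negative definite. Matrix
logs are cached per matrix, so an n-set Gram matrix costs n
eigendecompositions plus one dense multiply.

**Bandwidth.** σ defaults to the median pairwise LEM distance over the
pooled (target ∪ aligned source) set — scale-free and standard. Sets
with more than 500 pairs are subsampled with a fixed seed; a degenerate
all-equal set falls back to σ = 1 with a warning.

**Objective.** With the joint Gram `K` ordered target-first,
`Θ = blockdiag(α·St, β·Sb)` collects the terms to maximise — target
variance `St = K_t H_t K_tᵀ` (H_t the centering matrix) and source
between-class scatter `Sb = Σ_c N_s^{(c)} (m^{(c)} − m̄)(m^{(c)} − m̄)ᵀ`
on kernel columns — and
`Ψ = Σ_c (μ·K M_c K + β·S_w^{(c)}) + ρI` the terms to minimise:
class-conditional MMD matrices `M_c` (entries `1/N_t^{(c)2}`,
`1/N_s^{(c)2}`, `−1/(N_s^{(c)}N_t^{(c)})` over same-class pairs) and
per-class within scatters embedded in the source block. `Tr(Wᵀ K M_c K W)`
equals the squared distance between the class-c embedded means of the
two domains, which is what makes the pseudo-label loop meaningful. The
kernelised MMD term uses the symmetric sandwich `K M_c K`; a
single-sided multiplication would produce an asymmetric matrix and an
ill-posed eigenproblem.

**Ridge.** `ρ` defaults to `1e-3·Tr(Ψ₀)/N`; if Ψ is still not positive
definite the ridge grows tenfold up to three times before erroring.

**Solver.** `W` holds the `k` leading generalized eigenvectors of
`Θw = λΨw` (scipy's symmetric-definite solver), Ψ-orthonormal
(`WᵀΨW = I`) with a deterministic sign convention (largest-magnitude
entry positive). `k` defaults to `d`, the SPD matrix size.

**Feature standardisation.** Embedded features `z = WᵀK` are
standardised per dimension (zero mean, unit variance over the training
pool) before the kNN stage, in both fitting and prediction.
Ψ-orthonormal eigenvectors carry arbitrary per-direction scales —
directions where Ψ is near its ridge floor come out inflated by
`~ρ^{-1/2}` — and a Euclidean kNN would otherwise be dominated by those
noise directions. This is ordinary feature scaling ahead of a
scale-sensitive classifier, not a change to the learned subspace.

**Iteration.** Pseudo-labels start from MDRM on the aligned source
(AIRM metric; LEM available by flag) and are refined each round by
kNN with k = 3 and fully deterministic tie-breaks (majority vote →
smaller mean distance → lower label). `St`, `Sb`, `S_w` depend only on
fixed quantities and are built once; only the `M_c` are rebuilt from
the current pseudo-labels. The loop stops as soon as no label changes,
or after T = 15 rounds (trade-offs α = μ = 1, β = 0.1). A class absent
from the current pseudo-labels contributes a zero `M_c` for that round
rather than aborting. Fitting is fully deterministic — all randomness
lives in the data generator's seed.

**Prediction** computes kernel columns of new (already target-frame)
matrices against the stored training set, embeds with the stored `W`
and standardisation, and votes against the stored source embeddings.
Predicting the training targets reproduces the final pseudo-labels
exactly.

## E-frames

Per-channel 8–30 Hz band power (linear detrend → 6th-order zero-phase
Butterworth bandpass → Welch PSD with Hann taper, segment length
min(256, window), 50% inner overlap → PSD integral over the band) is
computed on sliding windows (default 1.0 s, 50% overlap — the window
parameters are configurable since no canonical values exist) and placed
on a `g×g` grid mirroring the scalp layout; cells without an electrode
take the mean power over all channels. The covariance of the
horizontally concatenated frame sequence is a `g×g` SPD descriptor —
5×5 for the shipped 22-electrode layout — shrinking the tangent-space
dimension from `c(c+1)/2` to `g(g+1)/2` (253 → 15 for 22 channels,
7021 → 66 for 118 channels at g = 11). Layouts for other montages are
supplied as JSON (`{"grid_side": g, "cells": {"<electrode>": [row, col]}}`).
The shipped 22-electrode map places electrode 0 at (0,2), electrodes
1–5, 7–11 and 13–17 across rows 1–3, and electrode 19 at (4,2); the
remaining electrodes are deliberately unmapped and average-filled, and
the assignment is configurable because physical montages differ.

## Synthetic generator

`make_transfer_problem` draws `l` class prototypes as exponentials of
random tangent directions at the identity — for two classes, antipodal
directions `exp(±(class_sep/2)·V)`, which commute, so their AIRM
distance is exactly `class_sep`. Samples scatter around each prototype
by `exp_map` of symmetric Gaussian tangent noise (entrywise std =
`dispersion`), guaranteeing SPD outputs at any noise level. The target
domain sees every prototype through a hidden congruence
`A = exp(shift_strength·G)` with `G` scaled to Frobenius norm `d/2`,
chosen so that at the default `shift_strength = 0.6` the domain
displacement exceeds the class separation — large enough that a
source-only classifier is measurably degraded and alignment visibly
repairs it — while `A`'s conditioning stays mild. All emitted matrices
are trace-normalised, matching the population of real covariance
descriptors. Defaults (d = 6, 2 classes, 40 source + 40 target per
class, separation 2, dispersion 0.15, shift 0.6, seed 0) are the
package's reference study conditions used by the test suite and the
acceptance script.

What the generator does *not* emulate: non-congruence domain shifts
(e.g. per-class conditional drifts that alignment cannot remove),
non-stationarity within a session, artifacts, volume conduction, or
realistic eigenvalue spectra of EEG covariances. Passing tests
demonstrate that the pipeline recovers the transformation family it is
built to invert, under realistic noise — not that it reaches any
particular accuracy on real recordings.

`make_eeg_trials` produces band-limited oscillations (10 Hz mu, 22 Hz
beta) with class-dependent channel gains plus white noise — enough to
exercise the bandpass/Welch/E-frame stack end to end, nothing more.

## Problem sizes

The default test and acceptance workloads use d = 6 descriptors with
160 matrices per transfer problem, 20-seed kernel property sweeps, and
5-replicate end-to-end averages; the full suite runs in well under a
minute and the acceptance script in seconds on one CPU.

## Known limitations

- The kernel bandwidth and ridge are heuristics; the original
  formulation leaves both unspecified, and real-data behaviour can be
  sensitive to them.
- MDRM initialisation with heavily overlapping classes can start the
  pseudo-label loop in a poor basin; the loop has no restart mechanism.
- Only a single source domain is supported; no negative-transfer
  detection or source weighting.
- The supervised-target variant (running one loop round with true
  target labels) exists as a code path but is not validated against any
  external benchmark.
- Real BCI-competition recordings are outside the test surface; no
  downloader or GDF/MAT reader is bundled.
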