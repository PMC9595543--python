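# Methods

## Problem and model

`megspike` delineates the irritative zone (IZ) — the cortical territory
generating interictal epileptiform discharges — from MEG sensor recordings,
without visual spike marking. The pipeline rests on one structural
assumption: an interictal spike source is a fixed cortical generator whose
sensor footprint is a rank-1 spatiotemporal pattern, a spatial topography
`u` (how the source projects onto the sensor array) times a stereotyped
waveform `v` (the spike morphology), repeating over the recording.

Processing has two stages, run separately for gradiometers and
magnetometers:

**Stage I — candidate detection.** The recording is resampled to 200 Hz and
band-passed 2–90 Hz (zero-phase Hamming-window FIR). FastICA extracts 20
components; among the first 10 by explained variance, a component is kept
when its time course is "peaky" (excess kurtosis in [1, 10]) and its
topography is dipolar (single-dipole MUSIC goodness of fit ≥ 0.80 for
magnetometers, ≥ 0.60 for gradiometers), or when GOF > 0.95 regardless of
kurtosis. Kept components are band-passed 20–90 Hz, robust-scaled
(median/IQR), and peaks of the absolute scaled signal are collected with a
threshold lowered along the grid {8, 7, 6, 5, 4, 3, 2.5, 2} until at least
300 peaks are pooled. Each peak is scored by MUSIC on the −20..+30 ms
sensor window; a greedy sweep in descending GOF keeps at most one event per
0.5 s.

**Stage II — clustering by convolutional sparse coding.** One-second
epochs centered on the Stage-I timestamps form a tensor `X [N × C × T]`,
decomposed into K = 3 rank-1 atoms by minimizing

    Σ_n ½‖Xⁿ − Σ_k z_kⁿ * (u_k v_kᵀ)‖² + λ Σ_k ‖z_kⁿ‖₁,
    s.t. ‖u_k‖² ≤ 1, ‖v_k‖² ≤ 1, z_kⁿ ≥ 0,

with λ = 0.1 and atom length 0.5 s (100 samples). Events are assigned to an
atom by thresholding its per-epoch maximal activation at 7 MAD of the
pooled nonzero activations, lowering along {7, 6, 5, 4, 3, 2.5, 2, 1.5}
until ≥ 15 events. Four runs — all selected components first, then one
k-means topography group per run — give 12 candidate atoms per sensor type.
Each candidate is scored by the mean of three 0–1 features: MUSIC GOF of
`u`; mean correlation of the assigned epochs' best-channel trace with
`u[best]·v` at the activation latency (negatives clipped); and event count
saturating at 20. Atoms above mean + 1 SD of the candidate scores are
selected; a config exclusion list stands in for visual review.

**Localization and validation.** The average of an atom's events (re-cut
±0.5 s around the assigned peaks) is localized by Tikhonov-regularized
minimum-norm estimation with a diagonal noise covariance taken as the
per-channel variance of the averaged window. Activation maps are computed
at PEAK (maximum global field power) and SLOPE (first sample of the
ascending branch at ≥ 50 % of peak GFP), binarized at 50 % of the maximum,
summed over atoms of both sensor types, thresholded at strictly more than
half the atoms, and dilated by 10 mm (Euclidean, on vertex coordinates).
Visually marked spikes, when provided, are localized individually at their
marked peak; vertices present in at least half the single-spike maps are
kept and dilated the same way. Validation converts the resected area into a
convex hull and reports the mean signed Euclidean distance of the IZ
vertices from the hull surface (negative inside); estimate types are
compared across subjects with a two-sided paired Wilcoxon signed-rank test,
exact for n ≤ 25.

## Numerical choices

* **CSC solver.** Alternating minimization. z-step: cyclic coordinate
  descent on the non-negative convolutional lasso per epoch (closed-form
  coordinate updates with an incrementally maintained Gram correlation;
  compiled with numba). (u, v)-step: exact block minimizers — `u` is an
  isotropic least-squares solution projected onto the unit ball; `v` solves
  a Toeplitz system, with a boundary solution found by bisection on the
  ridge multiplier when the unconstrained optimum leaves the ball. Every
  step decreases the objective, so the iteration is monotone; it stops
  after 30 outer iterations or a relative decrease below 1e-5. Signs are
  fixed by making the extremal sample of `v` positive.
* **Initialization.** The alternating scheme has local minima in which one
  atom absorbs two sources. Each epoch is summarized by the rank-1 SVD of
  the window around its absolute peak; the resulting spatial patterns are
  grouped by a sign-invariant k-means (centroids are principal eigenvectors
  of their members) and each atom starts from one group's centroid and its
  strongest member's waveform. Three seeded restarts (varying the initial
  assignment) are fitted and the lowest final objective wins. In planted-
  source experiments this initialization recovers well-separated sources
  reliably where random epoch windows did not.
* **MAD degeneracy.** With exactly repeating sparse activations the MAD of
  the pooled nonzero activations can be 0; then every epoch with a strictly
  positive activation is assigned. Real activations have a continuum of
  values and use the 7→1.5 schedule.
* **MUSIC.** Signal subspace dimension 1 (single-dipole assumption) for
  both event windows and topographies; GOF is the squared cosine of the
  principal angle between the vertex leadfield span (1 or 3 columns) and
  the signal subspace, invariant to scale and sign.
* **Inverse.** `W = G_wᵀ(G_w G_wᵀ + λ² μ I)⁻¹` in whitened coordinates,
  with μ the mean diagonal of the whitened sensor Gram so λ² is
  dimensionless; default λ² = 1/9 (SNR ≈ 3 convention). Free orientations
  are combined by the Euclidean norm per vertex.
* **SLOPE.** Operationalized as the first ascending-branch sample at ≥ 50 %
  of peak GFP (the latest strictly-below-half sample plus one); an averaged
  waveform peaking at the window edge is flagged and the atom skipped.
* **Voting.** "More than half of the atoms" is a strict inequality;
  "at least half of the individual spike maps" is non-strict — both as
  worded. Smoothing is Euclidean dilation, not geodesic.
* **Hull distances.** Interior points use the minimum facet-plane distance
  (exact for convex bodies); exterior points the minimum point-to-triangle
  distance over hull facets (vectorized Voronoi-region algorithm). Degenerate
  (coplanar) resections are rejected.
* **Seeding.** One integer seed drives everything; per-stage and per-restart
  seeds derive from it through `numpy.random.SeedSequence`, so reruns are
  bit-identical.

## Synthetic data

The generator emulates the target regime: 10–20 minute, 200 Hz recordings
in which a few focal sources emit brief spikes a few times per minute.
Sources sit on an 80 mm hemispheric shell, sensors on a 110 mm helmet
shell; leadfield columns are tangential current-dipole field patterns —
smooth, dipolar, mutually distinguishable (max off-diagonal column
correlation < 0.99), without BEM realism. The spike template is a sharp
biphasic transient (derivative of a Gaussian, σ = width/20) followed by a
slower after-wave, the whole complex spanning 70–200 ms; the sharp
component keeps energy in the 20–90 Hz band, as real interictal spikes do —
a pure Gaussian-derivative of that duration would be invisible to the
pipeline's peak-detection band. Events are Poisson-placed and thinned to a
global ≥ 0.5 s separation; the background is 1/f-shaped Gaussian noise,
unit variance per channel; `snr` is the spike's peak amplitude over the
background RMS at the atom's best channel. Defaults used in the tests and
the acceptance script: 2–4 sources, 3–6 spikes/min each, SNR 4–6 — spike
rates and counts of the order reported for clinical recordings (a few per
minute, tens per cluster).

What the generator does not emulate: realistic head conductor geometry,
source extent and propagation, non-stationary background (sleep spindles,
artifacts), sensor noise correlations, tSSS residuals. Passing tests
therefore show correctness of the algorithmic chain and its behavior under
the rank-1 repeating-spike model, not clinical performance.

## Problem sizes

Unit tests run on 60-channel / 300-vertex fixtures with 5–20 minute
recordings; the structural-counts check and the MUSIC localization bound
run at the full 204-channel / 500-vertex, 20-minute scale. A complete
single-sensor-type pipeline pass (20 min × 204 ch × 200 Hz, 4 runs × 3
atoms) takes on the order of 1–2 minutes on one CPU.

## Known limitations

* The CSC objective is the plain squared-error form; heavy-tailed noise
  modelling is out of scope, so bursty artifacts can claim atoms (the
  exclusion list is the mitigation).
* Atom recovery degrades when two sources are closely spaced (~40 mm) with
  near-identical waveforms; the restart/selection heuristic reduces but does
  not eliminate merged-source fits.
* k-means topography grouping uses k = 3 with one group per extra run; the
  mapping of groups to runs is a convention.
* Dilation is Euclidean, which can leak across sulci where geodesic
  distance is much larger.
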