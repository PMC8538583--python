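# Methods

This note records the model assumptions, the defaults the method itself
leaves open, the numerical choices, and what the synthetic phantoms do and
do not establish.

## Pipeline model

The identification model treats a vascular image as a texture source: the
spatial statistics of dark curvilinear vessels over a bright background
are assumed stable across repeated acquisitions of one person and
distinctive between people. No vessel segmentation or geometric matching
is performed; discrimination rests entirely on local binary pattern (LBP)
statistics computed at multiple scales and under several fixed image
perturbations.

The filter bank serves feature diversification, not denoising: rotations
re-sample the same texture at fixed orientations, the median and Gaussian
filters provide smoothed views, and the speckle operator deliberately
injects multiplicative noise so that a noise-perturbed view contributes
its own histogram. Max-pooling with windows 2..32 provides the scale
sweep; because the maximum over a 2^t block equals t nested 2 × 2 maxima,
pooling the original at window 2^t and pooling recursively are the same
operator (a property the tests verify bitwise).

## Frozen conventions

* **Intensity scale.** Images decode to 8-bit and are divided by 255.
  This fixes the speckle-noise variance scale (0.05 on a [0, 1] signal)
  and the clipping range after noise. Whether to clip or rescale noisy
  images is an open choice; clipping to [0, 1] was chosen and is the only
  interpretation under which intensities stay in the declared range.
* **Median/Gaussian padding.** Median: zero padding. Gaussian: σ = 0.5,
  radius ceil(2σ) (3 × 3 kernel), replicate padding, kernel normalized to
  sum 1. Both configurable (`gaussian_sigma`, `median_window`).
* **LBP variant.** Upright (non-rotation-invariant) uniform LBP, 8
  neighbors, radius 1, diagonal neighbors by bilinear interpolation, tie
  rule *neighbor ≥ center → 1*, bits packed most-significant-first
  starting at the right neighbor and proceeding counter-clockwise, 59
  bins (58 uniform codes ascending + catch-all), Euclidean histogram
  normalization. Any consistent bit convention spans the same feature
  space; one must be frozen for reproducibility, and tests pin this one
  against a naive per-pixel oracle and, up to bin permutation, against
  scikit-image's `nri_uniform` implementation.
* **Minimum image size.** Level-5 pooling divides each side by 32 and the
  LBP needs a 3 × 3 interior, so the full pipeline requires sides ≥ 96
  (and divisibility by 32; the loader center-crops to enforce the
  latter). 512 × 512 inputs pool to 16 × 16 at the coarsest level.

## NCA optimizer

The selector maximizes
`F(w) = (1/n) Σᵢ pᵢ − λ Σᵣ wᵣ²`, with `pᵢⱼ ∝ exp(−d_w(xᵢ,xⱼ)/σ)`,
`pᵢᵢ = 0`, `d_w` the wᵣ²-weighted L1 distance, by per-sample stochastic
gradient ascent: one pass over the samples per epoch in shuffled order.
Defaults: λ = 1/n, σ = 1, initial weights all 1, 20 epochs. The initial
step size is 0.1 and halves every 5 epochs (a piecewise-constant decay;
the step size is the one optimizer constant the method description leaves
fully open, and 0.1 with halving converges on all tested problem sizes —
the per-epoch exact objective trace is recorded so convergence is
auditable). Softmax terms are computed after subtracting the row minimum
distance, so large weighted distances cannot underflow to a 0/0; should
every term still underflow the row falls back to a uniform distribution.
Weights are reported as absolute values: the model only ever sees wᵣ², so
the sign is meaningless, and relevance is defined as wᵣ². Selection keeps
the ceil(d/6) features of largest relevance, ties to the lower column
index; with d = 2478 this is exactly 413.

Selection is fit **once on the full matrix before cross-validation**,
reproducing the select-then-classify protocol the pipeline evaluates.
This leaks test information into the selector; the `nested_selection`
option refits NCA inside each training fold for a leakage-free estimate,
and a paired-seed test checks that the nested estimate does not exceed
the leaky one in most seeds.

## Classifier and metrics

1-NN, Euclidean, per-fold column standardization by training-fold
mean/std (zero-variance columns pass through unscaled — dividing by 1
avoids an undefined operation and cannot change distances), distance ties
to the lower training index, stratified 10-fold CV with a fixed seed.
Stratification is required: with ~40 frames per subject and 10 folds,
unstratified folds could drop a subject from a training fold entirely.
Pooled predictions feed a confusion matrix; macro metrics average
per-class values (absent predicted classes contribute precision 0), micro
metrics equal accuracy for single-label problems. Reported percentages
are rounded to 2 decimals; full precision is kept internally. Per-subject
recall is computed from the pooled CV predictions.

## Synthetic phantoms

Each subject is a random recursive binary vessel tree (depth 5, entry at
the top border, branch angles within ±40°, child length ratio
0.6–0.85, child width ratio 0.6–0.8, initial width 8 px at the 512
reference size, stroke contrast depth 0.35–0.55). A frame renders the
subject's fixed tree over a bright background (0.75 base plus a smooth
low-frequency field of amplitude 0.05), subtracts the anti-aliased
strokes scaled by a per-frame contrast factor, then applies per-frame
similarity jitter, σ = 1 Gaussian blur, and additive Gaussian noise.

Default study conditions: **12 subjects × 24 frames × 512 px**, rotation
jitter ±2°, translation ±4 px, contrast factor U(0.9, 1.1), noise
σ = 0.02, master seed 7. The frame count approximates the ~42 frames per
subject of a realistic acquisition database scaled down so the full study
runs in about two minutes; `--paper-scale` provides the 51 × 42
database-shaped variant (tens of minutes of compute). Jitter magnitudes
model small table/gantry differences between runs of one acquisition;
they were fixed once as realistic values, and a three-level sweep
(2°/4 px/0.02 → 8°/16 px/0.06 → 20°/40 px/0.15) verifies that accuracy
degrades monotonically as acquisition stability is destroyed.

All randomness derives from `SeedSequence(master_seed, spawn_key)`
children — subject s uses key (s,), frame f of subject s uses (s, f) —
so a dataset regenerates byte-identically from its seed, independently of
generation order.

**What the phantoms do not model:** projection/fluoroscopy physics,
contrast-agent dynamics, anatomy change between sessions, pathology,
background organs, or inter-subject similarity in global vessel layout.
Phantom accuracy therefore validates the pipeline's mechanics and its
sensitivity ordering (more jitter → worse), not clinical-grade biometric
performance; real-database performance must be measured with the
`benchmark` command on real data.

## Problem sizes used in the shipped checks

Unit oracles run on 8–32 px arrays. The end-to-end check uses the default
12 × 24 × 512 px study; the jitter sweep uses 8 × 12 × 128 px (the
ordering, not the absolute accuracy, is under test there); NCA recovery
uses n = 100, d = 100 with 10 planted features over 10 seeds. These sizes
are the package's chosen trade-off between statistical resolution and a
test suite that completes in minutes.

## Known limitations

* The NCA SGD pass is O(n²·d) per epoch; at thousands of samples with
  2478 features a full `benchmark` run takes tens of minutes.
* The per-epoch exact objective evaluation doubles NCA cost; it is kept
  because an auditable convergence trace is worth more here than speed.
* Histogram normalization before concatenation means bundle members with
  few interior pixels (coarse pooling levels) carry the same weight as
  full-resolution members.
* The speckle filter consumes one stream draw per image in dataset order;
  inserting or removing a sample shifts all later speckle noise (the
  feature matrix is reproducible per dataset, not per image).
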