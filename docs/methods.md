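# Methods

## The model

The package trains an unconditional GAN to synthesize radiograph-like
dental images and regularizes the generator with a spatial-coherence term
motivated by dental pulp physiology. The generator objective is a weighted
sum

    L_G = 0.4 · L_adv + 0.25 · L_pixel + 0.35 · L_spatial

where `L_adv` is binary cross-entropy against the discriminator (a
Wasserstein critic mode is available), `L_pixel` is a reconstruction term
active only in paired mode (below), and `L_spatial` is one of six
registered constraints: the pulp loss, total variation, bilateral
affinity, L2 smoothness, a perceptual feature distance, or none. The
discriminator loss adds a gradient penalty `10 · E[(‖∇_x D(x̂)‖ − 1)²]` on
real/fake interpolates. Optimization is Adam(2e−4, β₁ 0.5, β₂ 0.999),
batch 16, with the learning rate halved at the decay epoch
(`lr(e) = lr₀ · 0.5^[e ≥ e_decay]`, defaults 200 epochs / decay at 100).

### Pulp loss

    L_pulp = λ · (1/|Ω|) Σ_{(i,j)} Σ_{p∈N(i,j)} w(d)·‖G_ij − G_p‖²·M(i,j,p)

- **Neighbourhood.** 8-connected, ordered pairs (each unordered pair
  counted twice); neighbourhoods are clipped at image borders rather than
  padded, so no intensities are fabricated. A 4-connected variant exists
  for ablation.
- **Distance weight.** `w(d) = exp(−d²/(2σ²))` with σ = 1.5 px. Biological
  coupling between odontoblasts decays over 50–200 µm; at radiograph
  resolutions of 0.1–0.3 mm/px that is sub-pixel to ≈2 px, which fixes the
  default.
- **Anatomical mask.** `M = α·m_enamel + β·m_dentin + γ·m_boundary` with
  (α, β, γ) = (0.5, 0.3, 0.2). The published form is written on pixel
  *pairs* while masks are per-pixel; the package defines each per-tissue
  pair indicator as the AND of the two endpoint values (symmetric, keeps
  M ≤ α+β+γ, and zero across tissue borders except through the boundary
  band). OR and endpoint-average rules are available behind an enum since
  the intended convention is not derivable from the source material.
- **Normalization.** The leading factor is implemented as `λ/|Ω|`
  (`mean_over_pixels`), making λ resolution-independent; a raw `sum` mode
  is provided. Under `sum` mode with w≡1 and M≡1 the loss reduces exactly
  to the L2-smoothness constraint — the identity the ablation grid's
  "all components off" row relies on, and a test oracle.
- **Multi-channel images** are scored per channel and averaged, keeping
  the scale comparable to grayscale.

Masks for *generated* images during training are propagated from the real
images sampled in the same step, mirroring the guidance-propagation idea
for unconditional synthesis; at evaluation/gating time the caller supplies
masks (for phantoms, the ground truth).

### Comparison regularizers

TV uses forward differences without wraparound. The bilateral affinity is
implemented literally as published — `exp(−‖ΔI‖²/σ_r²)·exp(−d²/σ_s²)`
over ordered 8-neighbour pairs, denominators σ² without a factor 2. As
printed the term *rewards* similarity (it is maximal for constant images);
since the intended form is ambiguous, a `weighted_difference` variant
multiplying by ‖ΔI‖² ships behind a flag, and neither is asserted to be
"the" method. The perceptual loss is `Σ_l ‖φ_l(A)−φ_l(B)‖²/(C_l H_l W_l)`
over a pluggable extractor; tests and training use a small fixed-seed
random-weight convolutional stack so nothing is downloaded, and a
pre-trained deep extractor can be plugged in at run time.

### Architecture

The generator maps a latent vector (default 128; 100 is also supported, as
both appear in the source tables) through a dense projection to 4×4
features, then stride-2 transposed convolutions to the output resolution,
with densely connected blocks (growth rates 64/32/16/8, four internal 3×3
convolutions, a 3×3 transition back to the stage width, optional identity
skip) after every upsampling stage but the last, then two refinement
convolutions and a tanh head. Transposed convolutions use kernel 4 — the
printed transpose parameter counts imply a non-integer kernel and cannot
be matched, so kernel 4 (checkerboard-safe, doubles resolution exactly)
was chosen and those counts are not treated as ground truth. The
discriminator alternates stride-2/stride-1 3×3 convolutions through a
64-128-256-512 schedule, then flatten → dense(512) → dropout (0.3 by
default; 0.4 also appears in print) → dense(1) → sigmoid.

Convolutions are bias-free: under that convention every printed 3×3
convolution count equals `in·out·k²` exactly (1,728 … 2,359,296), and the
final dense row equals `512·1+1 = 513`; `count_layer_parameters`
reproduces these as worked examples. A `width_multiplier` scales all
channel counts so the same topology trains at desk scale (1/32 of the
reference width in the test protocol).

**Initialization.** Generator weights are He-scaled (keeps contrast
through the deep upsampling stack at small widths). Discriminator weights
are drawn N(0, 0.02), the standard initialization for this convolutional
GAN family; He initialization compounded through the channel schedule
gives input-gradient norms of order 10 at initialization, which makes the
gradient penalty dominate the critic loss from the first step.

### Training-loop conventions

- The generator is unconditional (noise → image), but pixel, perceptual
  and PSNR terms need a reference. In *paired mode* each noise vector is
  tied to a template real image. In the default pure-noise mode those
  weights are forced to 0 and the remaining (adversarial, pulp) weights
  are rescaled to preserve the configured total.
- Feature matching on discriminator features is implemented but defaults
  to weight 0: at its published magnitude (10.0) its gradient is ~400×
  the pulp term's and erases the 0.4/0.25/0.35 balance that defines the
  objective. Set `weights.feature_matching` to enable it.
- Both adversarial modes share the gradient-penalty formulation; the
  penalty needs second-order differentiation, which the autodiff engine
  supports by expressing every vector-Jacobian product in terms of
  primitives.
- One global run seed drives named substreams (init, noise, augmentation,
  interpolates, batching, evaluation) via seed-sequence spawning, so runs
  are exactly reproducible and substreams independent of each other.
- Augmentation: rotation ±15°·intensity, horizontal flip with
  p = 0.5·intensity, brightness ±20%·intensity (default intensity 0.75);
  masks receive the identical geometric transforms and no photometric
  ones.
- The Inception Score used for mode-collapse monitoring is computed every
  5 epochs (configurable) with the desk-scale classifier and linearly
  interpolated between evaluations; an epoch is flagged when IS falls
  more than 30% below the maximum of the preceding 50-epoch window. Loss
  stability is summarized by the coefficient of variation (population
  SD / mean) of post-warm-up trajectories.

### Quality gate

A generated image enters the augmented dataset only if its pulp loss is
≤ τ. τ is either absolute or, by default, the 95th percentile of the real
set's pulp losses — the published rule states the criterion but not the
threshold, so the percentile form (which adapts to image scale and noise
level) is the package's documented choice.

### Segmentation pipeline

Preprocess (min-max to [0,1], histogram equalization with 256 bins;
constant images pass through unchanged by convention) → overlapping
patches (256 px, 50% overlap; the last patch per axis is snapped flush
with the border; images smaller than a patch are reflect-padded) →
patch-wise inference by any segmenter satisfying the patch-in/probability
-patch-out contract → fusion → 0.5 threshold → morphological closing
(disk radius 2) and removal of 8-connected components under 16 px.

The published fusion algorithm exists only as a figure; the operator here
is a documented reconstruction: separable Hann windows per patch, floored
at 1e−3 so border pixels keep support, with the applied weights
renormalized to sum to one at every pixel. This makes fusion a convex
combination (partition of unity), so a single identity patch reconstructs
its input exactly and overlap seams blend smoothly. Coordinates are
0-based, half-open, row-major throughout.

The bundled `MinimalUNet` (depth ≤ 3 encoder-decoder with skip
connections, Dice-BCE objective) is a deliberately small stand-in for the
heavyweight segmentation baselines, sufficient to demonstrate the
augmentation effect. Its `fit` default learning rate is 3e−3: the
desk-scale protocol trains for only 200 steps, and at the GAN's 2e−4 a
~1%-foreground problem cannot escape the all-background solution in that
budget.

## The phantom generator

Phantoms emulate the features of panoramic radiographs the losses and
masks rely on: tooth-shaped ellipse composites with a bright enamel rim,
darker dentin core and a boundary band of configurable thickness between
them (obtained by constrained dilation of the core, since the source
never defines how the boundary mask is produced); optional dark lesion
blobs confined to tooth tissue; a smooth vertical background gradient;
additive Gaussian noise; intensities quantized to the output bit depth so
PNG round-trips are bit-identical. Per-sample RNG streams derive from
(seed, index), so a dataset is reproducible independent of its size.

They do **not** emulate X-ray physics, overlapping anatomy, jaw
curvature, device artifacts, or realistic lesion morphology. Passing
tests therefore demonstrate that the machinery is correct and that the
regularization/augmentation mechanisms behave as designed on controlled
data — not that clinical-scale image quality or segmentation accuracy is
reproduced.

## Desk-scale study conditions

The stochastic checks run a fixed protocol chosen to exercise the full
training dynamics on one CPU in minutes: 16 phantoms at 32×32, generator
and discriminator at 1/32 width (latent 16), 20 epochs, batch 16, five
seeds, with paired seeds between the pulp-on (λ = 0.35) and pulp-off
(λ = 0) arms; the segmentation comparison trains the minimal segmenter
(width 4) for 200 steps on 16 real phantoms versus 16 real + 64
gate-accepted synthetic phantoms and evaluates median Dice on 16 held-out
phantoms. `scripts/acceptance.py` re-runs exactly this protocol.

At these sizes the headline clinical-scale numbers of full 200-epoch GPU
training are out of reach by design; the properties asserted are
directional: finite, stable losses; lower median generated-image pulp
loss with the regularizer on; gate-accepted augmentation not reducing
held-out Dice.

## Numerical choices

- All computation in float64; loss oracles agree to 1e−9 relative,
  analytic gradients to 1e−4 of central differences (step 1e−4).
- FID uses `scipy.linalg.sqrtm` on Σ_r Σ_g; small negative residue from
  rank-deficient covariances is clipped within a dimension-scaled
  tolerance, larger violations raise. The eigendecomposition route is the
  independent oracle in tests. The prose mention of a covariance scaling
  factor is not in the printed formula and is not implemented.
- IS treats 0·log 0 as 0 and is computed on a single split by default.
- PSNR of identical images is reported as a documented 99 dB cap.
- F1 is computed as 2TP/(2TP+FP+FN) so the F1 ≡ Dice identity is exact in
  floating point; undefined metrics are reported as None, never as 0.
- Batch-norm statistics are per-batch in training and running averages in
  evaluation; checkpoints store parameters and buffers, so reloaded
  generators reproduce outputs bit-identically under fixed noise.

## Known limitations

- The desk-scale feature extractor and classifier are random-weight
  networks: FID/IS values are internally consistent but not comparable to
  published numbers computed with pre-trained embeddings.
- The bilateral constraint's printed form rewards similarity; whether
  that is intended is undecidable from the source, so both readings ship.
- Dense-block internal layer counts are a documented reconstruction; the
  printed dense/transpose parameter counts of the generator table are
  internally inconsistent and are not asserted anywhere.
- The asymmetric real/fake batch sizes mentioned in one configuration
  table are exposed as an option but default to symmetric batches.
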