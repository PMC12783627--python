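# pulpgan

Spatially regularized GAN augmentation and patch-based caries segmentation
for dental radiographs.

Pediatric panoramic radiograph datasets are small (a few hundred annotated
images is typical), which limits the segmentation networks trained on them.
One remedy is to augment the training set with GAN-synthesized radiographs —
but unconstrained adversarial generators produce pixel-level artifacts and
anatomically implausible tissue, which hurt rather than help the downstream
segmenter. `pulpgan` implements a biologically motivated spatial-coherence
loss that addresses this, together with everything needed to use and
evaluate it: the comparison regularizers, the generator/discriminator
architecture with exact parameter accounting, a multi-loss training loop
with quality gating, generation metrics (FID, IS, PSNR), and a patch-based
panorama segmentation pipeline. A seeded phantom generator supplies
radiograph-like images with ground-truth enamel/dentin/boundary and lesion
masks, so the entire stack runs and is tested at desk scale with no
external data.

## The pulp loss

Odontoblasts in dental pulp couple to their neighbours through gap
junctions; their activity is spatially correlated, with coupling strength
decaying over 50–200 µm and strongest near the enamel–dentin junction. The
loss translates this into a constraint on a generated image G over pixel
domain Ω:

    L_pulp = λ · (1/|Ω|) · Σ_{(i,j)∈Ω} Σ_{p∈N(i,j)}
                 w(d_{i,j,p}) · ‖G_{i,j} − G_p‖² · M(i,j,p)

with

- `N(i,j)` the 8-connected pixel neighbourhood (ordered pairs),
- `w(d) = exp(−d²/(2σ²))`, σ = 1.5 px by default (the biological decay
  range expressed at typical radiograph resolutions of 0.1–0.3 mm/px),
- `M(i,j,p) = α·m_enamel + β·m_dentin + γ·m_boundary`, where each pair
  indicator `m` is 1 iff both endpoints lie in that tissue, and
  (α, β, γ) = (0.5, 0.3, 0.2),
- λ = 0.35, balancing the term against the adversarial (0.4) and
  pixel-wise (0.25) components of the generator objective.

Smooth tissue interiors are rewarded, differences across tissue borders are
not penalized (the pair indicators vanish there), and the loss is exactly
zero on constant images. Every loss in the package has an explicit
double-loop reference implementation that the vectorized version is tested
against to 1e−9 relative.

Because no deep-learning framework is assumed, the package carries a
compact numpy reverse-mode autodiff engine (`pulpgan.nn`) with
higher-order gradient support — required for the WGAN-GP gradient penalty,
which differentiates the norm of an input gradient with respect to the
discriminator parameters.

## Worked example

```python
import numpy as np
from pulpgan import (PhantomConfig, generate_phantom, PulpLossConfig,
                     pulp_loss, gaussian_weight)

sample = generate_phantom(PhantomConfig(height=128, width=128, n_teeth=4,
                                        lesion_rate=0.5, seed=7))
cfg = PulpLossConfig()   # lam=0.35, sigma=1.5, alpha/beta/gamma=0.5/0.3/0.2

clean = pulp_loss(sample.image, sample.masks, cfg)
rng = np.random.default_rng(0)
noisy = pulp_loss(np.clip(sample.image + rng.normal(0, 0.05,
                  sample.image.shape), 0, 1), sample.masks, cfg)
print(f"pulp loss, clean phantom : {clean:.6f}")
print(f"pulp loss, +5% noise     : {noisy:.6f}")
print(f"w(d=1)  = {gaussian_weight(1.0, 1.5):.6f}")
```

prints

```
pulp loss, clean phantom : 0.000259
pulp loss, +5% noise     : 0.001675
w(d=1)  = 0.800737
```

The clean phantom scores low because its tissue interiors are smooth;
adding 5% Gaussian noise raises the loss ~6.5×. This is the quantity the
quality gate thresholds when deciding which synthetic images enter an
augmented training set, and (λ-weighted) the term the generator minimizes
during training.

## Command line

```sh
pulpgan phantom  --n 16 --seed 1 --out phantoms/      # synthetic dataset
pulpgan train    --seed 0 --epochs 20 --image-size 32 --width 0.03125
pulpgan gate     --images phantoms/ --out gate.json   # pulp-loss gating
pulpgan segment  --input pano.png --truth lesion.png  # patch pipeline
pulpgan evaluate --real phantoms/ --generated gen/    # FID / IS / PSNR
pulpgan bench    --grid ablation                      # ablation sweep
```

Every run writes a resolved-config snapshot and seed manifest so it can be
reproduced exactly. `bench` sweeps either the regularizer registry
(`none`, `tv`, `bilateral`, `l2`, `perceptual`, `pulp`) or the pulp-loss
ablation grid (anatomical masking off, distance weighting off, 4-connected
neighbourhood, L1 penalty, all components off).

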