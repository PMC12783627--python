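"""Synthetic radiograph-like dental phantoms with ground-truth masks.

Each phantom emulates the contrast ordering of a panoramic radiograph: bright
enamel rims around darker dentin cores, a thin boundary band at the
enamel-dentin junction, optional dark carious-lesion blobs inside the tooth
tissue, a smooth vertical background gradient and additive Gaussian noise.
The generator is fully seeded so every downstream module is testable without
external data; it makes no attempt at photorealism or X-ray physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .pulp_loss import AnatomicalMaskSet

__all__ = ["PhantomConfig", "PhantomSample", "generate_phantom", "generate_dataset"]


@dataclass
class PhantomConfig:
    height: int = 128
    width: int = 128
    n_teeth: int = 4
    lesion_rate: float = 0.5
    boundary_thickness: int = 2
    noise_sd: float = 0.02
    seed: int = 0
    bit_depth: int = 8  # image quantized to this depth so PNG roundtrips losslessly

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise ValueError("height and width must be >= 8")
        if not 0.0 <= self.lesion_rate <= 1.0:
            raise ValueError("lesion_rate must be in [0, 1]")
        if self.boundary_thickness < 1:
            raise ValueError("boundary_thickness must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_teeth < 0:
            raise ValueError("n_teeth must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass
class PhantomSample:
    image: np.ndarray            # (H, W) float in [0, 1]
    masks: AnatomicalMaskSet
    lesion_mask: np.ndarray      # (H, W) uint8 in {0, 1}
    metadata: dict


def _ellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float,
             ) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Generate one phantom; deterministic for a fixed config (incl. seed)."""
    h, w = config.height, config.width
    rng = np.random.default_rng(config.seed)

    enamel = np.zeros((h, w), bool)
    dentin = np.zeros((h, w), bool)
    boundary = np.zeros((h, w), bool)
    lesion = np.zeros((h, w), bool)
    teeth_meta = []

    if config.n_teeth > 0:
        spacing = w / config.n_teeth
        rx_max = spacing / 2.0 - 2.0
        ry_max = h / 2.0 - 2.0
        rx = min(rx_max, 0.35 * spacing)
        ry = min(ry_max, 0.38 * h)
        min_r = 2.0 * config.boundary_thickness + 2.0
        if rx < min_r or ry < min_r:
            raise ValueError(
                f"grid {h}x{w} too small to place {config.n_teeth} teeth of "
                f"usable radius (needs >= {min_r:.0f} px, got {min(rx, ry):.1f})")
        for t in range(config.n_teeth):
            cx = spacing * (t + 0.5) + rng.uniform(-0.05, 0.05) * spacing
            cy = h / 2.0 + rng.uniform(-0.08, 0.08) * h
            cy = float(np.clip(cy, ry + 1, h - ry - 2))
            outer = _ellipse(h, w, cy, cx, ry, rx)
            inner = _ellipse(h, w, cy, cx + 0.08 * rx, 0.55 * ry, 0.55 * rx)
            # dentin core, boundary band of the stated thickness, enamel rim
            core = inner & ndimage.binary_erosion(
                outer, iterations=config.boundary_thickness + 1)
            band = (ndimage.binary_dilation(
                core, iterations=config.boundary_thickness) & outer) & ~core
            rim = outer & ~core & ~band
            dentin |= core
            boundary |= band
            enamel |= rim
            has_lesion = bool(rng.random() < config.lesion_rate)
            if has_lesion and core.any():
                ys, xs = np.nonzero(core | rim)
                k = rng.integers(len(ys))
                lr = max(2.0, 0.25 * min(rx, ry))
                blob = _ellipse(h, w, ys[k], xs[k], lr, lr)
                lesion |= blob & (core | rim)
            teeth_meta.append({"center": [cy, cx], "radii": [float(ry), float(rx)],
                               "lesion": has_lesion})

    # smooth vertical background gradient + noise, tissue intensities on top
    grad = np.linspace(0.10, 0.30, h)[:, None] * np.ones((1, w))
    image = grad.copy()
    image[dentin] = 0.55
    image[boundary] = 0.70
    image[enamel] = 0.85
    image[lesion] = 0.30
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=(h, w))
    image = np.clip(image, 0.0, 1.0)
    # quantize so that PNG write -> read roundtrips bit-identically
    levels = 2**config.bit_depth - 1
    image = np.round(image * levels) / levels

    masks = AnatomicalMaskSet(enamel.astype(np.uint8), dentin.astype(np.uint8),
                              boundary.astype(np.uint8))
    metadata = {"seed": config.seed, "teeth": teeth_meta,
                "config": asdict(config)}
    return PhantomSample(image, masks, lesion.astype(np.uint8), metadata)


def sample_seed(base_seed: int, index: int) -> int:
    """Derived per-sample seed; independent of dataset size."""
    ss = np.random.SeedSequence([base_seed, index])
    return int(ss.generate_state(1)[0])


def generate_dataset(config: PhantomConfig, n: int, out_dir) -> dict:
    """Write ``n`` phantoms (image + masks as PNG) and a JSON manifest."""
    from .imgio import write_image, write_mask

    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n):
        seed = sample_seed(config.seed, i)
        sample = generate_phantom(
            PhantomConfig(**{**asdict(config), "seed": seed}))
        stem = f"phantom_{i:04d}"
        paths = {
            "image": f"{stem}.png",
            "enamel": f"{stem}_enamel.png",
            "dentin": f"{stem}_dentin.png",
            "boundary": f"{stem}_boundary.png",
            "lesion": f"{stem}_lesion.png",
        }
        write_image(out / paths["image"], sample.image,
                    bit_depth=config.bit_depth)
        write_mask(out / paths["enamel"], sample.masks.enamel)
        write_mask(out / paths["dentin"], sample.masks.dentin)
        write_mask(out / paths["boundary"], sample.masks.boundary)
        write_mask(out / paths["lesion"], sample.lesion_mask)
        entries.append({"index": i, "seed": seed, "files": paths})
    manifest = {"n": n, "base_seed": config.seed, "config": asdict(config),
                "entries": entries}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def generate_batch_arrays(config: PhantomConfig, n: int
                          ) -> list[PhantomSample]:
    """In-memory dataset with the same per-sample seed derivation as on disk."""
    from dataclasses import asdict as _asdict
    samples = []
    for i in range(n):
        seed = sample_seed(config.seed, i)
        samples.append(generate_phantom(
            PhantomConfig(**{**_asdict(config), "seed": seed})))
    return samples
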