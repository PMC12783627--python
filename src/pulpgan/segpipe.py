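"""Panoramic caries segmentation: patches, fusion, post-processing.

A panorama is preprocessed (min-max normalization to [0,1] plus histogram
equalization), tiled into overlapping patches (256 px with 50% overlap by
default, the last patch per axis snapped flush with the border), segmented
patch-wise by a pluggable segmenter, and re-assembled by weighted averaging
with separable Hann windows whose applied weights are renormalized to a
partition of unity at every pixel — overlap seams average out instead of
producing boundary inconsistencies. The binary mask is then cleaned by
morphological closing and small-component removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, morphology

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Adam, Conv2d, ConvTranspose2d, Module

__all__ = [
    "PatchGrid",
    "PipelineConfig",
    "preprocess",
    "extract_patches",
    "fuse_patches",
    "postprocess_mask",
    "segment_panorama",
    "MinimalUNet",
    "minimal_unet_segmenter",
    "dice_bce_loss",
]

WINDOW_FLOOR = 1e-3


@dataclass
class PatchGrid:
    """Row-major tiling with half-open [r, r+size) x [c, c+size) patches."""

    patch_size: int
    stride: int
    origins: list[tuple[int, int]]
    image_shape: tuple[int, int]
    padded_from: tuple[int, int] | None = None  # original shape if reflect-padded


@dataclass
class PipelineConfig:
    patch_size: int = 256
    overlap: float = 0.5
    threshold: float = 0.5
    closing_radius: int = 2
    min_component_px: int = 16


def preprocess(image) -> np.ndarray:
    """Min-max normalization to [0, 1] followed by histogram equalization.

    Constant images map to themselves (clipped to [0, 1]) by convention.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.clip(image, 0.0, 1.0)
    norm = (image - lo) / (hi - lo)
    return exposure.equalize_hist(norm, nbins=256)


def _axis_origins(dim: int, size: int, stride: int) -> list[int]:
    origins = list(range(0, dim - size + 1, stride))
    if origins[-1] + size < dim:
        origins.append(dim - size)
    return origins


def extract_patches(image, patch_size: int = 256, overlap_fraction: float = 0.5
                    ) -> tuple[PatchGrid, np.ndarray]:
    """Tile an image into overlapping patches covering every pixel."""
    image = np.asarray(image, dtype=float)
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    padded_from = None
    if image.shape[0] < patch_size or image.shape[1] < patch_size:
        padded_from = image.shape
        pad_r = max(0, patch_size - image.shape[0])
        pad_c = max(0, patch_size - image.shape[1])
        image = np.pad(image, ((0, pad_r), (0, pad_c)), mode="reflect")
    h, w = image.shape
    stride = max(1, int(round(patch_size * (1.0 - overlap_fraction))))
    rows = _axis_origins(h, patch_size, stride)
    cols = _axis_origins(w, patch_size, stride)
    origins = [(r, c) for r in rows for c in cols]
    stack = np.stack([image[r:r + patch_size, c:c + patch_size]
                      for r, c in origins])
    grid = PatchGrid(patch_size, stride, origins, (h, w), padded_from)
    return grid, stack


def _hann_window(size: int) -> np.ndarray:
    w1 = np.hanning(size)
    w2 = np.outer(w1, w1)
    return np.maximum(w2, WINDOW_FLOOR)


def fuse_patches(patch_stack, grid: PatchGrid, image_shape=None) -> np.ndarray:
    """Hann-weighted average of overlapping patches (weights renormalized)."""
    stack = np.asarray(patch_stack, dtype=float)
    if len(stack) != len(grid.origins):
        raise ValueError(f"{len(stack)} patches but grid lists {len(grid.origins)}")
    size = grid.patch_size
    if stack.shape[1:] != (size, size):
        raise ValueError(f"patch shape {stack.shape[1:]} != grid size {size}")
    h, w = image_shape if image_shape is not None else grid.image_shape
    window = _hann_window(size)
    num = np.zeros((h, w))
    den = np.zeros((h, w))
    for patch, (r, c) in zip(stack, grid.origins):
        num[r:r + size, c:c + size] += patch * window
        den[r:r + size, c:c + size] += window
    if np.any(den == 0):
        raise ValueError("patch grid does not cover the image domain")
    fused = num / den
    if grid.padded_from is not None:
        fused = fused[: grid.padded_from[0], : grid.padded_from[1]]
    return fused


def postprocess_mask(mask, min_component_px: int = 16, closing_radius: int = 2
                     ) -> np.ndarray:
    """Morphological closing then removal of small 8-connected components."""
    mask = np.asarray(mask).astype(bool)
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius)) > 0
    if min_component_px > 1:
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        if n:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            keep = np.zeros(n + 1, bool)
            keep[1:] = sizes >= min_component_px
            mask = keep[labels]
    return mask.astype(np.uint8)


def segment_panorama(image, segmenter, config: PipelineConfig | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Full pipeline: preprocess, tile, segment per patch, fuse, threshold,
    post-process. Returns (binary mask, probability map)."""
    config = config or PipelineConfig()
    pre = preprocess(image)
    grid, stack = extract_patches(pre, config.patch_size, config.overlap)
    probs = []
    for patch in stack:
        p = np.asarray(segmenter(patch), dtype=float)
        if p.shape != patch.shape:
            raise ValueError(
                f"segmenter returned {p.shape} for a {patch.shape} patch")
        probs.append(p)
    prob_map = fuse_patches(np.stack(probs), grid)
    if prob_map.min() < -1e-9 or prob_map.max() > 1 + 1e-9:
        raise ValueError("fused probabilities left [0, 1]")
    prob_map = np.clip(prob_map, 0.0, 1.0)
    mask = (prob_map >= config.threshold).astype(np.uint8)
    mask = postprocess_mask(mask, config.min_component_px, config.closing_radius)
    return mask, prob_map


# -- minimal trainable segmenter ---------------------------------------------


def _stable_bce_from_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """mean(max(x,0) - x*t + log(1 + exp(-|x|)))."""
    t = Tensor(target)
    return (ag.relu(logits) - logits * t
            + ag.tlog(1.0 + ag.texp(-1.0 * ag.tabs(logits)))).mean()


def dice_bce_loss(logits: Tensor, target: np.ndarray, eps: float = 1.0
                  ) -> Tensor:
    """Combined Dice + binary cross-entropy segmentation objective."""
    probs = ag.sigmoid(logits)
    t = Tensor(np.asarray(target, dtype=float))
    inter = (probs * t).sum()
    dice = 1.0 - (2.0 * inter + eps) / (probs.sum() + t.sum() + eps)
    return dice + _stable_bce_from_logits(logits, np.asarray(target, float))


class MinimalUNet(Module):
    """Small encoder-decoder with skip connections and a sigmoid head.

    The single pluggable segmenter of the pipeline; trained with Dice-BCE.
    """

    def __init__(self, depth: int = 2, base_channels: int = 8,
                 in_channels: int = 1, seed: int = 0):
        if depth < 1 or depth > 3:
            raise ValueError("depth must be in 1..3")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.stem = Conv2d(in_channels, base_channels, 3, 1, 1, rng)
        self.down = []
        ch = base_channels
        for _ in range(depth):
            self.down.append(Conv2d(ch, ch * 2, 3, 2, 1, rng))
            ch *= 2
        self.up = []
        self.merge = []
        for _ in range(depth):
            self.up.append(ConvTranspose2d(ch, ch // 2, 4, 2, 1, rng))
            self.merge.append(Conv2d(ch, ch // 2, 3, 1, 1, rng))
            ch //= 2
        self.head = Conv2d(ch, 1, 3, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Returns logits (apply sigmoid for probabilities)."""
        h, w = x.shape[2], x.shape[3]
        if h % 2**self.depth or w % 2**self.depth:
            raise ValueError(
                f"resolution {h}x{w} not divisible by 2^{self.depth}")
        skips = []
        cur = ag.leaky_relu(self.stem(x), 0.1)
        for down in self.down:
            skips.append(cur)
            cur = ag.leaky_relu(down(cur), 0.1)
        for up, merge in zip(self.up, self.merge):
            cur = ag.leaky_relu(up(cur), 0.1)
            cur = ag.concat([cur, skips.pop()], axis=1)
            cur = ag.leaky_relu(merge(cur), 0.1)
        return self.head(cur)

    def segment(self, patch: np.ndarray) -> np.ndarray:
        """Segmenter contract: one patch in, same-shape probabilities out."""
        patch = np.asarray(patch, dtype=float)
        with ag.no_grad():
            logits = self.forward(Tensor(patch[None, None]))
            probs = ag.sigmoid(logits)
        return probs.data[0, 0]

    def fit(self, images, masks, steps: int = 200, batch_size: int = 8,
            lr: float = 3e-3, seed: int = 0) -> list[float]:
        """Adam on Dice-BCE; returns the per-step loss trajectory."""
        images = np.asarray(images, dtype=float)
        masks = np.asarray(masks, dtype=float)
        if images.shape != masks.shape:
            raise ValueError("images and masks must align")
        rng = np.random.default_rng(seed)
        params = self.parameters()
        opt = Adam(params, lr=lr)
        history = []
        n = len(images)
        for _ in range(steps):
            idx = rng.choice(n, size=min(batch_size, n), replace=False)
            x = Tensor(images[idx][:, None])
            logits = self.forward(x)
            loss = dice_bce_loss(logits, masks[idx][:, None])
            grads = ag.grad(loss, params)
            opt.step(grads)
            history.append(loss.item())
        return history


def minimal_unet_segmenter(depth: int = 2, base_channels: int = 8,
                           seed: int = 0) -> MinimalUNet:
    return MinimalUNet(depth=depth, base_channels=base_channels, seed=seed)
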