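"""Patch extraction, fusion partition-of-unity, post-processing, segmenter."""

import numpy as np
import pytest

from pulpgan.metrics import confusion_from_masks, confusion_metrics
from pulpgan.nn import Tensor
from pulpgan.segpipe import (MinimalUNet, PipelineConfig, dice_bce_loss,
                             extract_patches, fuse_patches, postprocess_mask,
                             preprocess, segment_panorama, _hann_window)


class TestPreprocess:
    def test_output_range(self, rng):
        out = preprocess(rng.normal(size=(40, 40)) * 10 + 3)
        assert out.min() >= 0.0 and out.max() <= 1.0 + 1e-12

    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 0.4)
        assert np.array_equal(preprocess(img), img)

    def test_uniform_histogram_is_near_fixed_point(self):
        img = np.linspace(0, 1, 64 * 64).reshape(64, 64)
        out = preprocess(img)
        assert np.abs(out - img).max() <= 1 / 256 + 1e-9

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((0, 0)))


class TestExtractPatches:
    def test_exact_fit_single_patch(self, rng):
        grid, stack = extract_patches(rng.random((256, 256)), 256, 0.5)
        assert grid.origins == [(0, 0)]
        assert stack.shape == (1, 256, 256)

    def test_half_overlap_four_patches(self, rng):
        grid, stack = extract_patches(rng.random((384, 384)), 256, 0.5)
        assert sorted(grid.origins) == [(0, 0), (0, 128), (128, 0), (128, 128)]

    def test_edge_snapping(self, rng):
        grid, _ = extract_patches(rng.random((300, 300)), 256, 0.5)
        assert sorted(grid.origins) == [(0, 0), (0, 44), (44, 0), (44, 44)]

    def test_coverage_of_every_pixel(self, rng):
        img = rng.random((77, 130))
        grid, _ = extract_patches(img, 32, 0.25)
        covered = np.zeros(grid.image_shape, bool)
        for r, c in grid.origins:
            covered[r:r + 32, c:c + 32] = True
        assert covered.all()

    def test_small_image_reflect_padded(self, rng):
        grid, stack = extract_patches(rng.random((20, 20)), 32, 0.5)
        assert grid.padded_from == (20, 20)
        assert stack.shape == (1, 32, 32)

    def test_invalid_overlap_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_patches(rng.random((64, 64)), 32, 1.0)


class TestFusePatches:
    def test_single_patch_identity(self, rng):
        grid, stack = extract_patches(rng.random((64, 64)), 64, 0.5)
        assert np.allclose(fuse_patches(stack, grid), stack[0])

    def test_constant_patches_give_constant(self, rng):
        grid, stack = extract_patches(rng.random((96, 96)), 64, 0.5)
        fused = fuse_patches(np.full_like(stack, 0.37), grid)
        assert np.allclose(fused, 0.37)

    def test_partition_of_unity(self, rng):
        img = rng.random((96, 96))
        grid, stack = extract_patches(img, 64, 0.5)
        # fusing the original patches must reconstruct the image exactly:
        # the applied weights sum to one at every pixel
        assert np.abs(fuse_patches(stack, grid) - img).max() < 1e-9

    def test_intensity_convexity(self, rng):
        grid, stack = extract_patches(rng.random((96, 96)), 64, 0.5)
        noisy = stack + rng.normal(0, 0.1, stack.shape)
        fused = fuse_patches(noisy, grid)
        assert fused.min() >= noisy.min() - 1e-9
        assert fused.max() <= noisy.max() + 1e-9

    def test_symmetric_overlap_midpoint(self):
        # a pixel where both windows carry equal weight averages (a+b)/2
        from pulpgan.segpipe import PatchGrid
        grid = PatchGrid(3, 2, [(0, 0), (0, 2)], (3, 5))
        stack = np.stack([np.zeros((3, 3)), np.ones((3, 3))])
        fused = fuse_patches(stack, grid)
        w = _hann_window(3)
        assert np.allclose(w[:, 2], w[:, 0])  # symmetric window columns
        assert np.allclose(fused[:, 2], 0.5)

    def test_mismatched_stack_rejected(self, rng):
        grid, stack = extract_patches(rng.random((96, 96)), 64, 0.5)
        with pytest.raises(ValueError):
            fuse_patches(stack[:-1], grid)


class TestPostprocess:
    def test_empty_mask_unchanged(self):
        assert postprocess_mask(np.zeros((20, 20))).sum() == 0

    def test_small_components_removed(self):
        mask = np.zeros((40, 40), np.uint8)
        mask[2:4, 2:4] = 1           # 4 px, below threshold
        mask[10:20, 10:15] = 1       # 50 px, survives
        out = postprocess_mask(mask, min_component_px=10, closing_radius=0)
        assert out[12, 12] == 1 and out[2, 2] == 0

    def test_idempotence(self, rng):
        mask = (rng.random((50, 50)) > 0.7).astype(np.uint8)
        once = postprocess_mask(mask, 16, 2)
        twice = postprocess_mask(once, 16, 2)
        assert np.array_equal(once, twice)


class TestSegmentPanorama:
    def test_identity_segmenter_roundtrip(self, rng):
        img = rng.random((96, 96))
        cfg = PipelineConfig(patch_size=64, overlap=0.5,
                             min_component_px=0, closing_radius=0)
        _, prob = segment_panorama(img, lambda p: p, cfg)
        assert np.abs(prob - preprocess(img)).max() < 1e-6

    def test_constant_segmenter_thresholding(self, rng):
        img = rng.random((64, 64))
        cfg = PipelineConfig(patch_size=64, min_component_px=0,
                             closing_radius=0)
        mask, _ = segment_panorama(img, lambda p: np.full_like(p, 0.6), cfg)
        assert mask.all()

    def test_deterministic(self, rng):
        img = rng.random((96, 96))
        cfg = PipelineConfig(patch_size=64)
        seg = MinimalUNet(seed=0, base_channels=4)
        a = segment_panorama(img, seg.segment, cfg)
        b = segment_panorama(img, seg.segment, cfg)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_bad_segmenter_shape_rejected(self, rng):
        cfg = PipelineConfig(patch_size=64)
        with pytest.raises(ValueError):
            segment_panorama(rng.random((64, 64)),
                             lambda p: p[:10, :10], cfg)


class TestMinimalUNet:
    def test_untrained_output_is_probability(self, rng):
        seg = MinimalUNet(seed=0, base_channels=4)
        out = seg.segment(rng.random((32, 32)))
        assert out.shape == (32, 32)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_depth_and_resolution_validation(self):
        with pytest.raises(ValueError):
            MinimalUNet(depth=4)
        seg = MinimalUNet(depth=2)
        with pytest.raises(ValueError):
            seg.segment(np.zeros((30, 30)))

    def test_dice_bce_near_zero_for_confident_correct_logits(self):
        target = np.zeros((1, 1, 8, 8))
        target[0, 0, 2:5, 2:5] = 1.0
        logits = Tensor(np.where(target > 0, 20.0, -20.0))
        assert dice_bce_loss(logits, target).item() < 1e-3

    def test_training_improves_dice(self, phantom_batch):
        imgs = np.stack([s.image for s in phantom_batch[:8]])
        masks = np.stack([s.lesion_mask for s in phantom_batch[:8]])
        seg = MinimalUNet(seed=0, base_channels=4)

        def train_dice():
            values = []
            for img, msk in zip(imgs, masks):
                pred = seg.segment(img) >= 0.5
                d = confusion_metrics(confusion_from_masks(pred, msk))["dice"]
                values.append(0.0 if d is None else d)
            return float(np.mean(values))

        before = train_dice()
        seg.fit(imgs, masks, steps=200, batch_size=8, seed=0)
        after = train_dice()
        assert after > before
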