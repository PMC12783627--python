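"""Pulp loss: closed-form examples, oracle equivalence, gradient contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulpgan.nn import Tensor, grad
from pulpgan.phantom import PhantomConfig, generate_phantom
from pulpgan.pulp_loss import (AnatomicalMaskSet, PulpLossConfig,
                               gaussian_weight, neighbor_coords,
                               pair_mask_weight, pulp_loss, pulp_loss_map,
                               pulp_loss_reference, pulp_loss_tensor)
from pulpgan.regularizers import l2_smoothness_loss


def _mask_for(shape, seed):
    return generate_phantom(PhantomConfig(seed=seed, height=shape[0],
                                          width=shape[1], n_teeth=1,
                                          boundary_thickness=1)).masks


class TestGaussianWeight:
    def test_unity_at_zero_distance(self):
        assert gaussian_weight(0.0, 1.5) == 1.0

    def test_closed_form_values(self):
        assert gaussian_weight(1.5 * np.sqrt(2), 1.5) == pytest.approx(
            np.exp(-1.0), abs=1e-12)
        assert gaussian_weight(1.0, 1.0) == pytest.approx(np.exp(-0.5),
                                                          abs=1e-12)

    def test_strictly_decreasing(self):
        d = np.linspace(0, 5, 50)
        w = gaussian_weight(d, 1.5)
        assert np.all(np.diff(w) < 0)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_weight(1.0, 0.0)


class TestNeighborCoords:
    def test_interior_has_eight(self):
        assert len(neighbor_coords(5, 5, 16, 16)) == 8

    def test_corner_clipping(self):
        assert neighbor_coords(0, 0, 4, 4) == {(0, 1), (1, 0), (1, 1)}

    def test_single_pixel_grid_empty(self):
        assert neighbor_coords(0, 0, 1, 1) == set()

    def test_never_contains_self(self):
        for i in range(3):
            for j in range(3):
                assert (i, j) not in neighbor_coords(i, j, 3, 3)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            neighbor_coords(4, 0, 4, 4)


class TestPairMaskWeight:
    def test_both_endpoints_in_one_tissue(self):
        masks = AnatomicalMaskSet(np.ones((2, 2), np.uint8),
                                  np.zeros((2, 2), np.uint8),
                                  np.zeros((2, 2), np.uint8))
        assert pair_mask_weight(masks, (0.5, 0.3, 0.2), (0, 0), (0, 1)) == 0.5

    def test_all_zero_masks(self):
        z = np.zeros((2, 2), np.uint8)
        masks = AnatomicalMaskSet(z, z, z)
        assert pair_mask_weight(masks, (0.5, 0.3, 0.2), (0, 0), (1, 1)) == 0.0

    def test_overlapping_tissues_sum(self):
        ones = np.ones((2, 2), np.uint8)
        masks = AnatomicalMaskSet(ones, np.zeros((2, 2), np.uint8), ones)
        assert pair_mask_weight(masks, (0.5, 0.3, 0.2),
                                (0, 0), (0, 1)) == pytest.approx(0.7)


class TestPulpLoss:
    def test_constant_image_is_zero(self, phantom_sample):
        img = np.full((32, 32), 0.7)
        assert pulp_loss(img, phantom_sample.masks, PulpLossConfig()) == 0.0

    def test_two_pixel_hand_enumeration(self):
        masks = AnatomicalMaskSet.uniform((1, 2))
        cfg = PulpLossConfig(lam=1.0, sigma=1.0, alpha=1.0, beta=0.0,
                             gamma=0.0)
        value = pulp_loss(np.array([[0.0, 1.0]]), masks, cfg)
        assert value == pytest.approx(np.exp(-0.5), abs=1e-12)

    @pytest.mark.parametrize("pair_rule", ["and", "or", "mean"])
    @pytest.mark.parametrize("neighborhood", [8, 4])
    def test_oracle_equivalence_random_instances(self, rng, pair_rule,
                                                 neighborhood):
        cfg = PulpLossConfig(pair_rule=pair_rule, neighborhood=neighborhood)
        for trial in range(6):
            img = rng.random((12, 12))
            masks = _mask_for((12, 12), trial)
            v = pulp_loss(img, masks, cfg)
            r = pulp_loss_reference(img, masks, cfg)
            assert v == pytest.approx(r, rel=1e-9, abs=1e-15)

    def test_reduction_to_l2_smoothness(self, rng):
        img = rng.random((9, 9))
        cfg = PulpLossConfig(lam=0.7, alpha=1.0, beta=0.0, gamma=0.0,
                             normalization="sum",
                             use_distance_weighting=False)
        assert pulp_loss(img, AnatomicalMaskSet.uniform((9, 9)), cfg) == \
            pytest.approx(l2_smoothness_loss(img, 0.7), rel=1e-12)

    def test_large_sigma_approaches_l2(self, rng):
        img = rng.random((8, 8))
        cfg = PulpLossConfig(lam=1.0, sigma=1e6, alpha=1.0, beta=0.0,
                             gamma=0.0, normalization="sum")
        assert pulp_loss(img, AnatomicalMaskSet.uniform((8, 8)), cfg) == \
            pytest.approx(l2_smoothness_loss(img, 1.0), rel=1e-9)

    def test_linear_in_lambda(self, rng, phantom_sample):
        img = rng.random((32, 32))
        v1 = pulp_loss(img, phantom_sample.masks, PulpLossConfig(lam=0.35))
        v2 = pulp_loss(img, phantom_sample.masks, PulpLossConfig(lam=0.70))
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_nonnegative_on_random_inputs(self, rng, phantom_sample):
        for _ in range(10):
            img = rng.random((32, 32))
            assert pulp_loss(img, phantom_sample.masks, PulpLossConfig()) >= 0

    def test_multichannel_is_channel_mean(self, rng, phantom_sample):
        img = rng.random((32, 32, 3))
        per_chan = np.mean([pulp_loss(img[..., c], phantom_sample.masks,
                                      PulpLossConfig()) for c in range(3)])
        assert pulp_loss(img, phantom_sample.masks, PulpLossConfig()) == \
            pytest.approx(per_chan, rel=1e-12)

    def test_shape_mismatch_rejected(self, phantom_sample):
        with pytest.raises(ValueError):
            pulp_loss(np.zeros((8, 8)), phantom_sample.masks,
                      PulpLossConfig())

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=15, deadline=None)
    def test_zero_law_constant_images(self, value_seed):
        rng = np.random.default_rng(value_seed)
        img = np.full((8, 8), rng.random())
        masks = _mask_for((12, 12), 0)
        cfg = PulpLossConfig()
        assert pulp_loss(img[:8, :8], AnatomicalMaskSet(
            masks.enamel[:8, :8], masks.dentin[:8, :8],
            masks.boundary[:8, :8]), cfg) == 0.0


class TestPulpLossMap:
    def test_aggregate_matches_scalar(self, rng):
        img = rng.random((12, 12))
        masks = _mask_for((12, 12), 4)
        cfg = PulpLossConfig()
        m = pulp_loss_map(img, masks, cfg)
        assert np.all(m >= 0)
        assert m.sum() == pytest.approx(pulp_loss(img, masks, cfg),
                                        rel=1e-9)

    def test_zero_outside_mask_support(self, rng):
        img = rng.random((12, 12))
        masks = _mask_for((12, 12), 4)
        m = pulp_loss_map(img, masks, PulpLossConfig())
        support = (masks.enamel | masks.dentin | masks.boundary).astype(bool)
        outside = ~(support | np.roll(support, 1, 0) | np.roll(support, -1, 0)
                    | np.roll(support, 1, 1) | np.roll(support, -1, 1))
        # pixels with no masked neighbour contribute nothing
        assert np.all(m[outside] == 0)


class TestPulpLossGradient:
    def test_autodiff_matches_central_differences(self, rng):
        img = rng.random((8, 8))
        masks = _mask_for((12, 12), 2)
        masks8 = AnatomicalMaskSet(masks.enamel[:8, :8], masks.dentin[:8, :8],
                                   masks.boundary[:8, :8])
        cfg = PulpLossConfig()
        t = Tensor(img[None, None], requires_grad=True)
        (g,) = grad(pulp_loss_tensor(t, [masks8], cfg), [t])
        eps = 1e-4
        for idx in [(2, 3), (5, 5), (0, 7)]:
            xp, xm = img.copy(), img.copy()
            xp[idx] += eps
            xm[idx] -= eps
            fd = (pulp_loss(xp, masks8, cfg) - pulp_loss(xm, masks8, cfg)) \
                / (2 * eps)
            assert g.data[(0, 0) + idx] == pytest.approx(fd, rel=1e-4,
                                                         abs=1e-10)

    def test_tensor_loss_equals_numpy_loss(self, rng):
        img = rng.random((12, 12))
        masks = _mask_for((12, 12), 6)
        cfg = PulpLossConfig()
        t = Tensor(img[None, None])
        assert pulp_loss_tensor(t, [masks], cfg).item() == pytest.approx(
            pulp_loss(img, masks, cfg), rel=1e-12)
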