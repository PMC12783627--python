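"""Training loop components: losses, penalties, augmentation, gating,
stability diagnostics, and a short end-to-end smoke run."""

import numpy as np
import pytest

from pulpgan.gan import build_discriminator, build_generator, generate_batch
from pulpgan.nn import Dense, Tensor
from pulpgan.nn import autograd as ag
from pulpgan.pulp_loss import PulpLossConfig, pulp_loss
from pulpgan.training import (LossWeights, QualityGateConfig, TrainConfig,
                              TrainingDivergedError, augment_batch,
                              composite_generator_loss, detect_mode_collapse,
                              discriminator_step_loss, effective_weights,
                              gradient_penalty, learning_rate_at, loss_cv,
                              quality_gate_filter, train_gan, _bce_with_logits)


class TestCompositeLoss:
    def test_all_zero_components(self):
        assert composite_generator_loss(0.0, 0.0, 0.0,
                                        weights=LossWeights(
                                            feature_matching=0.0)) == 0.0

    def test_reference_weighted_sum(self):
        w = LossWeights(adversarial=0.4, pixel=0.25, pulp=0.35,
                        feature_matching=0.0)
        assert composite_generator_loss(1.0, 1.0, 1.0, weights=w) == \
            pytest.approx(1.0)

    def test_matches_manual_recomputation(self, rng):
        w = LossWeights(adversarial=0.4, pixel=0.25, pulp=0.35,
                        perceptual=0.1, feature_matching=2.0)
        adv, pix, pul, per, fm = rng.random(5)
        got = composite_generator_loss(adv, pix, pul, per,
                                       extras={"feature_matching": fm},
                                       weights=w)
        assert got == pytest.approx(0.4 * adv + 0.25 * pix + 0.35 * pul
                                    + 0.1 * per + 2.0 * fm)

    def test_negative_required_component_rejected(self):
        with pytest.raises(ValueError):
            composite_generator_loss(0.0, pixel=-1.0,
                                     weights=LossWeights())

    def test_weight_renormalization_in_noise_mode(self):
        w = effective_weights(LossWeights(), paired=False)
        assert w.pixel == 0.0 and w.perceptual == 0.0
        assert w.adversarial + w.pulp == pytest.approx(1.0)
        assert w.adversarial == pytest.approx(0.4 / 0.75)
        # dropping the pulp term moves the pixel mass onto the adversarial
        # loss: the configured total (0.4 + 0.25) is preserved
        w0 = effective_weights(LossWeights(pulp=0.0), paired=False)
        assert w0.adversarial == pytest.approx(0.65)


class TestDiscriminatorStepLoss:
    def test_bce_of_half_against_one_is_ln2(self):
        logits = Tensor(np.zeros((4, 1)))
        assert _bce_with_logits(logits, 1.0).item() == \
            pytest.approx(np.log(2.0), rel=1e-9)

    def test_unit_gradient_norm_gives_zero_penalty(self, rng):
        # D(x) = w.x with ||w|| = 1 has input gradient norm exactly 1
        d = Dense(16, 1, np.random.default_rng(0), use_bias=False)
        d.weight.data /= np.linalg.norm(d.weight.data)
        wrapped = lambda t: d(t.reshape(t.shape[0], 16))
        gp = gradient_penalty(wrapped, rng.random((3, 1, 4, 4)),
                              rng.random((3, 1, 4, 4)),
                              np.random.default_rng(1))
        assert gp.item() == pytest.approx(0.0, abs=1e-12)

    def test_gradient_norm_two_gives_penalty_ten(self, rng):
        d = Dense(16, 1, np.random.default_rng(0), use_bias=False)
        d.weight.data *= 2.0 / np.linalg.norm(d.weight.data)
        wrapped = lambda t: d(t.reshape(t.shape[0], 16))
        gp = gradient_penalty(wrapped, rng.random((3, 1, 4, 4)),
                              rng.random((3, 1, 4, 4)),
                              np.random.default_rng(1))
        assert 10.0 * gp.item() == pytest.approx(10.0, rel=1e-9)

    def test_modes_and_empty_batch(self, tiny_specs, rng):
        disc = build_discriminator(tiny_specs[1], seed=0)
        real = rng.uniform(-1, 1, (4, 1, 32, 32))
        fake = rng.uniform(-1, 1, (4, 1, 32, 32))
        for mode in ("bce_gp", "wgan_gp"):
            loss, gp = discriminator_step_loss(disc, real, fake, mode, 10.0,
                                               np.random.default_rng(0))
            assert np.isfinite(loss.item()) and np.isfinite(gp)
        with pytest.raises(ValueError):
            discriminator_step_loss(disc, real[:0], fake[:0])
        with pytest.raises(ValueError):
            discriminator_step_loss(disc, real, fake[:2])


class TestAugmentBatch:
    def test_zero_intensity_is_identity(self, rng):
        imgs = rng.random((3, 16, 16))
        masks = (rng.random((3, 2, 16, 16)) > 0.5).astype(np.uint8)
        out_i, out_m = augment_batch(imgs, masks, 0.0, seed=0)
        assert np.array_equal(out_i, imgs)
        assert np.array_equal(out_m, masks)

    def test_seeded_determinism(self, rng):
        imgs = rng.random((4, 16, 16))
        a, _ = augment_batch(imgs, None, 0.75, seed=9)
        b, _ = augment_batch(imgs, None, 0.75, seed=9)
        assert np.array_equal(a, b)

    def test_masks_follow_geometric_transforms(self, rng):
        from scipy import ndimage
        imgs = rng.random((4, 16, 16))
        masks = (rng.random((4, 2, 16, 16)) > 0.5).astype(np.uint8)
        out_i, out_m = augment_batch(imgs, masks, 1.0, seed=3)
        # independent replay of the seeded transform parameters
        replay = np.random.default_rng(3)
        for i in range(4):
            angle = replay.uniform(-15.0, 15.0)
            flip = replay.random() < 0.5
            replay.uniform(-0.2, 0.2)  # brightness draw (images only)
            for k in range(2):
                expect = ndimage.rotate(masks[i, k], angle, reshape=False,
                                        order=0, mode="nearest")
                if flip:
                    expect = expect[:, ::-1]
                assert np.array_equal(out_m[i, k], expect)

    def test_invalid_intensity_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_batch(rng.random((1, 8, 8)), None, 1.5, 0)


class TestQualityGate:
    def test_infinite_threshold_accepts_all(self, phantom_batch):
        images = [s.image for s in phantom_batch]
        masks = [s.masks for s in phantom_batch]
        accepted, report = quality_gate_filter(
            images, masks, PulpLossConfig(),
            QualityGateConfig(mode="absolute", tau=np.inf))
        assert len(accepted) == len(images)

    def test_zero_threshold_accepts_only_constant(self, phantom_batch):
        images = [s.image for s in phantom_batch] + [np.full((32, 32), 0.5)]
        masks = [s.masks for s in phantom_batch] + [phantom_batch[0].masks]
        accepted, report = quality_gate_filter(
            images, masks, PulpLossConfig(),
            QualityGateConfig(mode="absolute", tau=0.0))
        assert report["n_accepted"] == 1
        assert np.allclose(accepted[0], 0.5)

    def test_acceptance_monotone_in_threshold(self, phantom_batch, rng):
        images = [np.clip(s.image + rng.normal(0, sd, s.image.shape), 0, 1)
                  for s, sd in zip(phantom_batch, np.linspace(0, 0.3, 16))]
        masks = [s.masks for s in phantom_batch]
        losses = [pulp_loss(im, m, PulpLossConfig())
                  for im, m in zip(images, masks)]
        counts = []
        for tau in np.linspace(max(losses), 0, 7):
            _, rep = quality_gate_filter(
                images, masks, PulpLossConfig(),
                QualityGateConfig(mode="absolute", tau=tau))
            counts.append(rep["n_accepted"])
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_gate_consistency(self, phantom_batch):
        images = [s.image for s in phantom_batch]
        masks = [s.masks for s in phantom_batch]
        cfg = PulpLossConfig()
        _, rep = quality_gate_filter(images, masks, cfg,
                                     QualityGateConfig(tau=50.0),
                                     real_images=images,
                                     real_mask_sets=masks)
        for row in rep["images"]:
            if row["accepted"]:
                assert row["pulp_loss"] <= rep["tau"]

    def test_percentile_mode_requires_reference(self, phantom_batch):
        with pytest.raises(ValueError):
            quality_gate_filter([phantom_batch[0].image],
                                [phantom_batch[0].masks], PulpLossConfig(),
                                QualityGateConfig())


class TestStabilityDiagnostics:
    def test_constant_trajectory_no_events(self):
        assert detect_mode_collapse([5.0] * 120) == []

    def test_forty_percent_drop_flagged_at_crossing(self):
        traj = [5.0] * 60 + [3.0] + [5.0] * 10
        assert detect_mode_collapse(traj) == [60]

    def test_twenty_percent_drop_not_flagged(self):
        traj = [5.0] * 60 + [4.0] + [5.0] * 10
        assert detect_mode_collapse(traj) == []

    def test_window_limits_lookback(self):
        # events persist only while the peak remains inside the 50-epoch
        # window; afterwards the flat trajectory is quiet
        traj = [10.0] + [4.0] * 80
        assert detect_mode_collapse(traj) == list(range(1, 51))

    def test_loss_cv_reference_value(self):
        assert loss_cv([1.0, 3.0], warmup=0) == pytest.approx(0.5)

    def test_loss_cv_scale_invariance(self, rng):
        x = rng.random(50) + 0.5
        assert loss_cv(7.0 * x) == pytest.approx(loss_cv(x), rel=1e-12)

    def test_loss_cv_constant_zero(self):
        assert loss_cv([2.0, 2.0, 2.0]) == 0.0

    def test_loss_cv_errors(self):
        with pytest.raises(ZeroDivisionError):
            loss_cv([-1.0, 1.0])
        with pytest.raises(ValueError):
            loss_cv([1.0, 2.0], warmup=2)


class TestLearningRateDecay:
    def test_decay_law(self):
        cfg = TrainConfig(epochs=200, decay_epoch=100, learning_rate=2e-4,
                          decay_factor=0.5)
        assert learning_rate_at(0, cfg) == 2e-4
        assert learning_rate_at(99, cfg) == 2e-4
        assert learning_rate_at(100, cfg) == 1e-4
        assert learning_rate_at(199, cfg) == 1e-4


class TestTrainGanSmoke:
    def test_short_run_logs_finite_and_checkpoints(self, phantom_batch,
                                                   tiny_specs, tmp_path):
        gen_spec, disc_spec = tiny_specs
        cfg = TrainConfig(batch_size=16, epochs=3, decay_epoch=2,
                          image_size=32, seed=0, is_every=2)
        log, gen, disc = train_gan(phantom_batch, gen_spec, disc_spec, cfg)
        assert len(log.records) == 3
        for record in log.records:
            assert all(np.isfinite(v) for v in record.values())
        assert len(log.is_trajectory) == 3
        # decay applied inside the loop
        assert log.records[1]["lr"] == pytest.approx(2e-4)
        assert log.records[2]["lr"] == pytest.approx(1e-4)
        # checkpoint roundtrip reproduces the trained generator
        from pulpgan.gan import load_checkpoint, save_checkpoint
        path = tmp_path / "ck.npz"
        save_checkpoint(path, gen, disc)
        gen2, _, _ = load_checkpoint(path)
        assert np.array_equal(generate_batch(gen, n=2, seed=0),
                              generate_batch(gen2, n=2, seed=0))

    def test_empty_dataset_rejected(self, tiny_specs):
        with pytest.raises(ValueError):
            train_gan([], *tiny_specs, TrainConfig(epochs=1, decay_epoch=1))
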