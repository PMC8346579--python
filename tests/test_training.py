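"""Loss, patch pipeline, augmentation and the optimization protocol."""

import numpy as np
import pytest
from scipy import stats

from airwayseg import (
    AugmentConfig,
    Sample,
    TrainConfig,
    TrainingHistory,
    UNetConfig,
    VolumeGrid,
    augment,
    build_unet,
    convergence_check,
    crop_to_roi_bbox,
    find_admissible_size,
    masked_soft_dice_loss,
    sample_random_patch,
    train,
)


def make_sample(shape=(64, 64, 64), roi_window=None, seed=0):
    rng = np.random.default_rng(seed)
    image = VolumeGrid(rng.normal(-800, 100, size=shape).astype(np.float32))
    labels = VolumeGrid(rng.integers(0, 2, size=shape).astype(np.uint8))
    roi = np.zeros(shape, dtype=np.uint8)
    roi[roi_window if roi_window is not None else (slice(None),) * 3] = 1
    return Sample(image, labels, VolumeGrid(roi), sample_id=f"s{seed}")


class TestCropToRoiBbox:
    def test_buffer_interval_arithmetic(self):
        window = (slice(40, 80),) * 3
        cropped = crop_to_roi_bbox(make_sample((128, 128, 128), window), 30)
        assert cropped.image.shape == (100, 100, 100)  # [10, 110) per axis

    def test_clamped_at_volume_border(self):
        window = (slice(0, 20), slice(50, 60), slice(58, 64))
        cropped = crop_to_roi_bbox(make_sample((64, 64, 64), window), 30)
        assert cropped.image.shape == (50, 44, 36)

    def test_labels_masked_to_roi(self):
        sample = make_sample((32, 32, 32), (slice(8, 24),) * 3)
        cropped = crop_to_roi_bbox(sample, 2)
        outside = cropped.roi_mask.values == 0
        assert not cropped.labels.values[outside].any()

    def test_empty_roi_raises(self):
        sample = make_sample((16, 16, 16), (slice(0, 0),) * 3)
        with pytest.raises(ValueError, match="empty"):
            crop_to_roi_bbox(sample)


class TestPatchSampler:
    def test_degenerate_range_forces_origin(self, rng):
        sample = make_sample((20, 24, 28))
        pair = sample_random_patch(sample, (20, 24, 28), rng)
        assert pair.corner == (0, 0, 0)

    def test_patch_shape_and_corner_ranges(self, rng):
        sample = make_sample((40, 44, 48))
        for _ in range(200):
            pair = sample_random_patch(sample, (16, 20, 24), rng)
            assert pair.image_patch.shape == (16, 20, 24)
            assert pair.label_patch.shape == (16, 20, 24)
            for c, s, p in zip(pair.corner, (40, 44, 48), (16, 20, 24)):
                assert 0 <= c <= s - p

    def test_corner_marginals_are_uniform(self, rng):
        # chi-squared goodness of fit per axis at alpha = 0.01
        sample = make_sample((40, 40, 40))
        draws = np.array(
            [sample_random_patch(sample, (20, 20, 20), rng).corner
             for _ in range(2000)]
        )
        for axis in range(3):
            counts = np.bincount(draws[:, axis], minlength=21)
            _, p = stats.chisquare(counts)
            assert p > 0.01

    def test_oversized_patch_rejected(self, rng):
        with pytest.raises(ValueError, match="larger than volume"):
            sample_random_patch(make_sample((16, 16, 16)), (20, 16, 16), rng)


class TestAugment:
    def make_pair(self, rng, size=16):
        sample = make_sample((size,) * 3, seed=3)
        return sample_random_patch(sample, (size,) * 3, rng)

    def test_disabled_is_identity(self, rng):
        pair = self.make_pair(rng)
        out = augment(pair, AugmentConfig(enabled=False), rng)
        assert np.array_equal(out.image_patch, pair.image_patch)

    def test_null_parameters_are_identity(self, rng):
        pair = self.make_pair(rng)
        cfg = AugmentConfig(
            flip_axes=(False, False, False),
            max_rotation_deg=0.0,
            scale_range=(1.0, 1.0),
        )
        out = augment(pair, cfg, rng)
        assert np.allclose(out.image_patch, pair.image_patch, atol=1e-4)
        assert np.array_equal(out.label_patch, pair.label_patch)

    def test_flip_is_an_involution(self, rng):
        pair = self.make_pair(rng)
        cfg = AugmentConfig(
            flip_axes=(True, False, False),
            max_rotation_deg=0.0,
            scale_range=(1.0, 1.0),
        )
        # force both draws to flip by consuming rngs with identical state
        r1 = np.random.default_rng(1)
        once = augment(pair, cfg, r1)
        r1 = np.random.default_rng(1)
        if not np.array_equal(once.image_patch, pair.image_patch):
            r2 = np.random.default_rng(1)
            twice = augment(augment(pair, cfg, np.random.default_rng(1)), cfg, r2)
            assert np.allclose(twice.image_patch, pair.image_patch, atol=1e-4)
            assert np.array_equal(twice.label_patch, pair.label_patch)

    def test_labels_stay_binary_over_many_draws(self, rng):
        pair = self.make_pair(rng, size=12)
        cfg = AugmentConfig()
        for _ in range(200):
            out = augment(pair, cfg, rng)
            assert set(np.unique(out.label_patch)).issubset({0, 1})
            assert set(np.unique(out.roi_patch)).issubset({0, 1})
            assert out.image_patch.shape == pair.image_patch.shape


class TestMaskedSoftDice:
    def test_perfect_prediction_gives_zero(self, rng):
        g = (rng.random((8, 8, 8)) > 0.5).astype(np.float32)
        roi = np.ones_like(g)
        assert masked_soft_dice_loss(g, g, roi) == pytest.approx(0.0, abs=1e-5)

    def test_empty_overlap_gives_one(self, rng):
        g = np.zeros((8, 8, 8), dtype=np.float32)
        g[2:4] = 1
        p = np.zeros_like(g)
        assert masked_soft_dice_loss(p, g, np.ones_like(g)) == pytest.approx(
            1.0, abs=1e-5
        )

    def test_hand_computed_value(self):
        # ROI of 8 voxels, p = 0.5 everywhere, 4 positives:
        # 1 - 2*(0.5*4) / (0.5*8 + 4) = 0.5
        p = np.full((2, 2, 2), 0.5, dtype=np.float32)
        g = np.zeros((2, 2, 2), dtype=np.float32)
        g.ravel()[:4] = 1
        roi = np.ones_like(g)
        assert masked_soft_dice_loss(p, g, roi) == pytest.approx(0.5, abs=1e-6)

    def test_value_bounded_in_unit_interval(self, rng):
        for _ in range(25):
            p = rng.random((6, 6, 6)).astype(np.float32)
            g = (rng.random((6, 6, 6)) > 0.7).astype(np.float32)
            roi = (rng.random((6, 6, 6)) > 0.3).astype(np.float32)
            loss = masked_soft_dice_loss(p, g, roi)
            assert 0.0 <= loss <= 1.0

    def test_roi_independence_of_value_and_gradient(self, rng):
        p = rng.random((8, 8, 8)).astype(np.float32)
        g = (rng.random((8, 8, 8)) > 0.6).astype(np.float32)
        roi = np.zeros_like(g)
        roi[:4] = 1
        loss, grad = masked_soft_dice_loss(p, g, roi, return_grad=True)
        # perturb outside the ROI
        p2, g2 = p.copy(), g.copy()
        p2[4:] = rng.random((4, 8, 8))
        g2[4:] = 1 - g2[4:]
        loss2, grad2 = masked_soft_dice_loss(p2, g2, roi, return_grad=True)
        assert loss == pytest.approx(loss2, abs=1e-7)
        assert np.allclose(grad[:4], grad2[:4])
        assert np.all(grad[4:] == 0)

    def test_gradient_matches_finite_differences(self, rng):
        p = rng.random((4, 4, 4)).astype(np.float64)
        g = (rng.random((4, 4, 4)) > 0.5).astype(np.float64)
        roi = (rng.random((4, 4, 4)) > 0.2).astype(np.float64)
        _, grad = masked_soft_dice_loss(p, g, roi, return_grad=True)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 1)]:
            p[idx] += eps
            up = masked_soft_dice_loss(p, g, roi)
            p[idx] -= 2 * eps
            down = masked_soft_dice_loss(p, g, roi)
            p[idx] += eps
            assert grad[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-4)


class TestConvergenceCheck:
    CFG = TrainConfig(ma_window_epochs=50, stop_patience_epochs=20)

    def test_never_stops_while_steadily_decreasing(self):
        losses = list(0.9 * 0.99 ** np.arange(200))
        hist = TrainingHistory(train_loss=losses, val_loss=losses)
        stop, _ = convergence_check(hist, self.CFG)
        assert not stop

    def test_stops_on_constant_loss(self):
        losses = [0.5] * 70
        hist = TrainingHistory(train_loss=losses, val_loss=losses)
        stop, reason = convergence_check(hist, self.CFG)
        assert stop and "stall" in reason

    def test_stops_on_rising_moving_average(self):
        # 50-epoch moving average: (30*0.5 + 20*0.6)/50 = 0.54, an 8% rise
        # over the value 20 epochs earlier (0.5)
        losses = [0.5] * 50 + [0.6] * 20
        hist = TrainingHistory(train_loss=losses, val_loss=losses)
        stop, reason = convergence_check(hist, self.CFG)
        assert stop and "rise" in reason

    def test_no_stop_before_window_plus_patience(self):
        losses = [0.5] * 69  # one short of 50 + 20
        hist = TrainingHistory(train_loss=losses, val_loss=losses)
        stop, _ = convergence_check(hist, self.CFG)
        assert not stop


def phantom_samples(n, size=40, gens=3):
    from airwayseg import PhantomConfig, generate_phantom

    samples = []
    for s in range(n):
        ph = generate_phantom(
            PhantomConfig(volume_shape=(size,) * 3, n_generations=gens, seed=100 + s)
        )
        samples.append(Sample(ph.image, ph.lumen_mask, ph.lung_mask, f"ph{s}"))
    return samples


class TestTrainLoop:
    UCFG = UNetConfig(n_levels=2, n_features_first=2, n_valid_levels=1, init_seed=1)

    def tiny_config(self, **kw):
        size = find_admissible_size(self.UCFG, 24)
        defaults = dict(
            patch_size=(size,) * 3,
            max_epochs=2,
            patches_per_scan_per_epoch=2,
            ma_window_epochs=2,
            stop_patience_epochs=1,
            seed=5,
        )
        defaults.update(kw)
        return TrainConfig(**defaults)

    def test_zero_learning_rate_freezes_weights(self):
        samples = phantom_samples(2)
        model = build_unet(self.UCFG)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        model, history = train(model, samples, self.tiny_config(learning_rate=0.0))
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)
        assert len(set(np.round(history.val_loss, 10))) == 1

    def test_fixed_seed_reproduces_history(self):
        samples = phantom_samples(2)
        cfg = self.tiny_config()
        _, h1 = train(build_unet(self.UCFG), samples, cfg)
        _, h2 = train(build_unet(self.UCFG), samples, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_validation_loss_decreases_on_phantoms(self):
        samples = phantom_samples(3)
        cfg = self.tiny_config(max_epochs=8, patches_per_scan_per_epoch=4,
                               learning_rate=3e-3, ma_window_epochs=100,
                               stop_patience_epochs=50)
        _, history = train(build_unet(self.UCFG), samples, cfg)
        assert len(history.val_loss) == 8
        assert history.val_loss[-1] < history.val_loss[0]

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            train(build_unet(self.UCFG), phantom_samples(1), self.tiny_config())

    def test_inadmissible_patch_size_rejected(self):
        with pytest.raises(ValueError, match="not admissible"):
            train(
                build_unet(self.UCFG),
                phantom_samples(2),
                self.tiny_config(patch_size=(23, 23, 23)),
            )
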