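"""Label preparation, augmentation, losses, and the two training loops."""

import numpy as np
import pytest

from weedseg.metrics import CROP, IGNORE, SOIL, WEED, dice_error, argmax_classes
from weedseg.models import MobileConfig, build_mobile, build_stationary, init_weights
from weedseg.training import (
    TrainConfig,
    augment_pair,
    downsample_mask,
    exclude_borders,
    soft_cross_entropy,
    train_distill,
    train_hard,
)


class TestExcludeBorders:
    def test_half_and_half_radius_one(self):
        # 6x6 split into a soil half and a crop half: radius 1 removes the two
        # pixel rows flanking the boundary -> 12 ignores
        mask = np.zeros((6, 6), np.uint8)
        mask[3:] = CROP
        out = exclude_borders(mask, 1)
        assert (out == IGNORE).sum() == 12
        assert (out[:2] == SOIL).all() and (out[4:] == CROP).all()

    def test_radius_zero_is_identity(self, rng):
        mask = rng.integers(0, 3, (9, 9)).astype(np.uint8)
        np.testing.assert_array_equal(exclude_borders(mask, 0), mask)

    def test_idempotent_at_fixed_radius(self, rng):
        mask = rng.integers(0, 3, (12, 12)).astype(np.uint8)
        once = exclude_borders(mask, 2)
        np.testing.assert_array_equal(exclude_borders(once, 2), once)

    def test_ignore_set_grows_with_radius(self, rng):
        mask = rng.integers(0, 3, (12, 12)).astype(np.uint8)
        prev = -1
        for r in range(4):
            n = int((exclude_borders(mask, r) == IGNORE).sum())
            assert n >= prev
            prev = n

    def test_existing_ignores_preserved_and_inert(self):
        mask = np.zeros((4, 4), np.uint8)
        mask[0, 0] = IGNORE
        out = exclude_borders(mask, 1)
        # an ignore pixel is not a class boundary: nothing else is removed
        assert (out == IGNORE).sum() == 1

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            exclude_borders(np.zeros((4, 4), np.uint8), -1)


class TestDownsampleMask:
    def test_majority_vote(self):
        mask = np.zeros((4, 4), np.uint8)
        mask[:2, :2] = WEED  # 4 of 16 -> soil majority
        assert downsample_mask(mask, 4).item() == SOIL

    def test_tie_becomes_ignore(self):
        mask = np.array([[SOIL, SOIL], [WEED, WEED]], np.uint8)
        assert downsample_mask(mask, 2).item() == IGNORE

    def test_ignore_pixels_do_not_vote(self):
        mask = np.array([[WEED, IGNORE], [IGNORE, IGNORE]], np.uint8)
        assert downsample_mask(mask, 2).item() == WEED

    def test_all_ignore_cell(self):
        mask = np.full((2, 2), IGNORE, np.uint8)
        assert downsample_mask(mask, 2).item() == IGNORE

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError):
            downsample_mask(np.zeros((5, 8), np.uint8), 4)


class TestAugmentPair:
    def test_deterministic_given_rng_state(self, rng):
        image = rng.random((8, 8, 3), dtype=np.float32)
        mask = rng.integers(0, 3, (8, 8)).astype(np.uint8)
        a1 = augment_pair(image, mask, np.random.default_rng(7))
        a2 = augment_pair(image, mask, np.random.default_rng(7))
        np.testing.assert_array_equal(a1[0], a2[0])
        np.testing.assert_array_equal(a1[1], a2[1])

    def test_output_stays_in_unit_range(self, rng):
        image = rng.random((8, 8, 3), dtype=np.float32)
        mask = np.zeros((8, 8), np.uint8)
        for seed in range(30):
            out, _ = augment_pair(image, mask, np.random.default_rng(seed))
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_mask_values_never_change(self, rng):
        mask = rng.choice([0, 1, 2, IGNORE], size=(8, 8)).astype(np.uint8)
        image = rng.random((8, 8, 3), dtype=np.float32)
        for seed in range(10):
            _, m = augment_pair(image, mask, np.random.default_rng(seed))
            assert sorted(np.unique(m)) == sorted(np.unique(mask))

    def test_image_and_mask_flip_together(self):
        # equal channels keep the per-pixel jitter monotone, so the brightest
        # pixel's corner reveals which flips were applied to the image
        h, w = 6, 8
        vals = np.linspace(0.4, 0.6, h * w, dtype=np.float32).reshape(h, w)
        image = np.repeat(vals[..., None], 3, axis=-1)
        mask = np.arange(h * w, dtype=np.uint8).reshape(h, w) % 3
        flips = {
            (h - 1, w - 1): (False, False),
            (h - 1, 0): (True, False),
            (0, w - 1): (False, True),
            (0, 0): (True, True),
        }
        seen = set()
        for seed in range(24):
            img2, m2 = augment_pair(image, mask, np.random.default_rng(seed))
            corner = np.unravel_index(img2[..., 0].argmax(), (h, w))
            flip_h, flip_v = flips[corner]
            expect = mask[:, ::-1] if flip_h else mask
            expect = expect[::-1] if flip_v else expect
            np.testing.assert_array_equal(m2, expect)
            seen.add((flip_h, flip_v))
        assert seen == {(False, False), (True, False), (False, True), (True, True)}


class TestSoftCrossEntropy:
    def test_gibbs_inequality(self, rng):
        for _ in range(20):
            t = rng.random((3, 4, 3)).astype(np.float64)
            t /= t.sum(-1, keepdims=True)
            p = rng.random((3, 4, 3)).astype(np.float64)
            p /= p.sum(-1, keepdims=True)
            self_h = soft_cross_entropy(t, t)
            assert soft_cross_entropy(t, p) >= self_h - 1e-9

    def test_uniform_target_minimised_by_uniform_prediction(self):
        t = np.full((2, 2, 3), 1 / 3)
        assert soft_cross_entropy(t, t) == pytest.approx(np.log(3.0), abs=1e-6)
        skew = np.array([0.5, 0.3, 0.2]) * np.ones((2, 2, 3))
        assert soft_cross_entropy(t, skew) > np.log(3.0)


def _labelled_pairs(desk_pairs, n):
    return [(img, mask) for img, mask in desk_pairs[:n]]


class TestTrainHard:
    def test_loss_decreases_on_memorisation(self, tiny_stationary, desk_pairs):
        model = init_weights(build_stationary(tiny_stationary), seed=0)
        cfg = TrainConfig(epochs=8, batch_size=2, seed=0, augment=False)
        model = train_hard(model, _labelled_pairs(desk_pairs, 2), cfg)
        assert len(model.history) == 8
        assert model.history[-1] < model.history[0]

    def test_training_improves_predictions(self, tiny_stationary, desk_pairs):
        pairs = _labelled_pairs(desk_pairs, 2)
        model = init_weights(build_stationary(tiny_stationary), seed=0)
        before = [argmax_classes(model.predict(img)) for img, _ in pairs]
        cfg = TrainConfig(epochs=15, batch_size=2, seed=0)
        model = train_hard(model, pairs, cfg)
        after = [argmax_classes(model.predict(img)) for img, _ in pairs]
        from weedseg.training import downsample_mask as ds
        labels = [ds(m) for _, m in pairs]
        assert dice_error(after, labels) < dice_error(before, labels)

    def test_reproducible_given_seed(self, desk_pairs):
        pairs = _labelled_pairs(desk_pairs, 2)
        cfg = TrainConfig(epochs=2, batch_size=2, seed=9)
        g = build_mobile(MobileConfig(alpha=0.3))
        m1 = train_hard(init_weights(g, seed=1), pairs, cfg)
        m2 = train_hard(init_weights(g, seed=1), pairs, cfg)
        for k in m1.weights:
            np.testing.assert_array_equal(m1.weights[k], m2.weights[k])
        assert m1.history == m2.history

    def test_rejects_degenerate_datasets(self, desk_pairs):
        model = init_weights(build_mobile(MobileConfig(alpha=0.3)), seed=0)
        cfg = TrainConfig(epochs=1)
        with pytest.raises(ValueError):
            train_hard(model, [], cfg)
        img = desk_pairs[0][0]
        all_ignore = np.full(img.shape[:2], IGNORE, np.uint8)
        with pytest.raises(ValueError):
            train_hard(model, [(img, all_ignore)], cfg)
        with pytest.raises(ValueError):  # mask at neither full nor output res
            train_hard(model, [(img, np.zeros((5, 5), np.uint8))], cfg)

    def test_accepts_masks_at_output_resolution(self, desk_pairs):
        img, mask = desk_pairs[0]
        small = downsample_mask(mask)
        model = init_weights(build_mobile(MobileConfig(alpha=0.3)), seed=0)
        cfg = TrainConfig(epochs=1, batch_size=1, augment=False)
        model = train_hard(model, [(img, small)], cfg)
        assert len(model.history) == 1


class TestTrainDistill:
    def test_self_distillation_is_a_fixed_point(self, desk_pairs):
        """A student already matching its targets gets exactly zero gradient,
        so training leaves the weights untouched (BN off to keep the forward
        pass identical between eval and training)."""
        g = build_mobile(MobileConfig(alpha=0.3, use_bn=False))
        student = init_weights(g, seed=3)
        images = [img for img, _ in desk_pairs[:3]]
        dataset = [(img, student.predict(img)) for img in images]
        cfg = TrainConfig(epochs=2, batch_size=3, augment=False, seed=0)
        trained = train_distill(student.copy(), dataset, cfg)
        for k in student.weights:
            np.testing.assert_array_equal(trained.weights[k], student.weights[k])
        self_h = np.mean([soft_cross_entropy(t, t) for _, t in dataset])
        assert trained.history[-1] == pytest.approx(self_h, rel=1e-5)

    def test_distillation_moves_student_toward_teacher(self, desk_pairs):
        # BN off so that the gap is measurable in eval mode right away, before
        # the running statistics have converged
        g = build_mobile(MobileConfig(alpha=0.3, use_bn=False))
        teacher = init_weights(g, seed=1)
        student = init_weights(g, seed=2)
        images = [img for img, _ in desk_pairs[:4]]
        dataset = [(img, teacher.predict(img)) for img in images]

        def gap(model):
            return float(np.mean([soft_cross_entropy(t, model.predict(img))
                                  for img, t in dataset]))

        before = gap(student)
        cfg = TrainConfig(epochs=10, batch_size=2, augment=False, seed=0)
        student = train_distill(student, dataset, cfg)
        assert gap(student) < before

    def test_malformed_soft_labels_rejected(self, desk_pairs):
        model = init_weights(build_mobile(MobileConfig(alpha=0.3)), seed=0)
        img = desk_pairs[0][0]
        good = model.predict(img)
        cfg = TrainConfig(epochs=1)
        with pytest.raises(ValueError):  # rows don't sum to one
            train_distill(model.copy(), [(img, good * 2.0)], cfg)
        with pytest.raises(ValueError):  # wrong rank
            train_distill(model.copy(), [(img, good[..., 0])], cfg)
        with pytest.raises(ValueError):
            train_distill(model.copy(), [], cfg)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=-1.0)
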