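"""Synthetic field imagery: determinism, mask/image invariants, dataset
writing, and enough signal for a model to generalise from."""

import json

import numpy as np
import pytest

from weedseg.metrics import CROP, SOIL, WEED, argmax_classes, dice_error
from weedseg.synthetic_field import FieldConfig, generate_dataset, generate_field


class TestGenerateField:
    def test_deterministic_for_equal_seeds(self, desk_field_config):
        i1, m1 = generate_field(desk_field_config, np.random.default_rng([0, 3]))
        i2, m2 = generate_field(desk_field_config, np.random.default_rng([0, 3]))
        np.testing.assert_array_equal(i1, i2)
        np.testing.assert_array_equal(m1, m2)

    def test_seed_sequence_varies_images(self, desk_field_config):
        i1, _ = generate_field(desk_field_config, np.random.default_rng([0, 0]))
        i2, _ = generate_field(desk_field_config, np.random.default_rng([0, 1]))
        assert not np.array_equal(i1, i2)

    def test_shapes_dtypes_and_ranges(self, desk_field_config):
        image, mask = generate_field(desk_field_config)
        assert image.shape == (48, 64, 3) and image.dtype == np.float32
        assert mask.shape == (48, 64) and mask.dtype == np.uint8
        assert image.min() >= 0.0 and image.max() <= 1.0
        assert set(np.unique(mask)) <= {SOIL, CROP, WEED}

    def test_bare_soil_config(self):
        cfg = FieldConfig(height=32, width=32, n_crops=0, weed_density=0.0,
                          shadow_prob=0.0, seed=1)
        image, mask = generate_field(cfg)
        assert (mask == SOIL).all()
        # soil is brown: red channel dominates green and blue everywhere
        assert (image[..., 0] >= image[..., 1]).all()
        assert (image[..., 1] >= image[..., 2]).all()

    def test_plants_are_green_dominant(self, desk_pairs):
        for image, mask in desk_pairs:
            plant = mask != SOIL
            assert plant.any()
            g = image[..., 1][plant]
            assert (g >= image[..., 0][plant]).all()
            assert (g >= image[..., 2][plant]).all()

    def test_both_plant_classes_occur_across_the_dataset(self, desk_pairs):
        masks = np.stack([m for _, m in desk_pairs])
        assert (masks == CROP).any() and (masks == WEED).any()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FieldConfig(height=4)
        with pytest.raises(ValueError):
            FieldConfig(crop_radius_range=(10.0, 5.0))
        with pytest.raises(ValueError):
            FieldConfig(n_crops=-1)
        with pytest.raises(ValueError):
            FieldConfig(shadow_prob=1.5)

    def test_golden_class_fractions(self, desk_field_config):
        """Regression pin: per-class pixel fractions of the fixed-seed desk
        dataset. Loose bounds; a real generator change should still trip them."""
        masks = [generate_field(desk_field_config, np.random.default_rng([0, i]))[1]
                 for i in range(20)]
        total = sum(m.size for m in masks)
        crop = sum((m == CROP).sum() for m in masks) / total
        weed = sum((m == WEED).sum() for m in masks) / total
        assert 0.03 < crop < 0.45
        assert 0.01 < weed < 0.35
        assert crop + weed < 0.7  # soil stays the majority overall


class TestGenerateDataset:
    def test_writes_images_masks_and_manifest(self, desk_field_config, tmp_path):
        out = generate_dataset(desk_field_config, 3, tmp_path / "d")
        assert sorted(p.name for p in (out / "images").iterdir()) == [
            "0000.png", "0001.png", "0002.png"]
        assert sorted(p.name for p in (out / "masks").iterdir()) == [
            "0000.png", "0001.png", "0002.png"]
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["n_images"] == 3
        assert manifest["config"]["seed"] == desk_field_config.seed

    def test_manifest_reproduces_dataset_bit_for_bit(self, desk_field_config, tmp_path):
        out1 = generate_dataset(desk_field_config, 3, tmp_path / "a")
        manifest = json.loads((out1 / "manifest.json").read_text())
        cfg = FieldConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in manifest["config"].items()})
        out2 = generate_dataset(cfg, manifest["n_images"], tmp_path / "b")
        for sub in ("images", "masks"):
            for p in sorted((out1 / sub).iterdir()):
                assert p.read_bytes() == (out2 / sub / p.name).read_bytes()

    def test_round_trip_through_png(self, desk_field_config, tmp_path):
        from weedseg.cli_io import read_image, read_mask

        out = generate_dataset(desk_field_config, 1, tmp_path / "d")
        image, mask = generate_field(desk_field_config,
                                     np.random.default_rng([0, 0]))
        np.testing.assert_array_equal(read_mask(out / "masks" / "0000.png"), mask)
        # 8-bit quantisation: loaded image within half a grey level
        loaded = read_image(out / "images" / "0000.png")
        assert np.abs(loaded - image).max() <= 0.5 / 255 + 1e-6

    def test_overlapping_frames_share_content(self, desk_field_config, tmp_path):
        from weedseg.cli_io import read_image

        stride = 16
        out = generate_dataset(desk_field_config, 3, tmp_path / "d",
                               overlap_stride=stride)
        f0 = read_image(out / "images" / "0000.png")
        f1 = read_image(out / "images" / "0001.png")
        np.testing.assert_array_equal(f0[stride:], f1[:-stride])

    def test_invalid_arguments(self, desk_field_config, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(desk_field_config, 0, tmp_path / "d")
        with pytest.raises(ValueError):
            generate_dataset(desk_field_config, 2, tmp_path / "d",
                             overlap_stride=48)


class TestLearnability:
    def test_model_generalises_to_held_out_fields(self, desk_pairs):
        """A small model trained on 12 generated fields beats its untrained
        self on 5 held-out fields (fixed seeds end to end)."""
        from weedseg.models import MobileConfig, build_mobile, init_weights
        from weedseg.training import TrainConfig, downsample_mask, train_hard

        train, test = desk_pairs[:12], desk_pairs[15:]
        model = init_weights(build_mobile(MobileConfig(alpha=0.3)), seed=0)
        labels = [downsample_mask(m) for _, m in test]

        def err(m):
            return dice_error([argmax_classes(m.predict(img)) for img, _ in test],
                              labels)

        before = err(model)
        model = train_hard(model, train,
                           TrainConfig(epochs=20, batch_size=4, seed=0))
        assert err(model) < before
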