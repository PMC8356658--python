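"""Synthetic seed-image generator: determinism, class structure,
separability by an independent image-analysis rule, augmentation, splits."""

import numpy as np
import pytest
from skimage import measure

from seedsortnet import (
    SyntheticSpec,
    augment_x4,
    generate_dataset,
    train_test_split,
)
from seedsortnet.synthetic import load_dataset, save_dataset, to_input_batch


def object_count_rule(image: np.ndarray) -> int:
    """Independent oracle: global threshold + connected components.

    A normal seed image contains exactly one large bright object; abnormal
    images contain several objects, an irregular outline, or a split object.
    """
    gray = image.mean(axis=-1)
    mask = gray > 0.2
    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]
    return int((sizes > 20).sum())


class TestGeneration:
    def test_seeded_determinism_bytes(self):
        spec = SyntheticSpec(n_per_class=5, rng_seed=3)
        a, b = generate_dataset(spec), generate_dataset(spec)
        assert a.images.tobytes() == b.images.tobytes()
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_counts_and_balance(self):
        data = generate_dataset(SyntheticSpec(n_per_class=50, rng_seed=0))
        assert len(data) == 100
        assert (data.labels == 1).sum() == 50
        assert data.images.shape == (100, 100, 100, 3)

    def test_pixels_stay_in_unit_interval(self):
        data = generate_dataset(SyntheticSpec(n_per_class=10, noise_sd=0.5, rng_seed=1))
        assert data.images.min() >= 0.0 and data.images.max() <= 1.0

    def test_component_rule_separates_classes(self):
        """The connected-component rule labels >90% of 200 clean images."""
        data = generate_dataset(SyntheticSpec(n_per_class=100, noise_sd=0.0,
                                              rng_seed=42))
        preds = np.array([1 if object_count_rule(img) == 1 else 0
                          for img in data.images])
        assert (preds == data.labels).mean() > 0.9

    def test_noise_degrades_rule_accuracy_monotonically(self):
        """More pixel noise makes the thresholding rule worse on average."""
        def rule_acc(noise, seed):
            data = generate_dataset(SyntheticSpec(n_per_class=40, noise_sd=noise,
                                                  rng_seed=seed))
            preds = np.array([1 if object_count_rule(img) == 1 else 0
                              for img in data.images])
            return (preds == data.labels).mean()

        levels = [0.0, 0.15, 0.35]
        means = [np.mean([rule_acc(n, s) for s in (0, 1, 2)]) for n in levels]
        assert means[0] >= means[1] >= means[2]
        assert means[0] - means[2] > 0.05


class TestAugmentation:
    def test_factor_four_with_labels_copied(self):
        data = generate_dataset(SyntheticSpec(n_per_class=5, rng_seed=0))
        aug = augment_x4(data)
        assert len(aug) == 4 * len(data)
        np.testing.assert_array_equal(aug.labels, np.tile(data.labels, 4))

    def test_horizontal_flip_is_involution(self):
        data = generate_dataset(SyntheticSpec(n_per_class=3, rng_seed=0))
        aug = augment_x4(data)
        n = len(data)
        flipped_twice = aug.images[n:2 * n][:, :, ::-1]
        np.testing.assert_array_equal(flipped_twice, data.images)

    def test_rotation_is_quarter_turn(self):
        data = generate_dataset(SyntheticSpec(n_per_class=2, rng_seed=1))
        aug = augment_x4(data)
        n = len(data)
        np.testing.assert_array_equal(
            aug.images[3 * n:], np.rot90(data.images, k=1, axes=(1, 2)))


class TestSplit:
    def test_stratified_75_25(self):
        data = generate_dataset(SyntheticSpec(n_per_class=50, rng_seed=0))
        tr, te = train_test_split(data, 0.75, seed=0)
        assert len(tr) == 75 and len(te) == 25
        assert (tr.labels == 1).sum() == 37 or (tr.labels == 1).sum() == 38
        assert (tr.labels == 0).sum() + (te.labels == 0).sum() == 50

    def test_partitions_disjoint_and_exhaustive(self):
        data = generate_dataset(SyntheticSpec(n_per_class=20, rng_seed=5))
        tr, te = train_test_split(data, 0.75, seed=1)
        joined = np.concatenate([tr.images, te.images])
        # every original image appears exactly once across the two splits
        orig = {img.tobytes() for img in data.images}
        split = [img.tobytes() for img in joined]
        assert len(split) == len(data)
        assert set(split) == orig

    def test_same_seed_same_split(self):
        data = generate_dataset(SyntheticSpec(n_per_class=10, rng_seed=2))
        a = train_test_split(data, 0.75, seed=9)
        b = train_test_split(data, 0.75, seed=9)
        np.testing.assert_array_equal(a[0].images, b[0].images)

    def test_tiny_class_rejected(self):
        data = generate_dataset(SyntheticSpec(n_per_class=1, rng_seed=0))
        with pytest.raises(ValueError):
            train_test_split(data, 0.75, seed=0)


class TestIO:
    def test_png_roundtrip(self, tmp_path):
        data = generate_dataset(SyntheticSpec(n_per_class=4, rng_seed=7))
        save_dataset(data, tmp_path, train_fraction=0.75, seed=0)
        loaded = load_dataset(tmp_path)
        assert len(loaded) == len(data)
        assert sorted(loaded.labels) == sorted(data.labels)
        # 8-bit quantization bound
        first_saved = loaded.images[0]
        assert first_saved.min() >= 0 and first_saved.max() <= 1

    def test_manifest_lists_splits(self, tmp_path):
        import csv
        data = generate_dataset(SyntheticSpec(n_per_class=4, rng_seed=7))
        manifest = save_dataset(data, tmp_path, train_fraction=0.75, seed=0)
        rows = list(csv.DictReader(open(manifest)))
        assert {r["split"] for r in rows} == {"train", "test"}

    def test_resize_to_network_input(self):
        data = generate_dataset(SyntheticSpec(n_per_class=2, rng_seed=0))
        batch = to_input_batch(data, 224)
        assert batch.shape == (4, 224, 224, 3)
        assert batch.dtype == np.float32
        native = to_input_batch(data)
        assert native.shape == (4, 100, 100, 3)
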