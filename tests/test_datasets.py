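"""Dataset plumbing: synthetic generation, folder I/O, splitting, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lightmixer.datasets import (
    AugmentConfig,
    LabeledImageSet,
    TOMATO_CLASS_COUNTS,
    apportion,
    augmentation_pipeline,
    default_class_counts,
    default_recipes,
    generate_synthetic_dataset,
    load_image_folder,
    resize_images,
    split_dataset,
    to_network_input,
    validate_recipes,
)


def _label_only_set(class_counts):
    """A LabeledImageSet with shared 1x1 placeholder pixels, for split tests."""
    img = np.zeros((1, 1, 3), dtype=np.uint8)
    labels = np.concatenate(
        [np.full(n, k, dtype=np.int64) for k, n in enumerate(class_counts)]
    )
    return LabeledImageSet([img] * len(labels), labels,
                           [f"c{k}" for k in range(len(class_counts))])


class TestSplit:
    def test_single_class_of_100_splits_80_10_10(self):
        tr, va, te = split_dataset(_label_only_set([100, 3]), seed=0)
        counts = [s.class_counts()[0] for s in (tr, va, te)]
        assert counts == [80, 10, 10]

    def test_seven_items_apportion_by_largest_remainder(self):
        assert apportion(7, (0.8, 0.1, 0.1)) == [5, 1, 1]

    def test_partition_property(self, small_dataset):
        tr, va, te = split_dataset(small_dataset, seed=3)
        assert len(tr) + len(va) + len(te) == len(small_dataset)
        # proportions within one item per class
        for k in range(small_dataset.num_classes):
            n = small_dataset.class_counts()[k]
            for part, frac in zip((tr, va, te), (0.8, 0.1, 0.1)):
                assert abs(part.class_counts()[k] - n * frac) <= 1

    def test_split_is_deterministic(self, small_dataset):
        a = split_dataset(small_dataset, seed=5)
        b = split_dataset(small_dataset, seed=5)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.labels, pb.labels)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="need >= 3"):
            split_dataset(_label_only_set([10, 2]))

    def test_bad_fractions_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            split_dataset(small_dataset, fractions=(0.8, 0.1, 0.2))

    @settings(derandomize=True, max_examples=100)
    @given(n=st.integers(3, 10_000))
    def test_apportion_sums_and_stays_within_one(self, n):
        parts = apportion(n, (0.8, 0.1, 0.1))
        assert sum(parts) == n
        for got, frac in zip(parts, (0.8, 0.1, 0.1)):
            assert abs(got - n * frac) <= 1

    def test_real_dataset_bookkeeping(self):
        counts = list(TOMATO_CLASS_COUNTS.values())
        assert sum(counts) == 18_835
        tr, va, te = split_dataset(_label_only_set(counts), seed=0)
        assert len(tr) + len(va) + len(te) == 18_835


class TestGenerator:
    def test_default_counts_scale_the_real_profile(self):
        counts = default_class_counts()
        assert counts == [round(c / 50) for c in TOMATO_CLASS_COUNTS.values()]
        assert sum(counts) == 377

    def test_writes_expected_file_tree(self, tmp_path, two_class_recipes):
        ds = generate_synthetic_dataset(
            tmp_path, two_class_recipes, [5, 3], image_size=24, seed=1
        )
        assert sorted(p.name for p in tmp_path.iterdir()) == ["clean", "spotty"]
        assert len(list((tmp_path / "spotty").glob("*.png"))) == 5
        assert len(list((tmp_path / "clean").glob("*.png"))) == 3
        assert len(ds) == 8

    def test_byte_identical_under_seed(self, tmp_path, two_class_recipes):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_synthetic_dataset(a, two_class_recipes, [3, 3], 24, seed=9)
        generate_synthetic_dataset(b, two_class_recipes, [3, 3], 24, seed=9)
        for fa in sorted(a.rglob("*.png")):
            fb = b / fa.relative_to(a)
            assert fa.read_bytes() == fb.read_bytes()

    def test_round_trips_through_folder_loader(self, tmp_path, two_class_recipes):
        ds = generate_synthetic_dataset(
            tmp_path, two_class_recipes, [4, 3], image_size=24, seed=2
        )
        loaded = load_image_folder(tmp_path)
        # loader orders classes by sorted directory name: clean < spotty
        remap = {ds.class_names.index(n): i for i, n in enumerate(loaded.class_names)}
        assert sorted(loaded.class_names) == loaded.class_names
        assert np.array_equal(
            np.sort(loaded.labels), np.sort([remap[l] for l in ds.labels])
        )
        assert len(loaded) == 7

    def test_zero_count_rejected(self, two_class_recipes):
        with pytest.raises(ValueError, match="count"):
            generate_synthetic_dataset(None, two_class_recipes, [3, 0])

    def test_count_recipe_length_mismatch(self, two_class_recipes):
        with pytest.raises(ValueError):
            generate_synthetic_dataset(None, two_class_recipes, [3])

    def test_default_recipes_are_pairwise_distinct(self):
        validate_recipes(default_recipes())
        dup = [default_recipes()[0], default_recipes()[0]]
        with pytest.raises(ValueError, match="indistinguishable"):
            validate_recipes(dup)

    def test_classes_are_learnable_by_shallow_baseline(self):
        """A depth-2 MLP on downsampled pixels must separate the default
        classes, certifying the generator carries class signal."""
        from sklearn.neural_network import MLPClassifier

        ds = generate_synthetic_dataset(seed=0)
        tr, va, _ = split_dataset(ds, seed=0)
        feats = {
            tag: np.stack(resize_images(part.images, 16)).reshape(len(part), -1) / 255.0
            for tag, part in (("tr", tr), ("va", va))
        }
        clf = MLPClassifier(hidden_layer_sizes=(64,), max_iter=400, random_state=0)
        clf.fit(feats["tr"], tr.labels)
        assert clf.score(feats["va"], va.labels) > 0.8


class TestFolderLoader:
    def test_empty_class_directory_is_named_in_error(self, tmp_path):
        (tmp_path / "a").mkdir()
        (tmp_path / "b").mkdir()
        from PIL import Image

        Image.new("RGB", (8, 8)).save(tmp_path / "a" / "x.png")
        with pytest.raises(ValueError, match="b"):
            load_image_folder(tmp_path)

    def test_fewer_than_two_classes_rejected(self, tmp_path):
        (tmp_path / "only").mkdir()
        with pytest.raises(ValueError, match="at least 2"):
            load_image_folder(tmp_path)

    def test_undecodable_file_is_named_in_error(self, tmp_path):
        from PIL import Image

        for name in ("a", "b"):
            (tmp_path / name).mkdir()
            Image.new("RGB", (8, 8)).save(tmp_path / name / "ok.png")
        bad = tmp_path / "a" / "broken.png"
        bad.write_bytes(b"not an image")
        with pytest.raises(ValueError, match="broken.png"):
            load_image_folder(tmp_path)


class TestAugmentation:
    def test_output_is_always_224(self, rng):
        aug = augmentation_pipeline(seed=0)
        img = rng.integers(0, 255, size=(96, 128, 3), dtype=np.uint8)
        for _ in range(5):
            out = aug(img)
            assert out.shape == (224, 224, 3)
            assert out.dtype == np.uint8

    def test_identity_configuration_is_plain_resize(self, rng):
        from PIL import Image

        cfg = AugmentConfig(crop_scale=(1.0, 1.0), crop_ratio=(1.0, 1.0),
                            p_hflip=0.0, p_vflip=0.0, rotation_deg=0.0)
        aug = augmentation_pipeline(seed=0, cfg=cfg)
        img = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
        expected = np.asarray(
            Image.fromarray(img).resize((224, 224), Image.BILINEAR)
        )
        assert np.array_equal(aug(img), expected)

    def test_same_seed_same_outputs(self, rng):
        img = rng.integers(0, 255, size=(80, 80, 3), dtype=np.uint8)
        p1 = augmentation_pipeline(seed=4)
        p2 = augmentation_pipeline(seed=4)
        for _ in range(3):
            assert np.array_equal(p1(img), p2(img))

    def test_non_rgb_rejected(self):
        aug = augmentation_pipeline(seed=0)
        with pytest.raises(ValueError, match="RGB"):
            aug(np.zeros((64, 64), dtype=np.uint8))


def test_to_network_input_layout_and_range(small_dataset):
    x = to_network_input(small_dataset.images[:4])
    assert x.shape == (4, 3, 32, 32)
    assert x.dtype == np.float32
    assert x.min() >= -1.0 and x.max() <= 1.0
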