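import numpy as np
import pytest

from smearopt.data import (
    DISEASED,
    HEALTHY,
    ConfusionCounts,
    DatasetBundle,
    LabeledImage,
    augment,
    bundle_to_arrays,
    confusion_counts,
    load_image_folder,
    merge_datasets,
    resize_images,
    sensitivity_specificity_accuracy,
    split_dataset,
    write_image_folder,
)


def make_bundle(n_healthy, n_diseased, size=8, seed=0):
    rng = np.random.default_rng(seed)
    images = [
        LabeledImage(rng.integers(0, 256, (size, size, 3), dtype=np.uint8),
                     HEALTHY, f"h{i}")
        for i in range(n_healthy)
    ] + [
        LabeledImage(rng.integers(0, 256, (size, size, 3), dtype=np.uint8),
                     DISEASED, f"d{i}")
        for i in range(n_diseased)
    ]
    return DatasetBundle(images)


class TestMerge:
    def test_reference_subset_compositions_add_up(self):
        hybrid = merge_datasets(make_bundle(59, 49), make_bundle(130, 130))
        assert len(hybrid) == 368
        assert hybrid.class_counts() == {HEALTHY: 189, DISEASED: 179}

    def test_empty_is_identity(self):
        x = make_bundle(3, 2)
        merged = merge_datasets(DatasetBundle([]), x)
        assert len(merged) == 5
        assert merged.images == x.images

    def test_self_union_doubles(self):
        x = make_bundle(2, 2)
        assert len(merge_datasets(x, x)) == 8


class TestAugment:
    def test_six_fold_enlargement_preserves_class_balance(self):
        b = make_bundle(5, 3)
        out = augment(b)
        assert len(out) == 48
        assert out.class_counts() == {HEALTHY: 30, DISEASED: 18}

    def test_single_image_yields_all_six_transforms(self):
        out = augment(make_bundle(1, 0))
        assert len(out) == 6
        assert {im.transform for im in out.images} == {
            "identity", "reflect_h", "reflect_v", "rot90", "rot45", "rot_neg45"
        }
        assert len({im.source_id for im in out.images}) == 1

    def test_reflections_and_rot90_are_lossless_involutions(self):
        b = make_bundle(1, 0, size=12)
        orig = b.images[0].pixels
        by_t = {im.transform: im.pixels for im in augment(b).images}
        assert np.array_equal(by_t["reflect_h"][:, ::-1], orig)
        assert np.array_equal(by_t["reflect_v"][::-1, :], orig)
        r = orig
        for _ in range(4):
            r = np.rot90(r)
        assert np.array_equal(r, orig)
        assert np.array_equal(by_t["rot90"], np.rot90(orig))

    def test_double_augmentation_refused(self):
        once = augment(make_bundle(1, 1))
        with pytest.raises(ValueError, match="twice"):
            augment(once)

    def test_empty_bundle_refused(self):
        with pytest.raises(ValueError):
            augment(DatasetBundle([]))


class TestResize:
    def test_matching_size_is_a_pixel_noop(self):
        b = make_bundle(1, 0, size=64)
        out = resize_images(b, 64, 64)
        assert np.array_equal(out.images[0].pixels, b.images[0].pixels)

    def test_constant_image_stays_constant(self):
        px = np.full((128, 128, 3), 77, dtype=np.uint8)
        b = DatasetBundle([LabeledImage(px, HEALTHY, "c")])
        out = resize_images(b, 64, 64)
        assert out.images[0].pixels.shape == (64, 64, 3)
        assert np.all(out.images[0].pixels == 77)

    def test_arbitrary_shape_resized(self):
        px = np.random.default_rng(0).integers(0, 256, (257, 311, 3), dtype=np.uint8)
        b = DatasetBundle([LabeledImage(px, DISEASED, "x")])
        out = resize_images(b, 64, 64)
        assert out.images[0].pixels.shape == (64, 64, 3)


class TestSplit:
    def test_reference_composition_sizes(self):
        b = make_bundle(1134, 1074, size=2)
        out = split_dataset(b, seed=0)
        sizes = {k: len(v) for k, v in out.partitions.items()}
        assert sizes == {"train": 1768, "val": 220, "test": 220}

    def test_ten_images_floor_rule(self):
        out = split_dataset(make_bundle(5, 5, size=2), seed=0)
        sizes = {k: len(v) for k, v in out.partitions.items()}
        assert sizes == {"train": 8, "val": 1, "test": 1}

    def test_fewer_than_ten_images_warns_of_degenerate_partitions(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = split_dataset(make_bundle(3, 3, size=2), seed=0)
        assert len(out.partitions["val"]) == 0

    def test_partitions_disjoint_and_exhaustive(self):
        out = split_dataset(make_bundle(60, 40, size=2), seed=3)
        all_idx = sorted(sum(out.partitions.values(), []))
        assert all_idx == list(range(100))

    def test_stratified_by_class(self):
        out = split_dataset(make_bundle(100, 100, size=2), seed=1)
        for key, expected in [("val", 10), ("test", 10)]:
            labels = [out.images[i].label for i in out.partitions[key]]
            assert labels.count(HEALTHY) == expected
            assert labels.count(DISEASED) == expected

    def test_seed_determinism(self):
        b = make_bundle(30, 30, size=2)
        a = split_dataset(b, seed=5).partitions
        c = split_dataset(b, seed=5).partitions
        d = split_dataset(b, seed=6).partitions
        assert a == c
        assert a != d

    def test_split_by_source_keeps_variants_together(self):
        b = augment(make_bundle(20, 20, size=8))
        out = split_dataset(b, seed=0, by_source=True)
        src_part = {}
        for key, idxs in out.partitions.items():
            for i in idxs:
                src = out.images[i].source_id
                assert src_part.setdefault(src, key) == key

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(make_bundle(10, 10, size=2), fractions=(0.5, 0.2, 0.2))


class TestMetrics:
    def test_perfect_classifier(self):
        preds = [DISEASED] * 5 + [HEALTHY] * 5
        c = confusion_counts(preds, preds)
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 5, 0, 0)
        assert sensitivity_specificity_accuracy(c) == (1.0, 1.0, 1.0)

    def test_inverted_classifier(self):
        labels = np.array([DISEASED] * 5 + [HEALTHY] * 5)
        flipped = np.where(labels == DISEASED, HEALTHY, DISEASED)
        c = confusion_counts(flipped, labels)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 5, 5)

    def test_hand_built_vector_matches_manual_tally(self):
        rng = np.random.default_rng(7)
        labels = np.where(rng.random(20) < 0.5, DISEASED, HEALTHY)
        preds = labels.copy()
        miss = [2, 11]
        for i in miss:
            preds[i] = HEALTHY if preds[i] == DISEASED else DISEASED
        c = confusion_counts(preds, labels)
        assert c.total == 20
        assert c.fp + c.fn == 2
        assert c.tp == int(np.sum((preds == DISEASED) & (labels == DISEASED)))

    def test_hand_example_ratios(self):
        sn, sp, ac = sensitivity_specificity_accuracy(
            ConfusionCounts(tp=8, fn=2, tn=9, fp=1)
        )
        assert (sn, sp, ac) == (0.8, 0.9, 0.85)

    def test_undefined_ratio_is_nan_not_zero(self):
        sn, sp, ac = sensitivity_specificity_accuracy(
            ConfusionCounts(tp=0, fn=0, tn=3, fp=1)
        )
        assert np.isnan(sn)
        assert sp == 0.75

    def test_accuracy_decomposes_by_prevalence(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            c = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            sn, sp, ac = sensitivity_specificity_accuracy(c)
            P, N = tp + fn, tn + fp
            assert ac == pytest.approx((sn * P + sp * N) / (P + N))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts([DISEASED], [DISEASED, HEALTHY])


class TestIO:
    def test_folder_roundtrip(self, tmp_path):
        b = split_dataset(make_bundle(6, 6, size=16), seed=0)
        write_image_folder(b, tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        back = load_image_folder(tmp_path)
        assert len(back) == 12
        assert back.class_counts() == {HEALTHY: 6, DISEASED: 6}
        px = sorted(im.pixels.tobytes() for im in b.images)
        px2 = sorted(im.pixels.tobytes() for im in back.images)
        assert px == px2  # PNG is lossless

    def test_missing_folder_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_image_folder(tmp_path / "nope")

    def test_bundle_to_arrays_scaling_and_labels(self):
        b = make_bundle(2, 3, size=4)
        X, y = bundle_to_arrays(b)
        assert X.shape == (5, 3, 4, 4)
        assert X.min() >= 0.0 and X.max() <= 1.0
        assert list(y) == [0, 0, 1, 1, 1]

    def test_bundle_to_arrays_partition_selection(self):
        b = split_dataset(make_bundle(20, 20, size=4), seed=0)
        Xv, yv = bundle_to_arrays(b, "val")
        assert Xv.shape[0] == len(b.partitions["val"])
        with pytest.raises(KeyError):
            bundle_to_arrays(b, "nope")
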