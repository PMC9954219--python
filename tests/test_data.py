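"""Preprocessing, augmentation menu and fold-planner tests."""

import numpy as np
import pytest

from mbinet.data import (
    DataError,
    FoldPlan,
    LabeledImage,
    NormalizationStats,
    Rotate,
    Scale,
    StratificationError,
    Translate,
    VerticalFlip,
    apply_augmentation,
    build_fold_plan,
    default_augmentation_menu,
    load_dataset,
    resize_image,
    zscore_normalize,
)
from mbinet.labels import CLASS_NAMES, ClassLabel

PAPER_COUNTS = (300, 215, 215, 200, 200, 190)


def make_image(pixels, label=ClassLabel.NT):
    return LabeledImage(np.asarray(pixels, dtype=float), label, "test")


class TestResize:
    def test_identity_resize(self):
        rng = np.random.default_rng(0)
        img = make_image(rng.uniform(size=(224, 224, 3)))
        out = resize_image(img, (224, 224))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_constant_image_stays_constant(self):
        img = make_image(np.full((448, 448, 3), 0.37))
        out = resize_image(img, (224, 224))
        assert out.pixels.shape == (224, 224, 3)
        np.testing.assert_allclose(out.pixels, 0.37, atol=1e-12)

    def test_bilinear_upscale_matches_hand_computation(self):
        """2x2 checkerboard -> 4x4 against a direct bilinear gather using the
        centre-aligned convention src = (dst + 0.5) * scale - 0.5."""
        board = np.zeros((2, 2, 3))
        board[0, 1] = board[1, 0] = 1.0
        out = resize_image(make_image(board), (4, 4)).pixels

        def bilinear(src, i, j):
            y = (i + 0.5) * 0.5 - 0.5
            x = (j + 0.5) * 0.5 - 0.5
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            fy, fx = y - y0, x - x0
            val = 0.0
            for dy, wy in ((0, 1 - fy), (1, fy)):
                for dx, wx in ((0, 1 - fx), (1, fx)):
                    yy = min(max(y0 + dy, 0), src.shape[0] - 1)
                    xx = min(max(x0 + dx, 0), src.shape[1] - 1)
                    val += wy * wx * src[yy, xx]
            return val

        expected = np.array(
            [[bilinear(board[:, :, 0], i, j) for j in range(4)] for i in range(4)]
        )
        np.testing.assert_allclose(out[:, :, 0], expected, atol=1e-12)

    def test_zero_dimension_rejected(self):
        with pytest.raises(DataError):
            resize_image(LabeledImage(np.zeros((0, 4, 3)), ClassLabel.NT))


class TestZScore:
    def test_identity_stats(self):
        img = make_image(np.random.default_rng(1).uniform(size=(8, 8, 3)))
        out = zscore_normalize(img, NormalizationStats((0, 0, 0), (1, 1, 1)))
        np.testing.assert_array_equal(out, img.pixels)

    def test_image_equal_to_mean_is_zero(self):
        stats = NormalizationStats()
        img = make_image(np.broadcast_to(np.array(stats.mean), (4, 4, 3)).copy())
        np.testing.assert_allclose(zscore_normalize(img, stats), 0.0, atol=1e-12)

    def test_reference_channel_statistics(self):
        """Constant 0.5 image under the dataset-wide stats, checked against
        independent scalar arithmetic per channel."""
        stats = NormalizationStats()
        out = zscore_normalize(make_image(np.full((2, 2, 3), 0.5)), stats)
        expected = [
            (0.5 - 0.2552) / 0.4116,
            (0.5 - 0.4666) / 0.3645,
            (0.5 - 0.8804) / 0.2597,
        ]
        np.testing.assert_allclose(out[0, 0], expected, rtol=1e-12)

    def test_zero_std_rejected(self):
        with pytest.raises(DataError):
            NormalizationStats((0, 0, 0), (1, 0, 1))


class TestAugmentationMenu:
    def test_menu_has_exactly_ten_transforms(self):
        assert len(default_augmentation_menu()) == 10

    def test_one_image_yields_ten(self):
        img = make_image(np.random.default_rng(2).uniform(size=(32, 32, 3)))
        out = apply_augmentation(img)
        assert len(out) == 10
        assert all(o.label == img.label for o in out)
        assert all(o.pixels.shape == img.pixels.shape for o in out)

    def test_cardinality_scales_tenfold(self):
        imgs = [make_image(np.zeros((8, 8, 3)), ClassLabel(i % 6)) for i in range(33)]
        total = sum(len(apply_augmentation(im)) for im in imgs)
        assert total == 330

    def test_paper_faithful_audit_counts(self):
        from mbinet.data import paper_faithful_augmented_counts

        counts = dict(zip(CLASS_NAMES, PAPER_COUNTS))
        audited = paper_faithful_augmented_counts(counts)
        assert audited["NT"] == 3000
        assert sum(audited.values()) == 13200

    def test_vflip_is_involution(self):
        img = make_image(np.random.default_rng(3).uniform(size=(16, 16, 3)))
        once = VerticalFlip().apply(img.pixels)
        twice = VerticalFlip().apply(once)
        np.testing.assert_array_equal(twice, img.pixels)

    def test_rotation_of_centered_disk_is_stable(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (((yy - 31.5) ** 2 + (xx - 31.5) ** 2) <= 20**2).astype(float)
        pixels = np.stack([disk] * 3, axis=-1)
        out = Rotate(-30).apply(Rotate(+30).apply(pixels))
        # interior differs only by interpolation blur at the rim
        assert np.abs(out - pixels).mean() < 0.02

    def test_translate_moves_a_pixel_by_rounded_fraction(self):
        pixels = np.zeros((40, 40, 3))
        pixels[10, 12] = 1.0
        out = Translate(0.10, 0.10).apply(pixels)
        # shift = round(0.10 * 40) = 4 in both axes
        assert out[14, 16, 0] == 1.0
        assert out.sum() == pytest.approx(3.0)

    def test_parameter_bands_enforced(self):
        with pytest.raises(DataError):
            Rotate(5.0)
        with pytest.raises(DataError):
            Scale(1.5)
        with pytest.raises(DataError):
            Translate(0.3, 0.1)

    def test_rotation_and_scale_fill_borders_with_zero(self):
        pixels = np.ones((20, 20, 3))
        rot = Rotate(30).apply(pixels)
        assert rot.min() == 0.0  # corners exposed by rotation


class TestFoldPlan:
    def labels(self):
        return np.repeat(np.arange(6), PAPER_COUNTS)

    def test_reference_split_counts(self):
        plan = build_fold_plan(self.labels(), k=5, val_frac=0.2, seed=0)
        sizes = plan.split_counts()
        assert sizes["test"] == [264] * 5
        assert sizes["validation"] == [213] * 5
        assert sizes["train"] == [843] * 5

    def test_reference_per_class_validation_cells(self):
        plan = build_fold_plan(self.labels(), k=5, val_frac=0.2, seed=3)
        for fold in range(5):
            counts = plan.class_counts(fold, "validation")
            assert [counts[n] for n in CLASS_NAMES] == [48, 35, 35, 32, 32, 31]

    def test_every_sample_tests_exactly_once(self):
        labels = np.random.default_rng(5).integers(0, 6, size=200)
        plan = build_fold_plan(labels, k=5, seed=1)
        seen = np.concatenate([f["test"] for f in plan.folds])
        assert sorted(seen) == list(range(200))

    def test_parts_disjoint_and_exhaustive(self):
        labels = np.random.default_rng(6).integers(0, 6, size=150)
        plan = build_fold_plan(labels, k=5, seed=2)
        for fold in plan.folds:
            union = np.concatenate([fold[p] for p in ("train", "validation", "test")])
            assert len(union) == 150
            assert len(np.unique(union)) == 150

    def test_deterministic_given_seed(self):
        labels = self.labels()
        a = build_fold_plan(labels, seed=9)
        b = build_fold_plan(labels, seed=9)
        for fa, fb in zip(a.folds, b.folds):
            for part in fa:
                np.testing.assert_array_equal(fa[part], fb[part])

    def test_five_per_class_gives_one_test_each(self):
        labels = np.repeat(np.arange(6), 5)
        plan = build_fold_plan(labels, k=5, seed=0)
        for fold in range(5):
            counts = plan.class_counts(fold, "test")
            assert all(v == 1 for v in counts.values())

    def test_remainder_distributed_round_robin(self):
        labels = np.repeat(np.arange(6), 7)  # 7 per class, k=5
        plan = build_fold_plan(labels, k=5, seed=0)
        test_sizes = [len(f["test"]) for f in plan.folds]
        assert sum(test_sizes) == 42
        assert max(test_sizes) - min(test_sizes) <= 6  # per class at most +1

    def test_k_too_small_rejected(self):
        with pytest.raises(ValueError):
            build_fold_plan(np.zeros(10), k=1)

    def test_class_smaller_than_k_rejected(self):
        labels = [0] * 10 + [1] * 3
        with pytest.raises(StratificationError):
            build_fold_plan(labels, k=5)

    def test_json_roundtrip(self, tmp_path):
        labels = np.random.default_rng(7).integers(0, 6, size=60)
        plan = build_fold_plan(labels, k=5, seed=4)
        path = tmp_path / "plan.json"
        plan.to_json(path)
        back = FoldPlan.from_json(path)
        assert back.k == plan.k
        for fa, fb in zip(plan.folds, back.folds):
            for part in fa:
                np.testing.assert_array_equal(fa[part], fb[part])


class TestFolderIO:
    def test_roundtrip_via_generated_dataset(self, tmp_path):
        from mbinet.synthetic import PhantomParams, generate_dataset

        generate_dataset(2, PhantomParams(image_size=48, seed=5), tmp_path)
        images = load_dataset(tmp_path)
        assert len(images) == 12
        labels = sorted({im.label.name for im in images})
        assert labels == sorted(CLASS_NAMES)
        assert all(im.pixels.shape == (48, 48, 3) for im in images)
        assert all(0.0 <= im.pixels.min() and im.pixels.max() <= 1.0 for im in images)

    def test_missing_root_rejected(self, tmp_path):
        with pytest.raises(DataError):
            load_dataset(tmp_path / "nope")
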