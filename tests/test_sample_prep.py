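"""Patch-pool construction: threshold, mining, exclusion, cropping, augmentation."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.morphology import disk, opening

from renuseg.sample_prep import (
    NegativeMiningConfig,
    PatchSet,
    compute_negative_threshold,
    crop_negative_patches,
    exclude_annotated_regions,
    extract_negative_regions,
    extract_positive_patches,
)
from renuseg.synth import AnnotationSet, SynthConfig, generate_image


# ---------------------------------------------------------------------------
# threshold t = a * mean / std
# ---------------------------------------------------------------------------


class TestNegativeThreshold:
    def test_direct_arithmetic(self):
        # mu = 0.5, sigma = 0.4 -> t = 0.5 * 0.5 / 0.4 = 0.625
        red = np.array([0.1, 0.9, 0.1, 0.9])  # mean 0.5, std 0.4
        assert compute_negative_threshold(red, a=0.5) == pytest.approx(0.625)

    def test_default_scale_is_half(self):
        assert NegativeMiningConfig().a == 0.5

    def test_constant_image_errors(self):
        with pytest.raises(ValueError, match="standard deviation"):
            compute_negative_threshold(np.full((8, 8), 0.3))

    def test_threshold_between_class_means_for_balanced_classes(self):
        # with default colour means and roughly balanced pixel classes the
        # adaptive threshold separates nuclei (dark) from background (bright)
        cfg = SynthConfig(seed=0, n_nuclei=55, mean_long_axis=36,
                          noise_sd=0.05, placement="uniform", overlap_allowed=True)
        img, ann = generate_image(cfg)
        t = compute_negative_threshold(img[..., 0], a=0.5)
        assert cfg.nucleus_red_mean < t < cfg.background_red_mean


# ---------------------------------------------------------------------------
# negative region extraction
# ---------------------------------------------------------------------------


def _toy_image(nucleus_mask, lo=0.1, hi=0.9):
    img = np.full(nucleus_mask.shape + (3,), hi, dtype=np.float32)
    img[nucleus_mask] = lo
    # break exact constancy so std > 0 within classes
    img[0, 0, 0] = hi - 0.01
    return img


class TestExtractNegativeRegions:
    def test_matches_brute_force_morphology_oracle(self):
        # 64x64 toy image: background bright, one dark blob; compare against
        # per-pixel classification + identical morphology applied by hand
        nucleus = np.zeros((64, 64), dtype=bool)
        nucleus[20:40, 20:44] = True
        img = _toy_image(nucleus)
        # a chosen so t = a*mean/std lands between the two class intensities
        cfg = NegativeMiningConfig(a=0.2, opening_radius=3)
        got = extract_negative_regions(img, cfg)
        t = 0.2 * img[..., 0].mean() / img[..., 0].std()
        assert 0.1 < t < 0.9  # the threshold really separates the classes
        expected = opening(ndi.binary_fill_holes(img[..., 0] > t), disk(3))
        assert np.array_equal(got, expected)

    def test_all_nucleus_image_gives_empty_mask(self, caplog):
        img = np.full((64, 64, 3), 0.1, dtype=np.float32)
        img[0, 0, 0] = 0.12
        # t = a*mu/sigma is far above every red value -> empty mask, logged
        mask = extract_negative_regions(img, NegativeMiningConfig())
        assert not mask.any()

    def test_small_hole_is_filled(self):
        nucleus = np.zeros((96, 96), dtype=bool)
        nucleus[40:45, 40:45] = True  # 5-px dark hole inside bright region
        img = _toy_image(nucleus)
        cfg = NegativeMiningConfig(a=0.02, opening_radius=3)
        assert 0.1 < 0.02 * img[..., 0].mean() / img[..., 0].std() < 0.9
        mask = extract_negative_regions(img, cfg)
        assert mask[42, 42]


class TestExcludeAnnotated:
    def test_empty_exclusion_is_identity(self):
        mask = np.ones((32, 32), dtype=bool)
        labels = np.zeros((32, 32), dtype=np.int32)
        out = exclude_annotated_regions(mask, labels, margin=3)
        assert np.array_equal(out, mask)

    def test_full_exclusion_empties_mask(self):
        mask = np.ones((32, 32), dtype=bool)
        labels = np.ones((32, 32), dtype=np.int32)
        assert not exclude_annotated_regions(mask, labels).any()

    def test_set_algebra_oracle(self, rng):
        mask = rng.random((48, 48)) > 0.3
        labels = np.zeros((48, 48), dtype=np.int32)
        labels[10:20, 10:20] = 1
        labels[30:40, 5:12] = 2
        from skimage.morphology import dilation
        expected = mask & ~dilation(labels > 0, disk(4))
        got = exclude_annotated_regions(mask, labels, margin=4)
        assert np.array_equal(got, expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            exclude_annotated_regions(np.ones((4, 4), bool),
                                      np.zeros((5, 5), np.int32))


class TestCropNegatives:
    def test_footprints_disjoint_and_inside_mask(self, rng):
        mask = np.zeros((256, 256), dtype=bool)
        mask[10:200, 10:250] = True
        img = rng.random((256, 256, 3)).astype(np.float32)
        ps = crop_negative_patches(mask, img, n_max=6, seed=0)
        assert 1 <= len(ps) <= 6
        boxes = [(p["row"], p["col"]) for p in ps.provenance]
        for i, (r1, c1) in enumerate(boxes):
            assert mask[r1 : r1 + 64, c1 : c1 + 64].all()
            for r2, c2 in boxes[i + 1 :]:
                assert abs(r1 - r2) >= 64 or abs(c1 - c2) >= 64
        assert not ps.targets.any()
        assert (ps.polarity == "negative").all()

    def test_capacity_bound_single_window(self):
        mask = np.zeros((128, 128), dtype=bool)
        mask[0:64, 0:64] = True
        img = np.zeros((128, 128, 3), dtype=np.float32)
        ps = crop_negative_patches(mask, img, n_max=10, seed=1)
        assert len(ps) == 1

    def test_deterministic(self, rng):
        mask = rng.random((200, 200)) > 0.2
        img = rng.random((200, 200, 3)).astype(np.float32)
        a = crop_negative_patches(mask, img, n_max=4, seed=9)
        b = crop_negative_patches(mask, img, n_max=4, seed=9)
        assert np.array_equal(a.patches, b.patches)
        assert a.provenance == b.provenance


# ---------------------------------------------------------------------------
# positive extraction with 5-fold translation augmentation
# ---------------------------------------------------------------------------


class TestPositivePatches:
    def _annotation(self, shape, centers, radius=8):
        labels = np.zeros(shape, dtype=np.int32)
        for k, (r, c) in enumerate(centers, start=1):
            rr, cc = np.ogrid[: shape[0], : shape[1]]
            labels[(rr - r) ** 2 + (cc - c) ** 2 <= radius ** 2] = k
        return AnnotationSet(labels=labels, complete=True, source_image_id="t")

    def test_five_patches_per_nucleus(self, rng):
        ann = self._annotation((256, 256), [(100, 100), (180, 60)])
        img = rng.random((256, 256, 3)).astype(np.float32)
        ps = extract_positive_patches(img, ann)
        assert len(ps) == 5 * 2
        assert (ps.polarity == "positive").all()

    def test_augmentation_centers(self, rng):
        ann = self._annotation((256, 256), [(100, 100)])
        img = rng.random((256, 256, 3)).astype(np.float32)
        ps = extract_positive_patches(img, ann)
        corners = {(p["row"] + 32, p["col"] + 32) for p in ps.provenance}
        assert corners == {(100, 100), (84, 100), (116, 100), (100, 84), (100, 116)}

    def test_border_clamping(self, rng):
        ann = self._annotation((256, 256), [(5, 5)], radius=4)
        img = rng.random((256, 256, 3)).astype(np.float32)
        ps = extract_positive_patches(img, ann)
        assert len(ps) == 5
        for p in ps.provenance:
            assert 0 <= p["row"] <= 192 and 0 <= p["col"] <= 192

    def test_targets_are_union_of_annotated_nuclei(self, rng):
        # two nuclei inside one window: both appear in the target mask
        ann = self._annotation((256, 256), [(100, 100), (100, 120)])
        img = rng.random((256, 256, 3)).astype(np.float32)
        ps = extract_positive_patches(img, ann)
        first = ps.targets[0]  # centred window of nucleus 1 covers nucleus 2
        r0, c0 = ps.provenance[0]["row"], ps.provenance[0]["col"]
        expected = (ann.labels > 0)[r0 : r0 + 64, c0 : c0 + 64]
        assert np.array_equal(first, expected)
        assert expected[32, 52]  # the neighbour nucleus is inside and labelled

    def test_every_target_nonempty(self, small_tile, rng):
        img, ann = small_tile
        ps = extract_positive_patches(img, ann)
        assert len(ps) == 5 * ann.n_instances
        assert all(t.any() for t in ps.targets)

    def test_empty_annotations_error(self, rng):
        empty = AnnotationSet(labels=np.zeros((64, 64), np.int32), complete=True)
        with pytest.raises(ValueError):
            extract_positive_patches(rng.random((64, 64, 3)), empty)


class TestPatchSet:
    def test_negative_targets_must_be_zero(self, rng):
        with pytest.raises(ValueError):
            PatchSet(
                patches=rng.random((1, 64, 64, 3)).astype(np.float32),
                targets=np.ones((1, 64, 64), dtype=bool),
                polarity=np.array(["negative"], dtype=object),
            )

    def test_roundtrip(self, tmp_path, rng):
        ps = PatchSet(
            patches=rng.random((3, 64, 64, 3)).astype(np.float32),
            targets=rng.random((3, 64, 64)) > 0.5,
            polarity=np.array(["positive"] * 3, dtype=object),
            provenance=[{"source": "x", "nucleus": i, "offset": (0, 0),
                         "row": 0, "col": 0} for i in range(3)],
        )
        path = tmp_path / "pool.npz"
        ps.save(path)
        back = PatchSet.load(path)
        assert np.array_equal(ps.patches, back.patches)
        assert np.array_equal(ps.targets, back.targets)
        assert list(ps.polarity) == list(back.polarity)

    def test_concatenate_counts(self, rng):
        a = PatchSet(
            patches=rng.random((2, 64, 64, 3)).astype(np.float32),
            targets=np.zeros((2, 64, 64), dtype=bool),
            polarity=np.array(["negative"] * 2, dtype=object),
        )
        both = PatchSet.concatenate([a, PatchSet.empty(), a])
        assert len(both) == 4
        assert both.n_negative == 4
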