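"""Phantom generation, preprocessing, augmentation, splitting and file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from posam_ultra import (
    AugmentationConfig,
    BinaryMask,
    ImageVolume,
    PhantomSpec,
    PlacementError,
    generate_phantom,
    load_pair,
    minmax_normalize,
    resize_pair,
    save_pair,
    split_dataset,
)
from posam_ultra.phantom import (
    apply_augmentation,
    augment_pair,
    mask_sibling_path,
    sample_augmentation,
)


class TestGeneratePhantom:
    def test_fixed_seed_is_bit_identical(self):
        spec = PhantomSpec(seed=5)
        i1, m1 = generate_phantom(spec)
        i2, m2 = generate_phantom(spec)
        assert np.array_equal(i1.pixels, i2.pixels)
        assert np.array_equal(m1.pixels, m2.pixels)

    def test_no_tumors_gives_empty_mask(self):
        _, mask = generate_phantom(PhantomSpec(n_tumors=0, seed=1))
        assert mask.pixels.sum() == 0

    def test_mean_mask_fraction_matches_request(self):
        # Monte-Carlo over 100 phantoms at a requested 5% area fraction
        fracs = [
            generate_phantom(PhantomSpec(tumor_area_fraction=0.05, seed=s))[1]
            .pixels.mean()
            for s in range(100)
        ]
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_tumor_inside_brain_support(self):
        # noise-free phantom: the brain is exactly the bright region
        img, mask = generate_phantom(PhantomSpec(noise_sd=0.0, seed=3))
        brain = img.pixels.mean(axis=2) > 0.2
        assert np.all(brain[mask.pixels == 1])

    def test_oversized_tumor_raises(self):
        with pytest.raises(PlacementError):
            generate_phantom(PhantomSpec(height=32, width=32,
                                         tumor_area_fraction=0.3, seed=0))


class TestResizePair:
    def test_upscale_shapes(self, phantom64):
        img, msk = phantom64
        ri, rm = resize_pair(img, msk, size=256)
        assert ri.pixels.shape == (256, 256, 3)
        assert rm.pixels.shape == (256, 256)

    def test_identity_size_is_pixel_identical(self, phantom64):
        img, msk = phantom64
        ri, rm = resize_pair(img, msk, size=64)
        assert np.array_equal(ri.pixels, img.pixels)
        assert np.array_equal(rm.pixels, msk.pixels)

    def test_mask_stays_binary_under_upscaling(self):
        checker = np.indices((64, 64)).sum(axis=0) % 2
        img = ImageVolume(np.random.default_rng(0).random((64, 64, 3)))
        _, rm = resize_pair(img, BinaryMask(checker.astype(np.uint8)), size=256)
        assert set(np.unique(rm.pixels)) <= {0, 1}

    def test_shape_mismatch_raises(self, phantom64):
        img, _ = phantom64
        with pytest.raises(ValueError):
            resize_pair(img, BinaryMask(np.zeros((32, 32), dtype=np.uint8)))


class TestMinmaxNormalize:
    def test_output_spans_unit_interval(self):
        img = ImageVolume(np.arange(256, dtype=np.float64).reshape(16, 16)[:, :, None])
        out = minmax_normalize(img).pixels
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_image_maps_to_zeros(self):
        out = minmax_normalize(ImageVolume(np.full((8, 8, 1), 3.7))).pixels
        assert np.all(out == 0.0)

    def test_midpoint_arithmetic(self):
        arr = np.zeros((8, 8, 1))
        arr[0, 0] = 200.0
        arr[4, 4] = 100.0
        out = minmax_normalize(ImageVolume(arr)).pixels
        assert out[4, 4, 0] == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_nonconstant_output_always_in_unit_interval(self, seed):
        arr = np.random.default_rng(seed).normal(size=(8, 8, 3)) * 50 + 10
        out = minmax_normalize(ImageVolume(arr)).pixels
        assert out.min() == 0.0 and out.max() == 1.0


class TestAugmentation:
    def test_all_off_config_is_identity(self, phantom64, rng):
        img, msk = phantom64
        ai, am = augment_pair(img, msk, AugmentationConfig.identity(), rng)
        assert np.array_equal(ai.pixels, img.pixels)
        assert np.array_equal(am.pixels, msk.pixels)

    def test_double_horizontal_flip_restores(self, phantom64):
        img, msk = phantom64
        draw = {"angle": 0.0, "h_flip": True, "v_flip": False, "scale": 1.0,
                "brightness": 0.0, "contrast": 0.0}
        once = apply_augmentation(img, msk, draw)
        twice = apply_augmentation(*once, draw)
        assert np.array_equal(twice[0].pixels, img.pixels)
        assert np.array_equal(twice[1].pixels, msk.pixels)

    def test_sampled_rotation_angles_bounded(self, rng):
        cfg = AugmentationConfig()
        angles = [sample_augmentation(cfg, rng)["angle"] for _ in range(1000)]
        assert max(abs(a) for a in angles) <= 20.0

    def test_geometric_transforms_nearly_preserve_mask_area(self, phantom64, rng):
        img, msk = phantom64
        cfg = AugmentationConfig(scale_range=(1.0, 1.0), brightness_delta=0.0,
                                 contrast_delta=0.0)
        area = int(msk.pixels.sum())
        for _ in range(20):
            _, am = augment_pair(img, msk, cfg, rng)
            assert abs(int(am.pixels.sum()) - area) / area <= 0.05

    def test_invalid_scale_range_raises(self):
        with pytest.raises(ValueError):
            AugmentationConfig(scale_range=(1.1, 1.2))


class TestSplitDataset:
    def test_published_partition_sizes(self):
        split = split_dataset(3929)
        assert split.sizes() == (3143, 393, 393)

    def test_small_n_arithmetic(self):
        assert split_dataset(10).sizes() == (8, 1, 1)

    def test_too_few_items_raises(self):
        with pytest.raises(ValueError):
            split_dataset(2)

    @given(st.integers(10, 10000), st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_partition_is_disjoint_and_exhaustive(self, n, seed):
        split = split_dataset(n, seed=seed)
        allidx = np.concatenate([split.train, split.val, split.test])
        assert len(split.train) == int(np.floor(0.8 * n))
        assert len(allidx) == n
        assert len(np.unique(allidx)) == n


class TestFileIO:
    def test_tiff_round_trip_is_lossless(self, phantom64, tmp_path):
        img, msk = phantom64
        p = tmp_path / "slice.tif"
        save_pair(img, msk, p)
        li, lm = load_pair(p)
        assert np.allclose(li.pixels, img.pixels, atol=1e-7)  # float32 storage
        assert np.array_equal(lm.pixels, msk.pixels)

    def test_png_mask_binarized_from_255(self, tmp_path):
        from PIL import Image

        arr = np.zeros((16, 16), dtype=np.uint8)
        arr[2:6, 2:6] = 255
        img = (np.random.default_rng(0).random((16, 16)) * 255).astype(np.uint8)
        Image.fromarray(img).save(tmp_path / "a.png")
        Image.fromarray(arr).save(tmp_path / "a_mask.png")
        _, mask = load_pair(tmp_path / "a.png")
        assert set(np.unique(mask.pixels)) == {0, 1}
        assert np.array_equal(mask.pixels, (arr > 127).astype(np.uint8))

    def test_missing_mask_sibling_names_expected_path(self, phantom64, tmp_path):
        img, msk = phantom64
        p = tmp_path / "slice.tif"
        save_pair(img, msk, p)
        mask_sibling_path(p).unlink()
        with pytest.raises(FileNotFoundError, match="slice_mask.tif"):
            load_pair(p)
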