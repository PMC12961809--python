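"""Prior-channel pipeline: brain masking, z-scoring, intensity clustering,
candidate selection, morphological refinement and the assembled prior."""

import itertools

import numpy as np
import pytest

from posam_ultra import BinaryMask, ImageVolume, PhantomSpec, generate_phantom
from posam_ultra.prior import (
    assemble_four_channel,
    brain_mask_estimate,
    build_prior,
    kmeans_intensity,
    refine_mask,
    select_tumor_candidate,
    zscore,
)
from skimage import measure


class TestBrainMask:
    def test_covers_bright_ellipse(self):
        img, _ = generate_phantom(PhantomSpec(noise_sd=0.0, seed=2))
        ellipse = img.pixels.mean(axis=2) > 0.2
        mask = brain_mask_estimate(img).pixels.astype(bool)
        assert (mask & ellipse).sum() / ellipse.sum() >= 0.95

    def test_all_zero_image_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            mask = brain_mask_estimate(ImageVolume(np.zeros((16, 16, 1))))
        assert mask.pixels.sum() == 0

    def test_output_is_binary(self, phantom64):
        img, _ = phantom64
        assert set(np.unique(brain_mask_estimate(img).pixels)) <= {0, 1}


class TestZscore:
    def test_masked_moments(self, phantom64):
        img, _ = phantom64
        brain = brain_mask_estimate(img)
        z = zscore(img, brain).pixels[:, :, 0]
        inside = z[brain.pixels.astype(bool)]
        assert abs(inside.mean()) < 1e-6
        assert abs(inside.std() - 1.0) < 1e-6
        assert np.all(z[~brain.pixels.astype(bool)] == 0.0)

    def test_affine_invariance(self, phantom64):
        img, _ = phantom64
        brain = brain_mask_estimate(img)
        shifted = ImageVolume(2.5 * img.pixels + 0.7)
        assert np.allclose(zscore(img, brain).pixels,
                           zscore(shifted, brain).pixels, atol=1e-12)

    def test_constant_region_maps_to_zero(self):
        img = ImageVolume(np.full((16, 16, 1), 0.5))
        brain = BinaryMask(np.ones((16, 16), dtype=np.uint8))
        assert np.all(zscore(img, brain).pixels == 0.0)


def _wcss(values, labels):
    return sum(((values[labels == c] - values[labels == c].mean()) ** 2).sum()
               for c in np.unique(labels))


def _brute_force_1d_wcss(values, k=3):
    """Optimal k-partition of sorted 1-D data over contiguous split points."""
    v = np.sort(values)
    best = np.inf
    n = len(v)
    for i, j in itertools.combinations(range(1, n), 2):
        parts = [v[:i], v[i:j], v[j:]]
        cost = sum(((p - p.mean()) ** 2).sum() for p in parts)
        best = min(best, cost)
    return best


class TestKmeans:
    def test_three_separable_values_give_pure_clusters(self):
        rng = np.random.default_rng(0)
        vals = rng.choice([0.1, 0.5, 0.9], size=(16, 16))
        img = ImageVolume(vals[:, :, None])
        brain = BinaryMask(np.ones((16, 16), dtype=np.uint8))
        labels = kmeans_intensity(img, brain, seed=0)
        for c in range(3):
            assert np.unique(vals[labels == c]).size == 1

    def test_fixed_seed_reproducible(self, phantom64):
        img, _ = phantom64
        brain = brain_mask_estimate(img)
        l1 = kmeans_intensity(img, brain, seed=3)
        l2 = kmeans_intensity(img, brain, seed=3)
        assert np.array_equal(l1, l2)

    def test_wcss_close_to_brute_force_on_toy(self):
        rng = np.random.default_rng(1)
        vals = rng.random(20)
        img = ImageVolume(vals.reshape(4, 5).repeat(2, 0).repeat(2, 1)[:, :, None])
        brain = BinaryMask(np.ones(img.pixels.shape[:2], dtype=np.uint8))
        labels = kmeans_intensity(img, brain, seed=0)
        got = _wcss(img.pixels[:, :, 0][brain.pixels.astype(bool)],
                    labels[brain.pixels.astype(bool)])
        optimum = _brute_force_1d_wcss(img.pixels[:, :, 0].ravel())
        assert got <= optimum * (1 + 1e-9)

    def test_too_few_distinct_values_raise(self):
        img = ImageVolume(np.where(np.indices((8, 8)).sum(0) % 2, 0.2, 0.8)[:, :, None])
        brain = BinaryMask(np.ones((8, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            kmeans_intensity(img, brain, k=3)


class TestSelectCandidate:
    def test_highest_mean_cluster_selected(self):
        labels = np.array([[0, 1, 2]] * 3)
        img = np.array([[0.1, 0.5, 0.9]] * 3)
        sel = select_tumor_candidate(labels, img)
        assert np.array_equal(sel.pixels, (labels == 2).astype(np.uint8))

    def test_tie_breaks_to_lowest_index(self):
        labels = np.array([[0, 1], [0, 1]])
        img = np.full((2, 2), 0.5)
        sel = select_tumor_candidate(labels, img)
        assert np.array_equal(sel.pixels, (labels == 0).astype(np.uint8))

    def test_recovers_high_contrast_tumor(self):
        img, mask = generate_phantom(PhantomSpec(tumor_contrast=0.55, seed=9))
        brain = brain_mask_estimate(img)
        labels = kmeans_intensity(zscore(img, brain), brain, seed=0)
        sel = select_tumor_candidate(labels, zscore(img, brain))
        covered = (sel.pixels.astype(bool) & mask.pixels.astype(bool)).sum()
        assert covered / mask.pixels.sum() >= 0.8


class TestRefineMask:
    def test_full_grid_is_fixed_point(self):
        square = np.ones((10, 10), dtype=np.uint8)
        assert np.array_equal(refine_mask(BinaryMask(square)).pixels, square)

    def test_isolated_pixel_removed(self):
        m = np.zeros((9, 9), dtype=np.uint8)
        m[4, 4] = 1
        assert refine_mask(BinaryMask(m)).pixels.sum() == 0

    def test_interior_hole_filled(self):
        m = np.ones((12, 12), dtype=np.uint8)
        m[:1] = m[-1:] = m[:, :1] = m[:, -1:] = 0   # 10x10 solid block
        m[6, 6] = 0
        refined = refine_mask(BinaryMask(m))
        assert refined.pixels[6, 6] == 1

    def test_never_increases_component_count(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = (rng.random((24, 24)) > 0.7).astype(np.uint8)
            before = measure.label(m, connectivity=1).max()
            after_mask = refine_mask(BinaryMask(m)).pixels
            after = measure.label(after_mask, connectivity=1).max()
            assert after <= before


class TestBuildPrior:
    def test_values_in_unit_interval_and_deterministic(self, phantom64):
        img, _ = phantom64
        p1 = build_prior(img, seed=0).pixels
        p2 = build_prior(img, seed=0).pixels
        assert np.array_equal(p1, p2)
        assert p1.min() >= 0.0 and p1.max() <= 1.0

    def test_mean_prior_contrast_across_phantoms(self):
        deltas = []
        for s in range(20):
            img, mask = generate_phantom(PhantomSpec(seed=s))
            prior = build_prior(img, seed=s).pixels[:, :, 0]
            inside = prior[mask.pixels == 1].mean()
            outside = prior[mask.pixels == 0].mean()
            deltas.append(inside - outside)
        assert np.mean(deltas) >= 0.3

    def test_affine_intensity_invariance(self):
        for s in range(10):
            img, _ = generate_phantom(PhantomSpec(seed=100 + s))
            scaled = ImageVolume(3.0 * img.pixels + 1.5)
            assert np.array_equal(build_prior(img, seed=s).pixels,
                                  build_prior(scaled, seed=s).pixels)

    def test_support_inside_brain_mask(self, phantom64):
        img, _ = phantom64
        prior = build_prior(img, seed=0).pixels[:, :, 0]
        brain = brain_mask_estimate(img).pixels.astype(bool)
        assert np.all(brain[prior > 0])


class TestAssembleFourChannel:
    def test_stacks_prior_last(self, phantom64):
        img, _ = phantom64
        prior = build_prior(img, seed=0)
        x = assemble_four_channel(img, prior)
        assert x.shape == (4, 64, 64)
        assert np.array_equal(x[:3], np.moveaxis(img.pixels, 2, 0))
        assert np.array_equal(x[3], prior.pixels[:, :, 0])

    def test_single_channel_image_rejected(self):
        img = ImageVolume(np.zeros((16, 16, 1)))
        with pytest.raises(ValueError):
            assemble_four_channel(img, np.zeros((16, 16)))

    def test_shape_mismatch_rejected(self, phantom64):
        img, _ = phantom64
        with pytest.raises(ValueError):
            assemble_four_channel(img, np.zeros((32, 32)))
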