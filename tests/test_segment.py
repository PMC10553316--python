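import dataclasses

import numpy as np
import pytest

from stainquant import (
    ParameterError,
    PipelineConfig,
    binarize_hos,
    denoise_small_objects,
    density_filter,
    dilate_mask,
    fill_solid,
    fourth_central_moment_map,
    generate_slide,
    hos_transform,
    local_density,
    segment_roi,
    to_grayscale,
)


def brute_force_mu4(img, r):
    """Independent per-pixel fourth-central-moment loop (edge-repeating reflection)."""
    x = np.asarray(img, dtype=float)
    p = np.pad(x, r, mode="symmetric")
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            win = p[i : i + 2 * r + 1, j : j + 2 * r + 1]
            out[i, j] = np.mean((win - win.mean()) ** 4)
    return out


class TestHOS:
    def test_constant_image_is_zero(self):
        for v in (0, 128, 255):
            hos = hos_transform(np.full((12, 15), v, np.uint8), 2)
            assert (hos == 0).all()

    def test_cap_saturates_on_checkerboard(self):
        img = (np.indices((10, 10)).sum(axis=0) % 2 * 255).astype(np.uint8)
        # windows hold near-equal counts of 0 and 255: moment ~127.5**4 >> 255*300
        assert (hos_transform(img, 1) == 255).all()

    def test_matches_bruteforce_on_random_image(self, rng):
        img = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        got = fourth_central_moment_map(img, 1)
        want = brute_force_mu4(img, 1)
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_monotone_cap(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        assert hos_transform(img, 2).max() <= 255.0

    def test_oversized_window_rejected(self):
        with pytest.raises(ParameterError):
            hos_transform(np.zeros((3, 3), np.uint8), window_radius=4)


class TestBinarize:
    def test_cutoff_is_inclusive(self):
        hos = np.array([[0.0, 20.0, 255.0]])
        mask = binarize_hos(hos, 20)
        np.testing.assert_array_equal(mask, [[False, True, True]])

    def test_all_zero_map_empty(self):
        assert not binarize_hos(np.zeros((4, 4)), 20).any()

    def test_equals_elementwise_comparison(self, rng):
        hos = rng.uniform(0, 255, (30, 30))
        np.testing.assert_array_equal(binarize_hos(hos, 77.7), hos >= 77.7)


class TestLocalDensity:
    def test_equidistant_neighbors_give_exp_minus_one(self):
        # center point with 4 neighbors all at distance 5: distances cancel
        coords = np.array([(0, 0), (5, 0), (-5, 0), (0, 5), (0, -5)])
        ld = local_density(coords, k=4)
        assert ld[0] == pytest.approx(np.exp(-1), abs=1e-12)

    def test_unit_lattice_interior(self):
        yy, xx = np.mgrid[0:7, 0:7]
        coords = np.stack([yy.ravel(), xx.ravel()], axis=1)
        ld = local_density(coords, k=4)
        center = np.flatnonzero((coords == [3, 3]).all(axis=1))[0]
        assert ld[center] == pytest.approx(np.exp(-1), abs=1e-12)

    def test_isolated_point_scores_below_block(self):
        yy, xx = np.mgrid[0:30, 0:30]
        block = np.stack([yy.ravel(), xx.ravel()], axis=1)
        coords = np.vstack([block, [[15, 130]]])
        ld = local_density(coords, k=10)
        assert ld[-1] < ld[:-1].min()

    def test_single_point_is_zero(self):
        assert local_density(np.array([[3, 4]]), k=5)[0] == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ParameterError):
            local_density(np.empty((0, 2)), k=3)

    def test_k_reduced_when_few_points(self):
        coords = np.array([(0, 0), (0, 1), (1, 0)])
        ld = local_density(coords, k=10)  # only 2 neighbors exist
        assert (ld > 0).all() and (ld <= 1).all()


class TestDensityFilter:
    def test_zero_cutoff_is_identity(self, rng):
        mask = rng.random((20, 20)) < 0.3
        np.testing.assert_array_equal(density_filter(mask, 5, 0.0), mask)

    def test_coherent_blob_fully_retained_at_default_cutoff(self):
        mask = np.zeros((60, 220), bool)
        mask[10:40, 10:40] = True  # dense blob
        singles = [(5, 100), (50, 120), (10, 160), (40, 200), (25, 210)]
        for r, c in singles:
            mask[r, c] = True
        out = density_filter(mask, k=10, ld_cutoff=0.3)
        assert out[10:40, 10:40].all()

    def test_ld_jensen_lower_bound(self, rng):
        # mean(exp(-d/dbar)) >= exp(-1) for any multi-point set, with
        # equality only for equidistant neighbors: LD lives in [1/e, 1)
        coords = np.argwhere(rng.random((40, 40)) < 0.15)
        ld = local_density(coords, k=8)
        assert (ld >= np.exp(-1) - 1e-12).all()
        assert (ld < 1.0).all()

    def test_output_subset_of_input(self, rng):
        mask = rng.random((30, 30)) < 0.2
        out = density_filter(mask, 10, 0.3)
        assert not (out & ~mask).any()

    def test_empty_in_empty_out(self):
        assert not density_filter(np.zeros((5, 5), bool), 3, 0.5).any()


class TestMorphology:
    def test_dilate_single_pixel_radius_one_is_plus(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        out = dilate_mask(mask, 1)
        want = np.zeros((5, 5), bool)
        want[2, 1:4] = True
        want[1:4, 2] = True
        np.testing.assert_array_equal(out, want)

    def test_dilate_radius_zero_identity(self, rng):
        mask = rng.random((10, 10)) < 0.5
        np.testing.assert_array_equal(dilate_mask(mask, 0), mask)

    def test_dilate_full_mask_absorbing_and_superset(self, rng):
        full = np.ones((8, 8), bool)
        np.testing.assert_array_equal(dilate_mask(full, 2), full)
        mask = rng.random((20, 20)) < 0.2
        assert (dilate_mask(mask, 2) & mask).sum() == mask.sum()

    def test_fill_hollow_ring_becomes_solid(self):
        ring = np.zeros((9, 9), bool)
        ring[2:7, 2:7] = True
        ring[3:6, 3:6] = False
        out = fill_solid(ring)
        assert out[2:7, 2:7].all()

    def test_border_bay_not_filled(self):
        # U-shape open to the border: the bay is border-connected background
        mask = np.zeros((6, 7), bool)
        mask[1:6, 1] = True
        mask[1:6, 5] = True
        mask[5, 1:6] = True
        out = fill_solid(mask)
        assert not out[0:5, 2:5].any()

    def test_fill_no_holes_identity(self, rng):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:8] = True
        np.testing.assert_array_equal(fill_solid(mask), mask)


class TestDenoise:
    @staticmethod
    def _mask_with_areas(areas):
        """Disjoint rectangles of the requested pixel areas on one canvas."""
        mask = np.zeros((60, 40 * len(areas)), bool)
        for i, a in enumerate(areas):
            h = min(50, a)
            w, rem = divmod(a, h)
            mask[:h, 40 * i : 40 * i + w] = True
            if rem:
                mask[:rem, 40 * i + w] = True
        assert mask.sum() == sum(areas)
        return mask

    def test_cumulative_area_retention(self):
        mask = self._mask_with_areas([900, 90, 10])
        out = denoise_small_objects(mask, 0.95)
        assert out.sum() == 990  # 900+90 reaches 99% >= 95%; the 10-px blob goes

    def test_single_object_always_kept(self):
        mask = self._mask_with_areas([37])
        np.testing.assert_array_equal(denoise_small_objects(mask, 0.95), mask)

    def test_equal_halves_both_kept(self):
        mask = self._mask_with_areas([500, 500])
        np.testing.assert_array_equal(denoise_small_objects(mask, 0.95), mask)

    def test_empty_mask(self):
        assert not denoise_small_objects(np.zeros((5, 5), bool), 0.95).any()

    def test_output_subset(self, rng):
        mask = rng.random((40, 40)) < 0.4
        out = denoise_small_objects(mask, 0.8)
        assert not (out & ~mask).any()


class TestSegmentROI:
    def test_blank_image_gives_empty_roi(self):
        roi = segment_roi(np.full((64, 64), 200, np.uint8), PipelineConfig())
        assert not roi.any()

    def test_recovers_synthetic_object(self, small_slide):
        gray = to_grayscale(small_slide.image)
        roi = segment_roi(gray, PipelineConfig())
        truth = small_slide.roi_truth
        iou = (roi & truth).sum() / (roi | truth).sum()
        assert iou >= 0.9

    def test_noise_free_object_nearly_fully_covered(self, small_slide):
        params = dataclasses.replace(small_slide.params, n_noise_blobs=0)
        slide = generate_slide(params, seed=7)
        roi = segment_roi(to_grayscale(slide.image), PipelineConfig())
        covered = (roi & slide.roi_truth).sum() / slide.roi_truth.sum()
        assert covered >= 0.95

    def test_deterministic(self, small_slide):
        gray = to_grayscale(small_slide.image)
        a = segment_roi(gray, PipelineConfig())
        b = segment_roi(gray, PipelineConfig())
        np.testing.assert_array_equal(a, b)
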