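import numpy as np
import pytest

from conftest import brute_force_mean_filter, clean_spec
from pccount.errors import DegenerateImageError, ParameterError
from pccount.image_io import Image8, ImageF
from pccount.segmentation import (IntensityProfile, SegmentationParams,
                                  dual_filter_subtract, mean_filter,
                                  otsu_binarize, probe_intensity_vs_radius,
                                  remove_small_regions, segment_cells)
from pccount.synthetic import generate_scene


class TestSegmentationParams:
    @pytest.mark.parametrize("rs,rl,ma", [(0, 5, 8), (5, 5, 8), (7, 3, 8),
                                          (2, 5, 0)])
    def test_invalid_combinations_rejected(self, rs, rl, ma):
        with pytest.raises(ParameterError):
            SegmentationParams(r_small=rs, r_large=rl, min_area=ma)


class TestMeanFilter:
    def test_constant_image_unchanged(self):
        img = Image8(np.full((12, 12), 100, np.uint8))
        for r in (0, 1, 5):
            assert np.allclose(mean_filter(img, r).pixels, 100.0)

    def test_single_bright_pixel_r1(self):
        # r=1 disk has 5 pixels; a lone 255 spreads as 255/5 = 51
        pixels = np.zeros((7, 7), np.uint8)
        pixels[3, 3] = 255
        out = mean_filter(Image8(pixels), 1).pixels
        assert out[3, 3] == pytest.approx(51.0)
        assert out[3, 4] == pytest.approx(51.0)
        assert out[4, 4] == pytest.approx(0.0)  # diagonal not in the disk

    @pytest.mark.parametrize("radius", [1, 2, 3, 5])
    def test_matches_brute_force_oracle(self, rng, radius):
        pixels = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        expected = brute_force_mean_filter(pixels, radius)
        got = mean_filter(Image8(pixels), radius).pixels
        assert np.abs(got - expected).max() <= 1e-9

    def test_radius_zero_identity(self, rng):
        pixels = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        np.testing.assert_array_equal(mean_filter(Image8(pixels), 0).pixels,
                                      pixels.astype(float))

    def test_negative_radius_rejected(self):
        with pytest.raises(ParameterError):
            mean_filter(Image8(np.zeros((4, 4), np.uint8)), -1)


class TestDualFilterSubtract:
    def test_constant_image_gives_zeros(self):
        img = Image8(np.full((20, 20), 77, np.uint8))
        out = dual_filter_subtract(img, SegmentationParams(3, 9))
        assert np.allclose(out.pixels, 0.0)

    def test_equal_radii_hook_gives_zeros(self, rng):
        img = Image8(rng.integers(0, 256, (20, 20)).astype(np.uint8))
        out = dual_filter_subtract(img, SegmentationParams(3, 9), _r_small=9)
        assert np.allclose(out.pixels, 0.0)

    def test_maximum_lies_inside_a_cell(self):
        spec = clean_spec(shape=(200, 200), n_cells=3, seed=2)
        pc, _, truth = generate_scene(spec)
        diff = dual_filter_subtract(pc, SegmentationParams(5, 18))
        peak = np.unravel_index(np.argmax(diff.pixels), diff.pixels.shape)
        dists = np.hypot(*(truth.centers - np.asarray(peak)).T)
        assert dists.min() <= truth.radii[np.argmin(dists)]


class TestOtsu:
    def test_half_and_half(self):
        pixels = np.zeros((20, 20))
        pixels[:, 10:] = 255.0
        mask = otsu_binarize(ImageF(pixels)).pixels
        assert np.all(mask[:, 10:] == 1)
        assert np.all(mask[:, :10] == 0)

    def test_two_gaussian_mixture_splits_evenly(self, rng):
        n = 10_000
        values = np.concatenate([rng.normal(50, 10, n), rng.normal(200, 10, n)])
        img = ImageF(values.reshape(200, 100))
        frac = otsu_binarize(img).pixels.mean()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_matches_exhaustive_threshold_search(self, rng):
        # oracle: evaluate the between-class variance at every 256-bin cut
        values = np.concatenate([rng.normal(80, 25, 3000),
                                 rng.normal(180, 15, 1500)])
        img = ImageF(values.reshape(90, 50))
        pixels = img.pixels
        lo, hi = pixels.min(), pixels.max()
        scaled = (pixels - lo) * 255.0 / (hi - lo)
        hist, _ = np.histogram(scaled, bins=256, range=(0.0, 256.0))
        best, best_thresh = -1.0, None
        total = hist.sum()
        centers = np.arange(256) + 0.5
        for t in range(1, 256):
            w0 = hist[:t].sum()
            w1 = total - w0
            if w0 == 0 or w1 == 0:
                continue
            mu0 = (hist[:t] * centers[:t]).sum() / w0
            mu1 = (hist[t:] * centers[t:]).sum() / w1
            var = w0 * w1 * (mu0 - mu1) ** 2
            if var > best:
                best, best_thresh = var, t
        expected = (scaled > best_thresh).astype(np.uint8)
        np.testing.assert_array_equal(otsu_binarize(img).pixels, expected)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            otsu_binarize(ImageF(np.full((5, 5), 3.0)))


class TestRemoveSmallRegions:
    def _mask_with_component(self, n_pixels):
        from pccount.image_io import BinaryMask

        pixels = np.zeros((10, 10), np.uint8)
        pixels.flat[:n_pixels] = 0
        pixels[0, :n_pixels] = 1  # a horizontal run of n pixels
        return BinaryMask(pixels)

    def test_seven_pixels_removed_eight_kept(self):
        assert remove_small_regions(self._mask_with_component(7), 8) \
            .pixels.sum() == 0
        assert remove_small_regions(self._mask_with_component(8), 8) \
            .pixels.sum() == 8

    def test_empty_mask_unchanged(self):
        from pccount.image_io import BinaryMask

        out = remove_small_regions(BinaryMask(np.zeros((6, 6))), 8)
        assert out.pixels.sum() == 0

    def test_monotone_in_min_area(self, small_scene):
        from skimage import measure

        spec, pc, _, _ = small_scene
        diff = dual_filter_subtract(pc, SegmentationParams(7, 13))
        mask = otsu_binarize(ImageF(np.maximum(diff.pixels, 0)))
        counts = []
        for min_area in (1, 4, 8, 16, 32):
            cleaned = remove_small_regions(mask, min_area)
            counts.append(measure.label(cleaned.pixels, connectivity=2).max())
        assert counts == sorted(counts, reverse=True)


class TestSegmentCells:
    def test_exact_count_on_clean_scenes(self):
        exact = 0
        for seed in range(20):
            pc, _, truth = generate_scene(clean_spec(seed=seed))
            regions = segment_cells(pc, SegmentationParams(7, 18))
            exact += regions.n_regions == truth.true_count
        assert exact >= 19  # count error 0 for >= 95% of seeds

    def test_blank_field_raises_degenerate(self):
        from pccount.synthetic import SceneSpec

        spec = SceneSpec(shape=(64, 64), n_cells=0, n_noise_blobs=0,
                         background_noise_sd=0.0, seed=0)
        pc, _, _ = generate_scene(spec)
        with pytest.raises(DegenerateImageError):
            segment_cells(pc, SegmentationParams(3, 9))

    def test_deterministic(self, small_scene):
        spec, pc, _, _ = small_scene
        a = segment_cells(pc, SegmentationParams(7, 13))
        b = segment_cells(pc, SegmentationParams(7, 13))
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_count_invariant_under_whole_pixel_translation(self):
        pc, _, truth = generate_scene(clean_spec(shape=(300, 300),
                                                 n_cells=10, seed=4))
        base = segment_cells(pc, SegmentationParams(7, 18)).n_regions
        shifted = np.roll(pc.pixels, (3, 5), axis=(0, 1))
        moved = segment_cells(Image8(shifted), SegmentationParams(7, 18))
        assert moved.n_regions == base


class TestIntensityProfile:
    def test_flat_profile_on_constant_image(self):
        img = Image8(np.full((40, 40), 90, np.uint8))
        prof = probe_intensity_vs_radius(img, [(20, 20), (10, 30)], [1, 3, 5])
        assert prof.mean_intensities == pytest.approx([90.0] * 3)

    def test_single_radius(self):
        img = Image8(np.full((10, 10), 7, np.uint8))
        prof = probe_intensity_vs_radius(img, [(5, 5)], [2])
        assert len(prof.radii) == 1

    def test_peak_radius_between_R_and_2R(self, default_scene):
        spec, pc, _, truth = default_scene
        centers = np.rint(truth.centers).astype(int)
        radii = list(range(2, 41, 2))
        prof = probe_intensity_vs_radius(pc, centers, radii)
        R = spec.cell_radius_mean
        assert R <= prof.argmax_radius <= 2 * R
        # rises to the peak, falls after it
        peak = int(np.argmax(prof.mean_intensities))
        assert prof.mean_intensities[peak] > prof.mean_intensities[0]
        assert prof.mean_intensities[peak] > prof.mean_intensities[-1]

    def test_out_of_bounds_point_rejected(self):
        img = Image8(np.zeros((10, 10), np.uint8))
        with pytest.raises(ParameterError):
            probe_intensity_vs_radius(img, [(10, 0)], [1])

    def test_radii_must_increase(self):
        with pytest.raises(ParameterError):
            IntensityProfile(radii=[3, 3], mean_intensities=[1.0, 2.0])
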