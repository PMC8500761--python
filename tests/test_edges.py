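"""Canny stages vs brute-force oracles, plus cross-check against scikit-image."""

import numpy as np
import pytest
from scipy import ndimage

from wristseg import (
    CannyEdgeDetector,
    CannyParams,
    canny_detect,
    compute_gradient,
    gaussian_smooth,
    hysteresis_link,
    nonmax_suppress,
)
from wristseg.edges import GradientField, gaussian_kernel

from oracles import (
    direct_convolve_reflect,
    finite_difference_gradient,
    hysteresis_bfs,
    nms_double_loop,
)


class TestGaussianSmooth:
    def test_kernel_normalized_and_symmetric(self):
        k = gaussian_kernel(1.3)
        assert k.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(k, k[::-1, :]) and np.allclose(k, k[:, ::-1])

    def test_constant_image_unchanged(self):
        img = np.full((9, 9), 0.37)
        assert np.allclose(gaussian_smooth(img, sigma=2.0), 0.37, atol=1e-12)

    def test_matches_direct_convolution(self, rng):
        img = rng.uniform(size=(7, 9))
        k = gaussian_kernel(1.0, radius=3)
        out = gaussian_smooth(img, sigma=1.0, radius=3)
        assert np.allclose(out, direct_convolve_reflect(img, k), atol=1e-12)

    def test_impulse_center_equals_central_weight(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        k = gaussian_kernel(1.0, radius=3)
        out = gaussian_smooth(img, sigma=1.0, radius=3)
        assert out[4, 4] == pytest.approx(k[3, 3])

    def test_larger_sigma_never_increases_total_variation(self, default_phantom):
        img = default_phantom.image

        def tv(a):
            return np.abs(np.diff(a, axis=0)).sum() + np.abs(np.diff(a, axis=1)).sum()

        tvs = [tv(gaussian_smooth(img, s)) for s in (0.5, 1.0, 2.0, 4.0)]
        assert all(a >= b - 1e-9 for a, b in zip(tvs, tvs[1:]))

    def test_mean_preserved_on_checkerboard(self):
        img = np.indices((12, 12)).sum(axis=0) % 2 * 0.5 + 0.25
        out = gaussian_smooth(img, sigma=1.5)
        assert out.mean() == pytest.approx(img.mean(), abs=1e-6)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.ones((5, 5)), sigma=0.0)


class TestGradient:
    def test_constant_image_zero_gradient(self):
        f = compute_gradient(np.full((5, 5), 0.4))
        assert np.all(f.magnitude == 0)

    def test_column_ramp(self):
        w = 10
        img = np.tile(np.arange(w) / w, (6, 1))
        f = compute_gradient(img)
        assert np.allclose(f.gx[:, 1:-1], 1.0 / w)
        assert np.allclose(f.gy, 0.0)
        assert np.allclose(f.direction[:, 1:-1], 0.0)

    def test_matches_elementwise_oracle(self, rng):
        img = rng.uniform(size=(6, 6))
        f = compute_gradient(img)
        gx, gy = finite_difference_gradient(img)
        assert np.allclose(f.gx, gx, atol=1e-12)
        assert np.allclose(f.gy, gy, atol=1e-12)
        assert np.allclose(f.magnitude, np.hypot(gx, gy), atol=1e-12)
        assert np.allclose(f.direction, np.arctan2(gy, gx), atol=1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            compute_gradient(np.ones((2, 5)))


class TestNonmaxSuppress:
    def test_constant_field_all_zero(self):
        mag = np.full((6, 6), 0.5)
        f = GradientField(
            gx=np.ones((6, 6)), gy=np.zeros((6, 6)),
            magnitude=mag, direction=np.zeros((6, 6)),
        )
        assert np.all(nonmax_suppress(f) == 0)

    def test_isolated_peak_preserved(self):
        mag = np.zeros((5, 5))
        mag[2, 2] = 1.0
        f = GradientField(
            gx=np.ones((5, 5)), gy=np.zeros((5, 5)),
            magnitude=mag, direction=np.zeros((5, 5)),
        )
        out = nonmax_suppress(f)
        assert out[2, 2] == 1.0
        assert out.sum() == 1.0

    def test_blurred_vertical_step_thins_to_one_column_per_row(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 1.0
        smoothed = gaussian_smooth(img, sigma=1.5)
        nms = nonmax_suppress(compute_gradient(smoothed))
        band = nms[:, 3:13]
        assert np.all((band > 0).sum(axis=1) <= 1)
        assert (band > 0).any()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle_on_random_fields(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(size=(16, 16))
        f = compute_gradient(gaussian_smooth(img, 1.0))
        assert np.array_equal(
            nonmax_suppress(f), nms_double_loop(f.magnitude, f.direction)
        )


class TestHysteresis:
    def test_all_below_low_empty(self):
        assert hysteresis_link(np.full((4, 4), 0.05), 0.1, 0.2).sum() == 0

    def test_all_above_high_full(self):
        assert hysteresis_link(np.full((4, 4), 0.5), 0.1, 0.2).sum() == 16

    def test_weak_chain_linked_until_gap(self):
        eps = 0.01
        t_l, t_h = 0.1, 0.3
        row = np.array([[t_h + eps, t_l + eps, t_l + eps, t_l - eps, t_h + eps]])
        out = hysteresis_link(row, t_l, t_h)
        assert out.tolist() == [[1, 1, 1, 0, 1]]
        assert np.array_equal(out, hysteresis_bfs(row, t_l, t_h))

    def test_isolated_weak_component_dropped(self):
        nms = np.zeros((7, 7))
        nms[1, 1:4] = 0.15  # weak only
        nms[5, 5] = 0.5  # strong elsewhere, not connected
        out = hysteresis_link(nms, 0.1, 0.3)
        assert out[1, 1:4].sum() == 0
        assert out[5, 5] == 1

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            hysteresis_link(np.ones((3, 3)), 0.4, 0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_oracle_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        nms = rng.uniform(size=(20, 20)) * (rng.uniform(size=(20, 20)) > 0.6)
        out = hysteresis_link(nms, 0.2, 0.6)
        assert np.array_equal(out, hysteresis_bfs(nms, 0.2, 0.6))

    def test_every_weak_edge_has_path_to_strong(self, default_phantom):
        params = CannyParams()
        smoothed = gaussian_smooth(default_phantom.image, params.sigma)
        nms = nonmax_suppress(compute_gradient(smoothed))
        t_l = params.low * nms.max()
        t_h = params.ratio * t_l
        out = hysteresis_link(nms, t_l, t_h)
        assert np.all(nms[out.astype(bool)] >= t_l)
        assert np.array_equal(out, hysteresis_bfs(nms, t_l, t_h))


class TestCannyDetect:
    def test_clean_two_region_edges_near_truth(self, two_region_image):
        ph = two_region_image
        edges = canny_detect(ph.image, CannyParams())
        assert edges.sum() > 0
        near_truth = ndimage.binary_dilation(
            ph.truth_edges.astype(bool), structure=np.ones((3, 3), bool)
        )
        assert np.all(near_truth[edges.astype(bool)])

    def test_threshold_above_max_magnitude_gives_empty_map(self, two_region_image):
        edges = canny_detect(
            two_region_image.image,
            CannyParams(sigma=1.0, low=10.0, ratio=2.0, relative=False),
        )
        assert edges.sum() == 0

    def test_flat_image_gives_empty_map(self):
        assert canny_detect(np.full((16, 16), 0.5), CannyParams()).sum() == 0

    def test_edge_count_monotone_non_increasing_in_ratio(self, default_phantom):
        img = default_phantom.image
        smoothed = gaussian_smooth(img, 1.4)
        nms = nonmax_suppress(compute_gradient(smoothed))
        t_l = 0.12 * nms.max()
        counts = [
            canny_detect(img, CannyParams(sigma=1.4, low=t_l, ratio=r, relative=False)).sum()
            for r in (0.3, 0.6, 0.9, 1.2, 1.5, 1.8)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_ratio_one_equals_single_threshold(self, default_phantom):
        img = default_phantom.image
        smoothed = gaussian_smooth(img, 1.4)
        nms = nonmax_suppress(compute_gradient(smoothed))
        t_l = 0.12 * nms.max()
        collapsed = canny_detect(img, CannyParams(sigma=1.4, low=t_l, ratio=1.0, relative=False))
        assert np.array_equal(collapsed, (nms >= t_l).astype(np.uint8))

    def test_estimator_wrapper_matches_function(self, default_phantom):
        det = CannyEdgeDetector().fit()
        assert np.array_equal(det.transform(default_phantom.image),
                              canny_detect(default_phantom.image, CannyParams()))

    def test_agrees_with_scikit_image_reference(self):
        """Sanity cross-check against an independent detector, not
        bit-exactness: NMS conventions differ (quantized vs interpolated),
        and the reference's Sobel gradient scale is 8x that of central
        differences, so its thresholds are scaled accordingly."""
        skimage_feature = pytest.importorskip("skimage.feature")
        from wristseg import default_wrist_spec, generate_phantom

        sigma, t_l = 1.0, 0.02
        agreements = []
        for seed in range(20):
            ph = generate_phantom(
                default_wrist_spec(seed=seed, size=32, noise_sigma=0.02,
                                   bias_amplitude=0.05)
            )
            ours = canny_detect(
                ph.image, CannyParams(sigma=sigma, low=t_l, ratio=2.0, relative=False)
            )
            ref = skimage_feature.canny(
                ph.image, sigma=sigma,
                low_threshold=8 * t_l, high_threshold=16 * t_l,
            )
            agreements.append(np.mean(ours.astype(bool) == ref))
        assert min(agreements) >= 0.95
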