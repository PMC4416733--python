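"""Standard, scale-adaptive and orientation-adaptive LBP extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soalbp import (
    ScaleEstimate,
    TrainedBaseScales,
    adaptive_threshold,
    extract_sa_lbp,
    extract_soa_lbp,
    filter_image,
    lbp_codes,
    sampling_kernel,
    standard_lbp,
)
from soalbp.lbp import _histogram

ERFINV_99 = 1.8213863677184496  # numeric oracle for erfinv(0.99)


@pytest.fixture(scope="module")
def noise_image():
    return np.random.default_rng(7).uniform(0, 255, (64, 64))


@pytest.fixture(scope="module")
def base_A():
    return TrainedBaseScales({"A": 4.0})


def valid_estimate(s: float) -> ScaleEstimate:
    return ScaleEstimate(s_tilde=20.0, s=s, u=1.0, valid=True)


class TestStandardLBP:
    def test_constant_image_zero_threshold_all_ones_pattern(self):
        h = standard_lbp(np.full((16, 16), 9.0), radius=1.0, n=8)
        assert h.bins[255] == 1.0 and h.bins.sum() == pytest.approx(1.0)

    def test_constant_image_positive_threshold_all_zero_pattern(self):
        h = standard_lbp(np.full((16, 16), 9.0), radius=1.0, n=8, threshold=0.5)
        assert h.bins[0] == 1.0

    def test_bright_center_pixel_yields_pattern_zero(self):
        toy = np.zeros((5, 5))
        toy[2, 2] = 10.0
        codes = lbp_codes(toy, radius=1.0, n=8)
        assert codes.shape == (1, 1) and codes[0, 0] == 0

    def test_matches_reference_implementation(self, noise_image):
        # independent oracle: scikit-image's default LBP uses the same
        # neighbor geometry and sign convention
        from skimage.feature import local_binary_pattern

        for radius in (1.0, 2.0, 3.0):
            margin = int(np.ceil(radius)) + 1
            mine = lbp_codes(noise_image, radius, 8)
            ref = local_binary_pattern(noise_image, 8, radius, method="default")
            ref = ref.astype(int)[margin:-margin, margin:-margin]
            assert np.array_equal(mine, ref)

    def test_radius_below_one_rejected(self, noise_image):
        with pytest.raises(ValueError):
            standard_lbp(noise_image, radius=0.5)

    def test_image_too_small_for_radius(self):
        with pytest.raises(ValueError, match="too small"):
            lbp_codes(np.zeros((6, 6)), radius=3.0, n=8)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        radius=st.floats(1.0, 5.0),
        n=st.sampled_from([4, 8]),
        seed=st.integers(0, 1000),
    )
    def test_histogram_is_distribution(self, radius, n, seed):
        img = np.random.default_rng(seed).uniform(0, 255, (32, 32))
        h = standard_lbp(img, radius, n)
        assert len(h.bins) == 2**n
        assert h.bins.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(h.bins >= 0)


class TestSamplingKernel:
    def test_reference_values_for_radius_3(self):
        k = sampling_kernel(3.0, n=8, P=0.99)
        assert k.gr == pytest.approx(3 * np.pi / 8, rel=1e-12)
        assert k.sigma_g == pytest.approx(k.gr / (np.sqrt(2) * ERFINV_99), rel=1e-12)
        assert k.sigma_g == pytest.approx(0.4574, abs=1e-4)

    @pytest.mark.parametrize("lam", [0.5, 1.5, 3.0, 8.0, 20.0])
    def test_weights_symmetric_and_normalized(self, lam):
        k = sampling_kernel(lam)
        assert np.allclose(k.weights, k.weights[::-1])
        assert np.all(k.weights > 0)
        assert k.weights.sum() == pytest.approx(1.0, rel=1e-12)
        assert len(k.weights) == 2 * int(np.ceil(k.gr)) + 1

    def test_large_radius_weights_match_truncated_gaussian_std(self):
        # closed-form oracle: the kernel is a Gaussian truncated at +-gr,
        # i.e. at a = sqrt(2)*erfinv(P) standard deviations, whose std is
        # sigma_g * sqrt(1 - 2*a*phi(a)/P); the discrete second moment must
        # approach it for wide kernels
        k = sampling_kernel(60.0)
        a = np.sqrt(2) * ERFINV_99
        phi = np.exp(-(a**2) / 2) / np.sqrt(2 * np.pi)
        sd_truncated = k.sigma_g * np.sqrt(1.0 - 2.0 * a * phi / 0.99)
        x = np.arange(len(k.weights)) - (len(k.weights) - 1) / 2
        sd = np.sqrt(np.sum(k.weights * x**2))
        assert sd == pytest.approx(sd_truncated, rel=0.02)

    def test_radius_scaling_is_exact(self):
        # doubling the adapted radius doubles gr (and sigma_g) exactly
        k1, k2 = sampling_kernel(2.5), sampling_kernel(5.0)
        assert k2.gr == pytest.approx(2 * k1.gr, rel=1e-12)
        assert k2.sigma_g == pytest.approx(2 * k1.sigma_g, rel=1e-12)


class TestAdaptiveThreshold:
    def test_constant_image_gives_zero(self):
        assert adaptive_threshold(np.full((8, 8), 12.0)) == 0.0

    def test_two_valued_image(self):
        img = np.concatenate([np.zeros(32), np.full(32, 16.0)]).reshape(8, 8)
        assert adaptive_threshold(img) == pytest.approx(np.sqrt(8.0), rel=1e-12)

    def test_intensity_scaling_by_a_squared_scales_T_by_a(self, noise_image):
        t1 = adaptive_threshold(noise_image)
        t2 = adaptive_threshold(9.0 * noise_image)
        assert t2 == pytest.approx(3.0 * t1, rel=1e-12)


class TestAdaptiveExtraction:
    def test_sa_at_base_scale_uses_base_radius(self, noise_image, base_A):
        h = extract_sa_lbp(noise_image, "A", valid_estimate(4.0), 3.0, base_A)
        assert h.adapted_radius == pytest.approx(3.0)
        assert h.class_ref == "A" and h.base_radius == 3.0

    def test_identical_base_scales_give_identical_histograms(self, noise_image):
        base = TrainedBaseScales({"A": 4.0, "B": 4.0})
        s = valid_estimate(5.0)
        hA = extract_sa_lbp(noise_image, "A", s, 3.0, base)
        hB = extract_sa_lbp(noise_image, "B", s, 3.0, base)
        assert np.array_equal(hA.bins, hB.bins)

    def test_sa_reduces_to_standard_lbp_on_filtered_image(self, noise_image, base_A):
        # at s = s_bar the adapted radius equals rho; extraction equals the
        # standard LBP of the kernel-filtered image, bin for bin
        rho = 3.0
        h_sa = extract_sa_lbp(noise_image, "A", valid_estimate(4.0), rho, base_A)
        filtered = filter_image(noise_image, sampling_kernel(rho))
        h_std = standard_lbp(filtered, rho)
        assert np.array_equal(h_sa.bins, h_std.bins)

    def test_soa_single_orientation_reduces_to_sa(self, noise_image, base_A):
        s = valid_estimate(4.0)
        h_sa = extract_sa_lbp(noise_image, "A", s, 3.0, base_A)
        h_soa = extract_soa_lbp(
            noise_image, "A", s, 0.0, 3.0, base_A,
            delta_o_deg=0.0, threshold=0.0, dual_orientation=False,
        )
        assert np.array_equal(h_soa.bins, h_sa.bins)

    def test_soa_dual_orientation_accumulates_offsets_0_and_pi(self, noise_image, base_A):
        s = valid_estimate(4.0)
        h_soa = extract_soa_lbp(
            noise_image, "A", s, 0.0, 3.0, base_A,
            delta_o_deg=0.0, threshold=0.0, dual_orientation=True,
        )
        filtered = filter_image(noise_image, sampling_kernel(3.0))
        c0 = _histogram(lbp_codes(filtered, 3.0, 8, 0.0, 0.0), 8)
        c1 = _histogram(lbp_codes(filtered, 3.0, 8, 0.0, np.pi), 8)
        ref = (c0 + c1) / (c0 + c1).sum()
        assert np.allclose(h_soa.bins, ref, atol=1e-15)

    def test_constant_image_histogram_independent_of_orientation(self, base_A):
        img = np.full((32, 32), 50.0)
        s = valid_estimate(4.0)
        hists = [
            extract_soa_lbp(img, "A", s, o, 3.0, base_A, threshold=0.0)
            for o in (0.0, 0.7, 2.1)
        ]
        assert np.array_equal(hists[0].bins, hists[1].bins)
        assert np.array_equal(hists[0].bins, hists[2].bins)

    def test_invalid_scale_estimate_rejected(self, noise_image, base_A):
        with pytest.raises(ValueError, match="invalid"):
            extract_sa_lbp(noise_image, "A", ScaleEstimate.invalid(), 3.0, base_A)

    def test_doubling_scale_doubles_adapted_radius(self, noise_image, base_A):
        h1 = extract_sa_lbp(noise_image, "A", valid_estimate(4.0), 1.5, base_A)
        h2 = extract_sa_lbp(noise_image, "A", valid_estimate(8.0), 1.5, base_A)
        assert h2.adapted_radius == pytest.approx(2 * h1.adapted_radius, rel=1e-12)

    def test_soa_histogram_is_distribution(self, noise_image, base_A):
        h = extract_soa_lbp(noise_image, "A", valid_estimate(5.0), 1.2, 3.0, base_A)
        assert h.bins.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(h.bins) == 256
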