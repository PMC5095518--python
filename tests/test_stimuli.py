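"""Stimulus pipeline: DoG filtering, patch extraction, ON/OFF splitting."""

import numpy as np
import pytest
from scipy import signal, stats

from v1net import stimuli
from v1net.stimuli import (PatchStream, dog_filter, dog_kernel, extract_patch,
                           generate_synthetic_image, normalize_patch,
                           rates_from_stimulus, shuffle_pixels, split_on_off)


class TestDogFilter:
    def test_uniform_field_gives_zero_response(self):
        out = dog_filter(np.full((32, 32), 7.3))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_impulse_response_is_center_surround(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = dog_filter(img, 1.0, 2.0)
        k = dog_kernel(1.0, 2.0)
        r = k.shape[0] // 2
        assert np.allclose(out[20 - r:20 + r + 1, 20 - r:20 + r + 1], k)
        assert out[20, 20] > 0            # excitatory centre
        assert out[20, 20 + 3] < 0        # inhibitory surround

    def test_linearity_matches_direct_convolution(self, rng):
        i1 = rng.standard_normal((32, 32))
        i2 = rng.standard_normal((32, 32))
        a, b = 1.7, -0.4
        lhs = dog_filter(a * i1 + b * i2)
        rhs = a * dog_filter(i1) + b * dog_filter(i2)
        assert np.allclose(lhs, rhs, atol=1e-10)
        # interior agrees with an independent direct convolution
        k = dog_kernel(1.0, 2.0)
        direct = signal.convolve2d(i1, k, mode="same")
        r = k.shape[0] // 2
        assert np.allclose(dog_filter(i1)[r:-r, r:-r], direct[r:-r, r:-r],
                           atol=1e-10)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            dog_filter(np.zeros(10))
        with pytest.raises(ValueError):
            dog_filter(np.zeros((5, 5)), sigma_center=2.0, sigma_surround=1.0)


class TestExtractPatch:
    def test_17x17_identity_crop(self, rng):
        img = rng.standard_normal((17, 17))
        assert np.array_equal(extract_patch(img, rng), img)

    def test_too_small_image_errors_with_minimum(self, rng):
        with pytest.raises(ValueError, match="27"):
            extract_patch(np.zeros((20, 20)), rng)

    def test_rotation_180_of_symmetric_pattern(self, rng):
        y, x = np.mgrid[:64, :64]
        img = np.cos(0.3 * np.hypot(y - 31.5, x - 31.5))  # radially symmetric
        r = np.random.default_rng(0)
        p0 = extract_patch(img, np.random.default_rng(5), angle_deg=0.0)
        # same location via identical rng state, rotated 180 degrees
        p180 = extract_patch(img, np.random.default_rng(5), angle_deg=180.0)
        centre = np.hypot(*np.mgrid[:17, :17] - np.array([[[8]], [[8]]]))
        inner = centre < 7  # away from interpolation borders
        assert np.allclose(p0[inner], p180[::-1, ::-1][inner], atol=1e-6)

    def test_locations_uniform(self, rng):
        """Chi-square on a coarse grid of patch centres is not rejected."""
        img = np.arange(80 * 80, dtype=float).reshape(80, 80)
        r = np.random.default_rng(77)
        centres = []
        for _ in range(10_000):
            p = extract_patch(img, r, angle_deg=0.0)
            centres.append(p[8, 8])  # centre pixel encodes (row, col)
        centres = np.asarray(centres)
        rows = (centres // 80 - 13) // 18  # valid rows 13..66 -> 3 even bins
        cols = (centres % 80 - 13) // 18
        counts = np.bincount((rows * 3 + cols).astype(int), minlength=9)
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=8)


class TestNormalize:
    def test_hand_computed_toy(self):
        out = normalize_patch(np.array([[2.0, 4.0], [6.0, 8.0]]))
        assert np.allclose(out, [[-1.0, -1.0 / 3.0], [1.0 / 3.0, 1.0]])

    def test_constant_patch_maps_to_zero(self):
        assert np.array_equal(normalize_patch(np.full((17, 17), 3.0)),
                              np.zeros((17, 17)))

    @pytest.mark.parametrize("seed", range(5))
    def test_postconditions_and_idempotence(self, seed):
        p = np.random.default_rng(seed).standard_normal((17, 17))
        out = normalize_patch(p)
        assert abs(out.mean()) < 1e-9
        assert np.isclose(np.abs(out).max(), 1.0)
        assert np.allclose(normalize_patch(out), out, atol=1e-12)


class TestOnOffSplit:
    def test_all_positive_patch_has_zero_off_half(self):
        v = split_on_off(np.full((17, 17), 0.5))
        assert np.all(v[289:] == 0) and np.all(v[:289] == 0.5)

    def test_single_negative_pixel(self):
        p = np.zeros((17, 17))
        p[3, 4] = -0.5
        v = split_on_off(p)
        assert np.all(v[:289] == 0)
        off = v[289:].reshape(17, 17)
        assert off[3, 4] == 0.5 and off.sum() == 0.5

    def test_reconstruction_is_lossless(self, rng):
        for _ in range(100):
            p = np.clip(rng.standard_normal((17, 17)), -1, 1)
            v = split_on_off(p)
            assert np.all(v >= 0)
            assert np.allclose(v[:289] - v[289:], p.ravel())


class TestShuffle:
    def test_preserves_value_multiset(self, rng):
        p = rng.standard_normal((17, 17))
        out = shuffle_pixels(p, rng)
        assert np.array_equal(np.sort(out.ravel()), np.sort(p.ravel()))

    def test_constant_patch_unchanged(self, rng):
        p = np.full((17, 17), 2.5)
        assert np.array_equal(shuffle_pixels(p, rng), p)

    def test_marked_pixel_visits_positions_uniformly(self):
        r = np.random.default_rng(3)
        p = np.zeros((17, 17))
        p[0, 0] = 1.0
        counts = np.zeros(289)
        n = 6000
        for _ in range(n):
            counts += shuffle_pixels(p, r).ravel()
        chi2 = ((counts - n / 289) ** 2 / (n / 289)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=288)


class TestSyntheticImages:
    @staticmethod
    def _spectral_slope(img):
        f = np.abs(np.fft.fft2(img))
        fy = np.fft.fftfreq(img.shape[0])[:, None]
        fx = np.fft.fftfreq(img.shape[1])[None, :]
        r = np.hypot(fy, fx).ravel()
        a = f.ravel()
        sel = (r > 0.02) & (r < 0.4)
        bins = np.logspace(np.log10(0.02), np.log10(0.4), 16)
        idx = np.digitize(r[sel], bins)
        xs, ys = [], []
        for b in range(1, 16):
            m = idx == b
            if m.sum() > 4:
                xs.append(np.log(np.mean(r[sel][m])))
                ys.append(np.log(np.mean(a[sel][m])))
        return np.polyfit(xs, ys, 1)[0]

    @pytest.mark.parametrize("exponent", [0.0, 1.0])
    def test_spectral_slope_matches_request(self, exponent):
        img = generate_synthetic_image(256, exponent,
                                       np.random.default_rng(11))
        assert abs(self._spectral_slope(img) + exponent) < 0.15

    def test_determinism_and_seed_sensitivity(self):
        a = generate_synthetic_image(64, 1.0, np.random.default_rng(5))
        b = generate_synthetic_image(64, 1.0, np.random.default_rng(5))
        c = generate_synthetic_image(64, 1.0, np.random.default_rng(6))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            generate_synthetic_image(32)


class TestRates:
    def test_zero_and_linear(self):
        assert np.all(rates_from_stimulus(np.zeros(578), 300.0) == 0)
        v = np.zeros(578)
        v[17] = 1.0
        assert rates_from_stimulus(v, 250.0)[17] == 250.0

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            rates_from_stimulus(np.zeros(578), -1.0)

    def test_poisson_counts_recover_rates(self):
        """Poisson trains sampled at these rates recover them within 3 s.e."""
        r = np.random.default_rng(2)
        rates = rates_from_stimulus(np.array([0.1, 0.5, 1.0]), 100.0)
        T = 100.0  # seconds
        counts = r.poisson(rates * T)
        for c, lam in zip(counts, rates):
            assert abs(c / T - lam) <= 3.0 * np.sqrt(lam / T)


class TestPatchStream:
    def test_stream_patches_are_normalized_and_deterministic(self):
        s1 = PatchStream(np.random.default_rng(9), image_size=64,
                         patches_per_image=5)
        s2 = PatchStream(np.random.default_rng(9), image_size=64,
                         patches_per_image=5)
        a = s1.batch_on_off(7)
        b = s2.batch_on_off(7)
        assert np.array_equal(a, b)
        assert a.shape == (7, 578) and np.all(a >= 0)

    def test_shuffled_stream_preserves_values(self):
        base = PatchStream(np.random.default_rng(4), image_size=64)
        p = base.next_patch()
        assert abs(p.mean()) < 1e-9 and np.abs(p).max() <= 1.0
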