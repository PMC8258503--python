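"""Fourier engine: DFT conventions, band masks, windowing, reconstruction."""

import numpy as np
import pytest

from simquant import (
    BandSpec,
    FOOT_PROCESS_BAND,
    GrayImage,
    band_mask,
    circular_window,
    fit_plane_wave,
    forward_spectrum,
    make_plane_wave,
    power_spectrum,
    reconstruct_from_band,
)
from simquant.phantoms import PlaneWaveSpec

from conftest import naive_dft2, pearson


class TestForwardSpectrum:
    def test_constant_image_is_dc_only(self):
        img = GrayImage(np.full((128, 128), 3.5))
        spec = forward_spectrum(img)
        assert spec.coeffs[64, 64] == pytest.approx(3.5 * 128**2)
        off_dc = spec.coeffs.copy()
        off_dc[64, 64] = 0
        assert np.abs(off_dc).max() < 1e-8 * abs(spec.coeffs[64, 64])

    def test_diagonal_wave_peaks_at_conjugate_pair(self, wave_04):
        spec = forward_spectrum(wave_04)
        mags = np.abs(spec.coeffs)
        mags[64, 64] = 0
        flat = np.argsort(mags.ravel())[::-1][:2]
        peaks = {tuple(np.unravel_index(i, mags.shape)) for i in flat}
        # centered indices (u, v) = (8, 8) and (-8, -8): round(0.4*128/2pi) = 8
        assert peaks == {(64 + 8, 64 + 8), (64 - 8, 64 - 8)}

    def test_shallow_wave_peak_inside_inner_square(self, wave_005):
        mags = np.abs(forward_spectrum(wave_005).coeffs)
        mags[64, 64] = 0
        i, j = np.unravel_index(np.argmax(mags), mags.shape)
        assert max(abs(i - 64), abs(j - 64)) == 1

    @pytest.mark.parametrize("n", [16, 64, 256])
    def test_parseval(self, rng, n):
        pixels = rng.standard_normal((n, n))
        spec = forward_spectrum(GrayImage(pixels + 10))
        lhs = np.sum((pixels + 10) ** 2)
        rhs = np.sum(np.abs(spec.coeffs) ** 2) / n**2
        assert abs(lhs - rhs) < 1e-10 * lhs

    def test_matches_naive_dft_oracle(self, rng):
        pixels = rng.standard_normal((16, 16))
        spec = forward_spectrum(GrayImage(pixels + 5))
        oracle = naive_dft2(pixels + 5)
        assert np.abs(spec.coeffs - oracle).max() < 1e-8 * np.abs(oracle).max()

    @pytest.mark.parametrize("shape", [(127, 127), (128, 64), (64, 128)])
    def test_rejects_non_square_or_odd(self, rng, shape):
        img = GrayImage(np.abs(rng.standard_normal(shape)))
        with pytest.raises(ValueError, match="square"):
            forward_spectrum(img)

    def test_round_trip(self, rng):
        pixels = np.abs(rng.standard_normal((64, 64))) + 1
        spec = forward_spectrum(GrayImage(pixels))
        back = np.fft.ifft2(np.fft.ifftshift(spec.coeffs)).real
        assert np.abs(back - pixels).max() < 1e-8 * np.abs(pixels).max()


class TestPowerSpectrum:
    def test_point_symmetry_off_nyquist(self, rng):
        mags = power_spectrum(forward_spectrum(GrayImage(rng.standard_normal((32, 32)) + 4))).magnitudes
        sub = mags[1:, 1:]
        assert np.allclose(sub, sub[::-1, ::-1], rtol=1e-10)

    def test_magnitudes_nonnegative_and_match_coeffs(self, wave_04):
        spec = forward_spectrum(wave_04)
        ps = power_spectrum(spec)
        assert np.all(ps.magnitudes >= 0)
        assert np.array_equal(ps.magnitudes, np.abs(spec.coeffs))


class TestBandMask:
    def test_reference_band_bin_count(self):
        # lattice-count oracle: 31^2 - 7^2 = 912 bins for 4 <= max|u|,|v| <= 15
        mask = band_mask(128, FOOT_PROCESS_BAND)
        u = np.arange(128) - 64
        cheb = np.maximum(np.abs(u)[:, None], np.abs(u)[None, :])
        oracle = (cheb >= 4) & (cheb <= 15)
        assert mask.sum() == 912
        assert np.array_equal(mask, oracle)

    def test_full_band_covers_all_non_dc_below_nyquist(self):
        mask = band_mask(128, BandSpec(1.0, 0.0))
        u = np.arange(128) - 64
        cheb = np.maximum(np.abs(u)[:, None], np.abs(u)[None, :])
        expected = cheb < 64
        expected[64, 64] = False
        assert np.array_equal(mask, expected)

    def test_nested_bands_partition(self):
        inner = band_mask(128, BandSpec(1 / 16, 0.0))
        annulus = band_mask(128, BandSpec(1 / 4, 1 / 16))
        union = band_mask(128, BandSpec(1 / 4, 0.0))
        assert not np.any(inner & annulus)
        assert np.array_equal(inner | annulus, union)

    def test_half_open_family_tiles_spectrum(self):
        fractions = [0.0, 1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0]
        total = np.zeros((64, 64), dtype=int)
        for lo, hi in zip(fractions, fractions[1:]):
            total += band_mask(64, BandSpec(hi, lo)).astype(int)
        full = band_mask(64, BandSpec(1.0, 0.0))
        assert np.array_equal(total.astype(bool), full)
        assert total.max() == 1  # no overlap

    def test_rejects_inverted_fractions(self):
        with pytest.raises(ValueError):
            BandSpec(1 / 16, 1 / 4)


class TestReconstruction:
    def test_full_band_with_dc_recovers_input(self, rng):
        pixels = np.abs(rng.standard_normal((64, 64))) + 1
        spec = forward_spectrum(GrayImage(pixels))
        # full band excludes the Nyquist row/column, so build the input
        # from frequencies below Nyquist only
        low = np.fft.ifft2(np.fft.ifftshift(np.where(band_mask(64, BandSpec(1.0, 0.0)), spec.coeffs, 0))).real
        low += pixels.mean()
        spec2 = forward_spectrum(GrayImage(low))
        rec = reconstruct_from_band(spec2, BandSpec(1.0, 0.0), keep_dc=True)
        assert np.abs(rec.pixels - low).max() < 1e-8 * np.abs(low).max()

    def test_steep_wave_lives_in_annulus(self, wave_04):
        spec = forward_spectrum(wave_04)
        rec = reconstruct_from_band(spec, FOOT_PROCESS_BAND)
        assert pearson(rec.pixels, wave_04.pixels) >= 0.9
        rec_c = reconstruct_from_band(spec, FOOT_PROCESS_BAND, complement=True)
        assert pearson(rec_c.pixels, wave_04.pixels) <= 0.2

    def test_shallow_wave_lives_in_complement(self, wave_005):
        spec = forward_spectrum(wave_005)
        rec = reconstruct_from_band(spec, FOOT_PROCESS_BAND)
        assert pearson(rec.pixels, wave_005.pixels) <= 0.2
        rec_c = reconstruct_from_band(spec, FOOT_PROCESS_BAND, complement=True)
        assert pearson(rec_c.pixels, wave_005.pixels) >= 0.9


class TestCircularWindow:
    def test_constant_image_unchanged(self):
        img = GrayImage(np.full((32, 32), 2.0))
        for fill in ("mean", "zero"):
            out = circular_window(img, fill)
            if fill == "mean":
                assert np.array_equal(out.pixels, img.pixels)

    def test_zero_fill_count_matches_lattice_oracle(self):
        n = 128
        img = GrayImage(np.ones((n, n)))
        out = circular_window(img, fill="zero")
        c = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n]
        inside = np.hypot(xx - c, yy - c) <= n / 2
        assert (out.pixels == 0).sum() == n * n - inside.sum()

    def test_suppresses_cross_noise_of_wraparound_step(self):
        # half-bright image: the periodic-wraparound step concentrates
        # magnitude on the frequency axes; mean-fill windowing reduces it
        z = np.zeros((128, 128))
        z[:, :64] = 1.0
        img = GrayImage(z)

        def axis_magnitude(im):
            m = np.abs(forward_spectrum(im).coeffs)
            return m[64, :].sum() + m[:, 64].sum() - 3 * m[64, 64]

        assert axis_magnitude(circular_window(img)) < axis_magnitude(img)

    def test_unknown_fill_rejected(self):
        with pytest.raises(ValueError, match="fill"):
            circular_window(GrayImage(np.ones((16, 16))), fill="reflect")


class TestPlaneWaveFit:
    @pytest.mark.parametrize("omega", [0.4, 0.05])
    def test_recovers_printed_frequencies(self, omega):
        img = make_plane_wave(PlaneWaveSpec(omega_x=omega, omega_y=omega))
        fit = fit_plane_wave(img)
        assert fit.omega_x == pytest.approx(omega, abs=1e-6)
        assert fit.omega_y == pytest.approx(omega, abs=1e-6)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-6)
        assert fit.offset == pytest.approx(1.0, abs=1e-6)

    def test_recovers_asymmetric_frequencies_with_noise(self, rng):
        clean = make_plane_wave(PlaneWaveSpec(omega_x=0.3, omega_y=0.12, phase=0.7, amplitude=2.0))
        noisy = GrayImage(clean.pixels + 0.05 * rng.standard_normal((128, 128)))
        fit = fit_plane_wave(noisy)
        assert fit.omega_x == pytest.approx(0.3, abs=1e-3)
        assert fit.omega_y == pytest.approx(0.12, abs=1e-3)
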