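import numpy as np
import pytest
from scipy import stats
from scipy.signal import fftconvolve

from deepfoci.simulator import (
    CameraConfig,
    Phantom,
    build_spsf_stack,
    default_depth_grid,
    generate_background,
    generate_phantom,
    monte_carlo_spsf,
    render_image,
    widefield_psf,
)

PITCH = 2000.0 / 512  # µm/px of the scaled study images


def kernel_rms_radius(k):
    n = k.shape[0] // 2
    y, x = np.mgrid[-n : n + 1, -n : n + 1]
    return np.sqrt(((x**2 + y**2) * k).sum() / k.sum())


class TestPhantom:
    def test_empty_phantom(self):
        ph = generate_phantom(0, n_foci=0)
        assert len(ph) == 0

    def test_determinism(self):
        a = generate_phantom(42, n_foci=50)
        b = generate_phantom(42, n_foci=50)
        np.testing.assert_array_equal(a.centroids_um, b.centroids_um)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom(0, n_foci=-1)

    def test_fields_within_volume_and_scaling(self):
        ph = generate_phantom(7, n_foci=300, volume_mm=(2, 2, 0.5))
        assert ph.centroids_um.min() >= 0
        assert ph.centroids_um[:, 0].max() <= 2000
        assert ph.centroids_um[:, 2].max() <= 500
        assert ph.n_cells.min() >= 1 and ph.n_cells.max() <= 50
        # radius scales with cube root of cell count
        np.testing.assert_allclose(ph.radii_um, 7.0 * np.cbrt(ph.n_cells))
        # total fluorophore within the per-cell bounds
        assert np.all(ph.intensities >= 0.5 * ph.n_cells - 1e-9)
        assert np.all(ph.intensities <= 1.5 * ph.n_cells + 1e-9)

    def test_centroids_uniform_chi_square(self):
        ph = generate_phantom(3, n_foci=10_000, volume_mm=(10, 10, 0.5))
        edges = [
            np.linspace(0, 10_000, 9),
            np.linspace(0, 10_000, 9),
            np.linspace(0, 500, 5),
        ]
        hist, _ = np.histogramdd(ph.centroids_um, bins=edges)
        expected = 10_000 / hist.size
        chi2 = ((hist - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, hist.size - 1)
        assert p > 0.01


class TestBackground:
    def test_zero_contrast_is_constant(self):
        bg = generate_background(0, (64, 64), mean=200.0, contrast=0.0)
        np.testing.assert_allclose(bg, 200.0)

    def test_different_seeds_differ(self):
        a = generate_background(1, (64, 64))
        b = generate_background(2, (64, 64))
        assert not np.array_equal(a, b)

    def test_positive_and_mean_scaled(self):
        bg = generate_background(5, (256, 256), mean=500.0, contrast=0.3, pixel_pitch_um=PITCH)
        assert bg.min() > 0
        assert bg.mean() == pytest.approx(500.0, rel=0.05)

    def test_correlation_length_matches_configuration(self):
        """Radially averaged autocorrelation reaches 1/e near the configured lag."""
        target_um = 400.0
        pitch = 10.0
        estimates = []
        for seed in range(20):
            bg = generate_background(
                seed, (256, 256), mean=100.0, contrast=0.2,
                corr_length_um=target_um, pixel_pitch_um=pitch,
            )
            f = bg - bg.mean()
            acf = np.real(np.fft.ifft2(np.abs(np.fft.fft2(f)) ** 2))
            acf /= acf[0, 0]
            prof = acf[0, : 256 // 2]  # lag along one axis
            below = np.nonzero(prof < 1.0 / np.e)[0]
            estimates.append(below[0] * pitch if len(below) else np.nan)
        assert np.nanmean(estimates) == pytest.approx(target_um, rel=0.25)


class TestWidefieldPSF:
    def test_normalized_and_symmetric(self):
        k = widefield_psf(0.04, 520.0, PITCH)
        assert k.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(k, k.T)
        np.testing.assert_allclose(k, k[::-1, ::-1])
        assert k.shape[0] >= 3

    def test_second_moment_matches_sigma(self):
        na, lam, pitch = 0.1, 520.0, 1.0
        k = widefield_psf(na, lam, pitch)
        sigma_px = 0.21 * (lam / 1000.0) / na / pitch
        assert kernel_rms_radius(k) / np.sqrt(2) == pytest.approx(sigma_px, rel=0.05)

    def test_invalid_na_rejected(self):
        with pytest.raises(ValueError):
            widefield_psf(0.0)


class TestMonteCarloSPSF:
    def test_depth_zero_is_delta(self):
        k = monte_carlo_spsf(0.0, n_photons=2000, seed=0, kernel_half_px=10)
        assert k[10, 10] == pytest.approx(1.0)
        assert k.sum() == pytest.approx(1.0)

    def test_photon_conservation_without_absorption(self):
        """With zero absorption and full-exit binning over a wide window,
        nearly all photon weight reaches the surface (heavy-tailed
        first-passage leaves a few percent beyond any finite window)."""
        k = monte_carlo_spsf(
            100.0, mu_s_per_mm=20.0, g=0.0, mu_a_per_mm=0.0,
            n_photons=20_000, seed=3, pixel_pitch_um=500.0,
            kernel_half_px=40, max_events=20_000, acceptance_deg=None,
        )
        assert 0.95 <= k.sum() <= 1.0 + 1e-9

    def test_rms_radius_grows_with_depth(self):
        radii = []
        for seed in range(3):
            r = []
            for depth in (100.0, 400.0):
                k = monte_carlo_spsf(
                    depth, mu_s_per_mm=10.0, g=0.9, mu_a_per_mm=0.1,
                    n_photons=20_000, seed=seed, pixel_pitch_um=PITCH,
                    kernel_half_px=64,
                )
                r.append(kernel_rms_radius(k))
            radii.append(r)
        assert all(r400 > r100 for r100, r400 in radii)

    def test_peak_value_decays_with_depth(self):
        stack = build_spsf_stack(
            np.array([12.5, 237.5, 487.5]), n_photons=20_000, seed=1,
            pixel_pitch_um=PITCH, kernel_half_px=64,
        )
        peaks = [k.max() for k in stack.kernels]
        assert peaks[0] > peaks[1] > peaks[2]

    def test_kernels_nonnegative(self):
        k = monte_carlo_spsf(200.0, n_photons=2000, seed=0, kernel_half_px=32)
        assert np.all(k >= 0)

    def test_too_few_photons_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_spsf(100.0, n_photons=100)


def _single_focus_phantom(z_um, n_cells=20, volume=(1.0, 1.0, 0.5)):
    return Phantom(
        volume_mm=volume,
        centroids_um=np.array([[500.0, 500.0, z_um]]),
        n_cells=np.array([n_cells]),
        intensities=np.array([float(n_cells)]),
        radii_um=np.array([7.0 * n_cells ** (1 / 3)]),
    )


class TestRender:
    pitch = 1000.0 / 128  # 1 mm over 128 px

    def _quiet_camera(self):
        return CameraConfig(gain=1.0, read_noise_sd=0.0, shot_noise=False, quantize=False)

    def test_scatter_free_noise_free_reduces_to_convolution(self):
        ph = _single_focus_phantom(250.0)
        bg = generate_background(3, (128, 128), mean=50.0, contrast=0.2, pixel_pitch_um=self.pitch)
        psf = widefield_psf(0.04, 520.0, self.pitch)
        img, truth = render_image(
            ph, bg, psf, spsf_stack=None, camera=self._quiet_camera(),
            pixel_pitch_um=self.pitch, focus_brightness=100.0,
        )
        # rebuild the expected raster: projected spot + background, then PSF
        from deepfoci.simulator import _rasterize_plane

        spot = _rasterize_plane(
            (128, 128), np.array([500.0 / self.pitch]), np.array([500.0 / self.pitch]),
            ph.radii_um / (2 * self.pitch), ph.intensities * 100.0,
        )
        want = fftconvolve(spot + bg, psf, mode="same")
        np.testing.assert_allclose(img.pixels, np.maximum(want, 0), rtol=1e-6, atol=1e-9)

    def test_empty_phantom_is_background_only(self):
        ph = Phantom((1, 1, 0.5), np.empty((0, 3)), np.empty(0, int), np.empty(0), np.empty(0))
        bg = generate_background(1, (128, 128), mean=100.0, contrast=0.1, pixel_pitch_um=self.pitch)
        psf = widefield_psf(0.04, 520.0, self.pitch)
        img, truth = render_image(ph, bg, psf, None, self._quiet_camera(), self.pitch)
        assert len(truth) == 0
        want = fftconvolve(bg, psf, mode="same")
        np.testing.assert_allclose(img.pixels, want, rtol=1e-6)

    def test_shallow_peak_brighter_than_deep_peak(self):
        stack = build_spsf_stack(
            default_depth_grid(0.5, 50.0), n_photons=20_000, seed=2,
            pixel_pitch_um=self.pitch, kernel_half_px=32,
        )
        bg = np.full((128, 128), 10.0)
        psf = widefield_psf(0.04, 520.0, self.pitch)
        peaks = []
        for z in (30.0, 450.0):
            img, _ = render_image(
                _single_focus_phantom(z), bg, psf, stack, self._quiet_camera(),
                self.pitch, focus_brightness=100.0,
            )
            peaks.append(img.pixels.max())
        assert peaks[0] > peaks[1]

    def test_determinism(self):
        ph = _single_focus_phantom(100.0)
        bg = generate_background(1, (128, 128), mean=50.0, pixel_pitch_um=self.pitch)
        psf = widefield_psf(0.04, 520.0, self.pitch)
        cam = CameraConfig(gain=2.0, read_noise_sd=5.0)
        a, _ = render_image(ph, bg, psf, None, cam, self.pitch, noise_seed=9)
        b, _ = render_image(ph, bg, psf, None, cam, self.pitch, noise_seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_saturation_clipping(self):
        ph = _single_focus_phantom(10.0, n_cells=50)
        bg = np.full((128, 128), 100.0)
        psf = widefield_psf(0.04, 520.0, self.pitch)
        cam = CameraConfig(gain=None, target_peak_frac=2.0, read_noise_sd=0.0, shot_noise=False)
        img, _ = render_image(ph, bg, psf, None, cam, self.pitch, focus_brightness=100.0)
        assert img.pixels.max() == cam.saturation_value
        assert img.saturated_mask().any()

    def test_pitch_mismatch_rejected(self):
        stack = build_spsf_stack(np.array([25.0]), n_photons=2000, seed=0,
                                 pixel_pitch_um=4.0, kernel_half_px=8)
        bg = np.full((64, 64), 10.0)
        psf = widefield_psf(0.04, 520.0, 8.0)
        with pytest.raises(ValueError, match="pitch"):
            render_image(_single_focus_phantom(100.0), bg, psf, stack, None, 8.0)

    def test_energy_bookkeeping_scatter_free(self):
        """Without scattering, absorption or clipping, flux above background
        equals the emitted flux (PSF preserves total mass)."""
        ph = _single_focus_phantom(100.0, n_cells=10)
        bg = np.full((128, 128), 20.0)
        psf = widefield_psf(0.04, 520.0, self.pitch)
        img, truth = render_image(
            ph, bg, psf, None, self._quiet_camera(), self.pitch, focus_brightness=50.0
        )
        extra = img.pixels.sum() - fftconvolve(bg, psf, mode="same").sum()
        assert extra == pytest.approx(truth.intensity.sum(), rel=1e-3)


class TestDepthPhenomenology:
    def test_peak_snr_stratified_by_depth(self):
        """The rendered regime shows the characteristic depth structure:
        near-surface foci saturate, mid foci show clear unsaturated peaks,
        deep foci sink toward the noise margin."""
        from deepfoci.experiment import ExperimentConfig, reference_gain

        cfg = ExperimentConfig()
        stack = build_spsf_stack(
            default_depth_grid(0.5, 25.0), n_photons=10_000, seed=4,
            pixel_pitch_um=cfg.pixel_pitch_um, kernel_half_px=64,
        )
        psf = widefield_psf(cfg.na, cfg.wavelength_nm, cfg.pixel_pitch_um)
        bg = generate_background(
            11, (512, 512), cfg.background_mean, cfg.background_contrast,
            cfg.background_corr_um, cfg.pixel_pitch_um,
        )
        cam = CameraConfig(gain=reference_gain(cfg), read_noise_sd=cfg.read_noise_sd)
        snrs = {}
        base, _ = render_image(
            Phantom((2, 2, 0.5), np.empty((0, 3)), np.empty(0, int), np.empty(0), np.empty(0)),
            bg, psf, stack, cam, cfg.pixel_pitch_um, noise_seed=1,
        )
        noise_sd = np.std(base.pixels[100:200, 100:200] - np.median(base.pixels[100:200, 100:200]))
        for name, z in [("shallow", 20.0), ("mid", 200.0), ("deep", 460.0)]:
            ph = Phantom(
                (2, 2, 0.5), np.array([[1000.0, 1000.0, z]]), np.array([30]),
                np.array([30.0]), np.array([7.0 * 30 ** (1 / 3)]),
            )
            img, _ = render_image(
                ph, bg, psf, stack, cam, cfg.pixel_pitch_um, noise_seed=1,
                focus_brightness=cfg.focus_brightness,
            )
            peak = img.pixels[236:276, 236:276].max()
            local_bg = np.median(base.pixels[236:276, 236:276])
            snrs[name] = (peak - local_bg) / noise_sd
            if name == "shallow":
                assert img.saturated_mask().any()  # sensor clips at the surface
        assert snrs["shallow"] > snrs["mid"] > snrs["deep"]
        assert snrs["mid"] > 4  # clear unsaturated peak
        assert snrs["deep"] < 4  # near the noise margin
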