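"""Gradient-to-phase integration: Hilbert, cumulative and Wiener routes."""

import numpy as np
import pytest

from grom import (
    BiasSchedule,
    GradientPhaseImage,
    ImageGrid,
    PhaseImage,
    acquire_bias_series,
    background_correct,
    demodulate_nstep,
    integrate_cumulative,
    integrate_hilbert,
    make_random_phantom,
    make_sphere_phantom,
    phase_to_index_difference,
    reconstruct_volume,
    wiener_deconvolve,
    SphereSpec,
)

LAM = 0.65
PX = 0.1
SHEAR = 0.2


def grad_image(grid, values, nsteps=16):
    return GradientPhaseImage(grid=grid, grad_phase=values,
                              shear_axis=(1.0, 0.0), nsteps=nsteps)


def sheared_difference(phase, px, s):
    """Forward-shear oracle via Fourier shift (periodic)."""
    f = np.fft.fft(phase, axis=1)
    k = 2 * np.pi * np.fft.fftfreq(phase.shape[1], px)
    return np.fft.ifft(f * 2j * np.sin(k * s / 2), axis=1).real


class TestHilbert:
    def test_sinusoid_recovered_within_one_percent(self):
        # Phi = A sin(kx); its sheared difference is 2A sin(ks/2) cos(kx)
        grid = ImageGrid(16, 256, PX)
        A, cycles = 0.7, 6
        k = 2 * np.pi * cycles / (grid.nx * PX)
        assert k * SHEAR < 0.5
        x = grid.x_coords()
        truth = A * np.sin(k * x)[None, :] * np.ones((grid.ny, 1))
        g = 2 * A * np.sin(k * SHEAR / 2) * np.cos(k * x)[None, :] \
            * np.ones((grid.ny, 1))
        rec = integrate_hilbert(grad_image(grid, g), SHEAR,
                                extension="periodic")
        err = np.abs(rec.phase - truth).max()
        assert err < 0.01 * A

    def test_zero_gradient_zero_phase(self):
        grid = ImageGrid(16, 32, PX)
        rec = integrate_hilbert(grad_image(grid, np.zeros(grid.shape)), SHEAR)
        np.testing.assert_allclose(rec.phase, 0.0, atol=1e-14)

    def test_differentiate_then_integrate_round_trip(self):
        # smooth compact-support field: forward shear then inversion with
        # the default boundary model, < 2% RMS
        grid = ImageGrid(64, 64, PX)
        ph = make_random_phantom(grid, 0.8, 0.6, seed=4)
        from scipy.signal.windows import tukey
        window = np.outer(tukey(64, 0.5), tukey(64, 0.5))
        field = ph.phase * window
        g = sheared_difference(field, PX, SHEAR)
        rec = integrate_hilbert(grad_image(grid, g), SHEAR)
        # the per-row integration constant is a gauge freedom: compare in
        # the row-mean-free gauge both sides
        truth = field - field.mean(axis=1, keepdims=True)
        est = rec.phase - rec.phase.mean(axis=1, keepdims=True)
        rms_err = np.sqrt(np.mean((est - truth) ** 2))
        rms_sig = np.sqrt(np.mean(truth**2))
        assert rms_err < 0.02 * rms_sig

    def test_linearity_for_disjoint_beads(self, nyquist_optics):
        grid = ImageGrid(64, 64, nyquist_optics.pixel_size)
        h, w = grid.extent
        s1 = SphereSpec((w / 4, h / 2), 0.8, 1.588, 1.518)
        s2 = SphereSpec((3 * w / 4, h / 2), 0.8, 1.588, 1.518)

        def reconstruct(spheres):
            ph = make_sphere_phantom(grid, spheres, LAM)
            stack = acquire_bias_series(ph, nyquist_optics,
                                        BiasSchedule.uniform(16), blur=False)
            grad = demodulate_nstep(stack)
            return integrate_hilbert(grad, nyquist_optics.shear_distance).phase

        both = reconstruct([s1, s2])
        summed = reconstruct([s1]) + reconstruct([s2])
        np.testing.assert_allclose(both, summed, atol=1e-6)

    def test_dc_offset_invisible(self, nyquist_optics):
        # adding a constant to the specimen leaves the reconstruction
        # unchanged: the constant lives in c, fixed to zero
        grid = ImageGrid(32, 32, nyquist_optics.pixel_size)
        ph = make_random_phantom(grid, 0.5, 0.7, seed=8)
        for offset in (0.0, 1.3):
            shifted = ph.phase + offset
            from grom.phantom import PhasePhantom
            p = PhasePhantom(grid=grid, phase=shifted, wavelength=LAM)
            stack = acquire_bias_series(p, nyquist_optics,
                                        BiasSchedule.uniform(8), blur=False)
            rec = integrate_hilbert(demodulate_nstep(stack),
                                    nyquist_optics.shear_distance)
            if offset == 0.0:
                base = rec.phase
            else:
                np.testing.assert_allclose(rec.phase, base, atol=1e-9)


class TestCumulative:
    def test_constant_gradient_integrates_to_ramp(self):
        grid = ImageGrid(8, 64, PX)
        g0 = 0.05
        rec = integrate_cumulative(grad_image(grid, np.full(grid.shape, g0)),
                                   SHEAR)
        expected = g0 / SHEAR * PX * np.arange(1, 65)
        np.testing.assert_allclose(rec.phase[0], expected, rtol=1e-12)

    def test_zero_in_zero_out(self):
        grid = ImageGrid(8, 16, PX)
        rec = integrate_cumulative(grad_image(grid, np.zeros(grid.shape)), SHEAR)
        assert np.all(rec.phase == 0)

    def test_noise_random_walks_along_rows(self):
        # var of the running sum of iid noise grows linearly with x
        grid = ImageGrid(512, 128, PX)
        rng = np.random.default_rng(12)
        sigma = 0.1
        rec = integrate_cumulative(
            grad_image(grid, rng.normal(0, sigma, grid.shape)), SHEAR)
        var = rec.phase.var(axis=0)
        expected = sigma**2 * (PX / SHEAR) ** 2 * np.arange(1, 129)
        ratio = var[16:] / expected[16:]
        assert 0.7 < ratio.mean() < 1.3


class TestWiener:
    def test_matches_hilbert_at_high_snr(self):
        grid = ImageGrid(64, 64, PX)
        ph = make_random_phantom(grid, 0.8, 0.6, seed=4)
        g = grad_image(grid, sheared_difference(ph.phase, PX, SHEAR))
        hw = wiener_deconvolve(g, SHEAR, snr_parameter=1e8).phase
        hh = integrate_hilbert(g, SHEAR).phase
        rms = np.sqrt(np.mean((hw - hh) ** 2))
        assert rms < 0.02 * np.sqrt(np.mean(hh**2))

    def test_zero_in_zero_out(self):
        grid = ImageGrid(8, 16, PX)
        rec = wiener_deconvolve(grad_image(grid, np.zeros(grid.shape)), SHEAR)
        assert np.all(rec.phase == 0)

    def test_invalid_snr_rejected(self):
        grid = ImageGrid(8, 16, PX)
        with pytest.raises(ValueError):
            wiener_deconvolve(grad_image(grid, np.zeros(grid.shape)), SHEAR,
                              snr_parameter=0.0)

    def test_noisier_than_hilbert_on_noisy_bead(self, nyquist_optics):
        # the qualitative ranking: under shot noise the Wiener baseline has
        # the larger error against ground truth over the specimen support
        grid = ImageGrid(64, 64, nyquist_optics.pixel_size)
        h, w = grid.extent
        ph = make_sphere_phantom(
            grid, [SphereSpec((w / 2, h / 2), 1.0, 1.588, 1.518)], LAM)
        stack = acquire_bias_series(ph, nyquist_optics,
                                    BiasSchedule.uniform(16), blur=False,
                                    photons_per_unit=100, seed=21)
        grad = demodulate_nstep(stack)
        s = nyquist_optics.shear_distance
        support = ph.phase > 0
        err_h = np.sqrt(np.mean(
            (integrate_hilbert(grad, s).phase[support] - ph.phase[support]) ** 2))
        err_w = np.sqrt(np.mean(
            (wiener_deconvolve(grad, s).phase[support] - ph.phase[support]) ** 2))
        assert err_w > err_h


class TestBackgroundCorrection:
    def test_constant_offset_removed(self):
        grid = ImageGrid(64, 64, PX)
        img = PhaseImage(grid=grid, phase=np.full(grid.shape, 0.4))
        out = background_correct(img, radius=1.0)
        np.testing.assert_allclose(out.phase, 0.0, atol=1e-9)

    def test_bead_on_ramp_keeps_peak_height(self, nyquist_optics):
        grid = ImageGrid(64, 64, nyquist_optics.pixel_size)
        h, w = grid.extent
        ph = make_sphere_phantom(
            grid, [SphereSpec((w / 2, h / 2), 1.0, 1.588, 1.518)], LAM)
        X, _ = grid.mesh()
        img = PhaseImage(grid=grid, phase=ph.phase + 0.02 * X)
        out = background_correct(img, radius=3.0)
        assert out.phase.max() == pytest.approx(ph.peak, rel=0.03)

    def test_idempotent(self, nyquist_optics):
        grid = ImageGrid(64, 64, nyquist_optics.pixel_size)
        rng = np.random.default_rng(3)
        h, w = grid.extent
        ph = make_sphere_phantom(
            grid, [SphereSpec((w / 2, h / 2), 1.0, 1.588, 1.518)], LAM)
        img = PhaseImage(grid=grid,
                         phase=ph.phase + rng.normal(0, 0.003, grid.shape))
        once = background_correct(img, radius=3.0)
        twice = background_correct(once, radius=3.0)
        rms = np.sqrt(np.mean((twice.phase - once.phase) ** 2))
        assert rms < 1e-3

    def test_small_radius_rejected(self):
        grid = ImageGrid(16, 16, PX)
        img = PhaseImage(grid=grid, phase=np.zeros(grid.shape))
        with pytest.raises(ValueError, match="radius"):
            background_correct(img, radius=0.1)


class TestVolume:
    def _stacks(self, nyquist_optics, nplanes):
        grid = ImageGrid(24, 24, nyquist_optics.pixel_size)
        stacks = []
        for z in range(nplanes):
            ph = make_random_phantom(grid, 0.4, 0.7, seed=100 + z)
            stacks.append(acquire_bias_series(ph, nyquist_optics,
                                              BiasSchedule.uniform(4),
                                              blur=False))
        return stacks

    def test_twelve_planes_in_twelve_out(self, nyquist_optics):
        planes = reconstruct_volume(self._stacks(nyquist_optics, 12))
        assert len(planes) == 12

    def test_single_plane_reduces_to_2d_pipeline(self, nyquist_optics):
        stacks = self._stacks(nyquist_optics, 1)
        vol = reconstruct_volume(stacks)[0]
        grad = demodulate_nstep(stacks[0])
        flat = integrate_hilbert(grad, nyquist_optics.shear_distance)
        np.testing.assert_array_equal(vol.phase, flat.phase)

    def test_plane_independence_under_permutation(self, nyquist_optics):
        stacks = self._stacks(nyquist_optics, 4)
        fwd = reconstruct_volume(stacks)
        rev = reconstruct_volume(stacks[::-1])[::-1]
        for a, b in zip(fwd, rev):
            np.testing.assert_array_equal(a.phase, b.phase)

    def test_mismatched_grids_rejected(self, nyquist_optics):
        stacks = self._stacks(nyquist_optics, 2)
        grid2 = ImageGrid(32, 32, nyquist_optics.pixel_size)
        ph = make_random_phantom(grid2, 0.4, 0.7, seed=1)
        stacks.append(acquire_bias_series(ph, nyquist_optics,
                                          BiasSchedule.uniform(4), blur=False))
        with pytest.raises(ValueError, match="grid"):
            reconstruct_volume(stacks)


def test_phase_to_index_difference_roundtrip():
    grid = ImageGrid(8, 8, PX)
    t = 1.0
    dn = 0.07
    phase = PhaseImage(grid=grid,
                       phase=np.full(grid.shape, 2 * np.pi / LAM * dn * t))
    np.testing.assert_allclose(phase_to_index_difference(phase, LAM, t), dn,
                               rtol=1e-12)
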