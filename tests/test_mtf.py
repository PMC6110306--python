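"""Modulation analysis: profiles, peak fitting, intrinsic MTF recovery."""

import math

import numpy as np
import pytest

from hgspect import digitizer as dg
from hgspect import mtf
from hgspect.engine import PlanarImage
from hgspect.mtf import (IntrinsicMtfFit, UnresolvedModulation,
                         intrinsic_mtf, measure_modulation, measure_quadrants,
                         omega_to_sigma, project_profile, resolution_limit)
from hgspect.synthetic import make_toy_scene

FWHM = 2 * math.sqrt(2 * math.log(2))


class TestProjectProfile:
    def test_uniform_image_gives_constant_profile(self):
        img = PlanarImage(np.ones((100, 100)), 1.0)
        pos, prof = project_profile(img, (-20, 20, -10, 10), "x")
        assert np.allclose(prof, prof[0])

    def test_profile_total_equals_region_total(self, rng):
        img = PlanarImage(rng.uniform(size=(100, 100)), 1.0)
        pos, prof = project_profile(img, (-20, 20, -10, 10), "x")
        xc, yc = img.x_centers(), img.y_centers()
        sel = img.counts[np.ix_((yc >= -10) & (yc < 10),
                                (xc >= -20) & (xc < 20))]
        assert prof.sum() == pytest.approx(sel.sum())
        assert len(pos) == sel.shape[1]

    def test_synthetic_stripes_keep_their_period(self):
        img = PlanarImage(np.zeros((200, 200)), 0.5)
        x = img.x_centers()
        img.counts[:] = 1.0 + 0.8 * np.sin(2 * np.pi * x / 6.0)
        pos, prof = project_profile(img, (-40, 40, -40, 40), "x")
        f = np.fft.rfftfreq(len(prof), 0.5)
        amp = np.abs(np.fft.rfft(prof - prof.mean()))
        assert f[np.argmax(amp)] == pytest.approx(1 / 6.0, abs=0.01)

    def test_empty_region_rejected(self):
        img = PlanarImage(np.ones((10, 10)), 1.0)
        with pytest.raises(ValueError):
            project_profile(img, (100, 200, 0, 1))


class TestMeasureModulation:
    def test_sinusoid_recovers_amplitude_ratio(self):
        x = np.arange(0.25, 60, 0.5)
        p = 8.0
        prof = 10.0 + 4.0 * np.cos(2 * np.pi * (x - p / 4) / p)
        m = measure_modulation(x, prof, p)
        assert m.modulation == pytest.approx(0.4, rel=0.01)

    def test_scaling_invariance(self):
        x = np.arange(0.25, 60, 0.5)
        prof = 10.0 + 3.0 * np.cos(2 * np.pi * (x - 2.0) / 8.0)
        m1 = measure_modulation(x, prof, 8.0)
        m2 = measure_modulation(x, 37.5 * prof, 8.0)
        assert m1.modulation == pytest.approx(m2.modulation, rel=1e-6)

    def test_constant_profile_has_zero_modulation(self):
        # every window is a featureless plateau: A_max equals A_min
        x = np.arange(0.25, 60, 0.5)
        m = measure_modulation(x, np.full_like(x, 5.0), 8.0)
        assert m.modulation == 0.0

    def test_too_short_profile_rejected(self):
        x = np.arange(0.25, 10, 0.5)
        with pytest.raises(ValueError, match="three periods"):
            measure_modulation(x, np.ones_like(x), 8.0)

    def test_wrong_frequency_pattern_is_unresolved(self):
        # a Moire-like pattern at 9.6 mm shows peaks, but not on the
        # 8 mm grid
        x = np.arange(0.25, 64, 0.5)
        prof = 10.0 + 4.0 * np.cos(2 * np.pi * (x - 2.0) / 9.6)
        with pytest.raises(UnresolvedModulation):
            measure_modulation(x, prof, 8.0)

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 1.5])
    def test_blurred_square_wave_matches_fourier_series(self, sigma):
        """Gaussian-blurred 50% square wave: the peak/trough Gaussian
        fits reproduce the analytic harmonic-series modulation."""
        p = 8.0
        x = np.arange(0.05, 64, 0.1)

        def series(xv):
            out = np.zeros_like(xv) + 0.5
            for k in range(1, 13, 2):
                att = math.exp(-2 * (math.pi * sigma * k / p) ** 2)
                out += (2 / (math.pi * k)) * att \
                    * np.sin(2 * np.pi * k * xv / p)
            return out
        prof = series(x)
        peak = series(np.array([p / 4.0]))[0]
        trough = series(np.array([3 * p / 4.0]))[0]
        expected = (peak - trough) / (peak + trough)
        m = measure_modulation(x, prof, p)
        assert m.modulation == pytest.approx(expected, rel=0.02)

    def test_modulation_non_increasing_with_blur(self):
        from scipy.ndimage import gaussian_filter1d
        p = 8.0
        x = np.arange(0.05, 64, 0.1)
        sq = (np.mod(x, p) < p / 2).astype(float)
        last = 1.0
        for sigma in (0.5, 1.0, 2.0, 3.0):
            prof = gaussian_filter1d(sq, sigma / 0.1, mode="nearest")
            m = measure_modulation(x, prof, p)
            assert m.modulation <= last + 1e-6
            last = m.modulation


class TestIntrinsicMtf:
    def _mods(self, vals):
        return [mtf.ModulationMeasurement(p, v, 1 + v, 1 - v)
                for p, v in vals]

    def test_identical_measurements_give_zero_sigma(self):
        mods = self._mods([(4, 0.5), (6, 0.6), (8, 0.7), (10, 0.8)])
        fit = intrinsic_mtf(mods, mods)
        assert math.isinf(fit.omega)
        assert fit.sigma == 0.0

    def test_paper_width_parameter_conversion(self):
        # omega = 0.0873 / mm <-> sigma = 1.823 mm, FWHM = 4.29 mm
        assert omega_to_sigma(0.0873) == pytest.approx(1.823, abs=2e-3)
        fit = IntrinsicMtfFit((0.1,), (0.5,), 0.0873)
        assert fit.sigma == pytest.approx(1.823, abs=2e-3)
        assert fit.fwhm == pytest.approx(4.29, abs=0.01)

    def test_recovers_known_gaussian_ratio(self):
        sigma_true = 1.5
        freqs = [1 / 4, 1 / 6, 1 / 8, 1 / 10]
        sim = self._mods([(1 / f, 0.8) for f in freqs])
        meas = self._mods([
            (1 / f, 0.8 * math.exp(-2 * (math.pi * sigma_true * f) ** 2))
            for f in freqs])
        fit = intrinsic_mtf(meas, sim)
        assert fit.sigma == pytest.approx(sigma_true, rel=0.01)

    def test_ratios_above_one_are_clipped_with_warning(self):
        sim = self._mods([(6, 0.5), (8, 0.6), (10, 0.62)])
        meas = self._mods([(6, 0.55), (8, 0.5), (10, 0.5)])
        with pytest.warns(UserWarning, match="clipped"):
            fit = intrinsic_mtf(meas, sim)
        assert fit.ratios[0] == 1.0

    def test_zero_simulated_modulation_rejected(self):
        sim = self._mods([(6, 0.0), (8, 0.6)])
        meas = self._mods([(6, 0.1), (8, 0.5)])
        with pytest.raises(ValueError, match="zero"):
            intrinsic_mtf(meas, sim)


class TestBarImageRecovery:
    @pytest.mark.parametrize("sigma_true", [1.0, 1.82, 2.5])
    def test_injected_blur_recovered_within_ten_percent(self, sigma_true):
        """Blur a bar image by a known intrinsic LSF and recover the
        width through the full modulation / MTF pipeline.

        The reference image carries a mild blur of its own (standing in
        for collimator response and hole sampling, as a raw simulated
        image would) so that the profiles are band-limited; the ratio
        of measured to reference modulations then isolates the injected
        Gaussian.
        """
        mask = make_toy_scene("bar_mask_only", matrix=320, pixel_size=0.5)
        base = dg.apply_intrinsic_blur(mask, dg.IntrinsicBlurModel(1.2))
        blurred = dg.apply_intrinsic_blur(
            base, dg.IntrinsicBlurModel(sigma_true))
        sim = measure_quadrants(base)
        meas = measure_quadrants(blurred)
        pairs = [(meas[p], sim[p]) for p in sim
                 if meas[p] is not None and sim[p] is not None]
        assert len(pairs) >= 3
        fit = intrinsic_mtf(*zip(*pairs))
        assert fit.sigma == pytest.approx(sigma_true, rel=0.10)


class TestResolutionLimit:
    def test_ideal_mask_resolves_everything(self):
        img = make_toy_scene("bar_mask_only", matrix=320, pixel_size=0.5)
        assert resolution_limit(img) == 4.0

    def test_heavy_blur_resolves_nothing(self):
        img = make_toy_scene("bar_mask_only", matrix=320, pixel_size=0.5)
        smeared = dg.apply_intrinsic_blur(img, dg.IntrinsicBlurModel(8.0))
        assert resolution_limit(smeared) is None

    def test_moderate_blur_removes_only_fine_quadrants(self):
        img = make_toy_scene("bar_mask_only", matrix=320, pixel_size=0.5)
        blurred = dg.apply_intrinsic_blur(img, dg.IntrinsicBlurModel(2.2))
        assert resolution_limit(blurred) in (6.0, 8.0)
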