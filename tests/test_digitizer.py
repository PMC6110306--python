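"""Energy-resolution model, window acceptance, and spatial blurring."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize

from hgspect import digitizer as dg
from hgspect.digitizer import (EnergyResolutionModel, EnergyWindow,
                               IntrinsicBlurModel, apply_intrinsic_blur,
                               blur_spectrum, build_resolution_model,
                               window_acceptance_weight)
from hgspect.engine import PlanarImage


class TestResolutionModel:
    def test_two_point_fit_through_measured_resolutions(self):
        # absolute FWHM line through (134, 12.864) and (279, 25.389)
        m = build_resolution_model([(134.0, 0.096), (279.0, 0.091)])
        assert m.fwhm_slope == pytest.approx(0.08638, abs=2e-5)
        assert m.fwhm_intercept == pytest.approx(1.289, abs=2e-3)
        assert m.fwhm(134.0) == pytest.approx(12.864, abs=1e-6)

    def test_meets_vendor_bound_at_140_keV(self):
        m = dg.MEASURED_RESOLUTION
        assert m.relative_fwhm(140.0) <= 0.096
        assert m.relative_fwhm(140.0) == pytest.approx(0.0956, abs=5e-4)

    def test_equal_relative_resolutions_give_proportional_model(self):
        m = build_resolution_model([(100.0, 0.08), (200.0, 0.08)])
        assert m.fwhm_slope == pytest.approx(0.08)
        assert m.fwhm_intercept == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_resolution_model([(134.0, 0.096)])
        with pytest.raises(ValueError):
            build_resolution_model([(134.0, 0.096), (134.0, 0.091)])


class TestBlurSpectrum:
    def _grid(self):
        return np.arange(20.0, 300.0, 0.5) + 0.25

    def test_zero_width_model_is_identity(self):
        centers = self._grid()
        counts = np.zeros_like(centers)
        counts[100] = 7.0
        ident = EnergyResolutionModel(0.0, 0.0)
        assert np.allclose(blur_spectrum(centers, counts, ident), counts)

    def test_delta_spreads_to_the_model_fwhm(self):
        centers = self._grid()
        counts = np.zeros_like(centers)
        i134 = int(np.argmin(np.abs(centers - 134.0)))
        counts[i134] = 1e6
        out = blur_spectrum(centers, counts, dg.MEASURED_RESOLUTION)

        def gauss(x, a, mu, sig):
            return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)
        popt, _ = optimize.curve_fit(gauss, centers, out,
                                     p0=[out.max(), 134.0, 5.0])
        fwhm = abs(popt[2]) * 2 * math.sqrt(2 * math.log(2))
        assert fwhm == pytest.approx(12.864, rel=0.01)

    def test_total_counts_conserved_with_padding(self, rng):
        centers = self._grid()
        counts = np.zeros_like(centers)
        counts[150:300] = rng.uniform(0, 100, 150)
        out = blur_spectrum(centers, counts, dg.MEASURED_RESOLUTION)
        assert out.sum() == pytest.approx(counts.sum(), rel=1e-6)

    def test_too_coarse_bins_rejected(self):
        centers = np.arange(20.0, 300.0, 5.0)
        counts = np.ones_like(centers)
        with pytest.raises(ValueError, match="bin width"):
            blur_spectrum(centers, counts, dg.MEASURED_RESOLUTION)

    def test_nonuniform_bins_rejected(self):
        centers = np.array([20.0, 21.0, 23.0, 24.0])
        with pytest.raises(ValueError):
            blur_spectrum(centers, np.ones(4), dg.MEASURED_RESOLUTION)


class TestWindowAcceptance:
    def test_sharp_resolution_accepts_interior_energy_fully(self):
        m = EnergyResolutionModel(0.0, 1e-6)
        w = EnergyWindow(70.0, 0.30)
        assert window_acceptance_weight(70.0, w, m) == pytest.approx(1.0)
        assert window_acceptance_weight(40.0, w, m) == pytest.approx(0.0)

    def test_half_weight_exactly_on_the_edge(self):
        w = EnergyWindow(135.0, 0.20)
        for edge in (w.lower, w.upper):
            # 0.5 up to the ~2e-6 tail of the opposite window edge
            assert window_acceptance_weight(edge, w,
                                            dg.MEASURED_RESOLUTION) \
                == pytest.approx(0.5, abs=1e-4)

    def test_backscattered_279_lands_in_the_135_window(self):
        """Quadrature oracle: the Gaussian centred at 133.37 keV
        integrated over [121.5, 148.5] exceeds 0.9."""
        m = dg.MEASURED_RESOLUTION
        w = EnergyWindow(135.0, 0.20)
        sig = float(m.sigma(133.37))
        oracle = integrate.quad(
            lambda e: math.exp(-0.5 * ((e - 133.37) / sig) ** 2)
            / (sig * math.sqrt(2 * math.pi)), w.lower, w.upper)[0]
        got = float(window_acceptance_weight(133.37, w, m))
        assert got == pytest.approx(oracle, abs=1e-9)
        assert got > 0.9

    def test_partition_of_the_energy_axis_sums_to_one(self):
        bounds = [1.0, 59.5, 80.5, 121.5, 148.5, 252.0, 308.0, 5000.0]
        windows = [EnergyWindow((a + b) / 2, (b - a) / ((a + b) / 2))
                   for a, b in zip(bounds[:-1], bounds[1:])]
        for E in (45.0, 70.0, 100.0, 133.4, 200.0, 279.0, 305.0):
            total = sum(float(window_acceptance_weight(E, w,
                                                       dg.MEASURED_RESOLUTION))
                        for w in windows)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_window_bounds_convention(self):
        w = EnergyWindow(70.0, 0.30)
        assert w.lower == pytest.approx(59.5)
        assert w.upper == pytest.approx(80.5)
        with pytest.raises(ValueError):
            EnergyWindow(10.0, 2.5)


class TestIntrinsicBlur:
    def test_zero_sigma_is_identity(self, rng):
        img = PlanarImage(rng.uniform(size=(32, 32)), 0.5)
        out = apply_intrinsic_blur(img, IntrinsicBlurModel(0.0))
        assert np.array_equal(out.counts, img.counts)

    def test_point_source_spreads_to_4p29_mm_fwhm(self):
        img = PlanarImage(np.zeros((201, 201)), 0.25)
        img.counts[100, 100] = 1.0
        out = apply_intrinsic_blur(img, IntrinsicBlurModel(1.82))
        prof = out.counts[100]
        x = img.x_centers()
        half = prof.max() / 2

        def crossing(side):
            idx = np.where(prof >= half)[0]
            i = idx[0] if side == "l" else idx[-1]
            j = i - 1 if side == "l" else i + 1
            f = (prof[i] - half) / (prof[i] - prof[j])
            return x[i] + f * (x[j] - x[i])
        fwhm = crossing("r") - crossing("l")
        assert fwhm == pytest.approx(4.29, rel=0.01)

    def test_gaussian_semigroup(self, rng):
        counts = np.zeros((96, 96))
        counts[36:60, 36:60] = rng.uniform(size=(24, 24))
        img = PlanarImage(counts, 1.0)
        one = apply_intrinsic_blur(img, IntrinsicBlurModel(2.5))
        two = apply_intrinsic_blur(
            apply_intrinsic_blur(img, IntrinsicBlurModel(1.5)),
            IntrinsicBlurModel(2.0))
        rms = np.sqrt(np.mean((one.counts - two.counts) ** 2))
        assert rms < 1e-6 * img.counts.max()

    def test_counts_conserved_away_from_edges(self):
        img = PlanarImage(np.zeros((128, 128)), 1.0)
        img.counts[64, 64] = 1000.0
        out = apply_intrinsic_blur(img, IntrinsicBlurModel(3.0))
        assert out.counts.sum() == pytest.approx(1000.0, rel=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            IntrinsicBlurModel(-1.0)
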