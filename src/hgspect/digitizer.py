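"""Finite-resolution models applied after transport.

The camera's energy resolution is modeled as a linear absolute FWHM
versus energy (a two-point fit to measured photo-peak widths); its
intrinsic spatial resolution as an isotropic Gaussian line-spread
function.  The energy model is used two ways, kept deliberately
separate: spectra are convolved bin-by-bin with energy-dependent
Gaussians, while for imaging each detected event is weighted by the
probability that its (Gaussian-smeared) pulse falls inside the energy
window - the overlap of the window with a normal CDF centred on the
deposited energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import ndtr

FWHM_OVER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))   # 2.35482


@dataclass(frozen=True)
class EnergyResolutionModel:
    """Absolute FWHM(E) = slope * E + intercept (keV); an optional
    affine channel->keV calibration rides along."""

    fwhm_slope: float
    fwhm_intercept: float
    calibration_gain: float = 1.0      # keV per channel
    calibration_offset: float = 0.0    # keV

    def fwhm(self, E) -> np.ndarray:
        return self.fwhm_slope * np.asarray(E, float) + self.fwhm_intercept

    def sigma(self, E) -> np.ndarray:
        return self.fwhm(E) / FWHM_OVER_SIGMA

    def relative_fwhm(self, E) -> np.ndarray:
        return self.fwhm(E) / np.asarray(E, float)

    def channel_to_energy(self, channel) -> np.ndarray:
        return self.calibration_gain * np.asarray(channel, float) \
            + self.calibration_offset


@dataclass(frozen=True)
class EnergyWindow:
    """Acceptance window given as centre energy and fractional full
    width: bounds = centre * (1 +- width/2)."""

    center: float
    fractional_width: float

    def __post_init__(self):
        if self.center <= 0 or self.fractional_width <= 0:
            raise ValueError("window centre and width must be positive")
        if self.lower <= 0:
            raise ValueError("window lower bound must be positive")

    @property
    def lower(self) -> float:
        return self.center * (1.0 - self.fractional_width / 2.0)

    @property
    def upper(self) -> float:
        return self.center * (1.0 + self.fractional_width / 2.0)

    @property
    def label(self) -> str:
        return f"{self.center:g}keV"


#: the three acquisition windows used throughout the study
STUDY_WINDOWS = (EnergyWindow(70.0, 0.30), EnergyWindow(135.0, 0.20),
                 EnergyWindow(280.0, 0.20))


@dataclass(frozen=True)
class IntrinsicBlurModel:
    """Isotropic Gaussian intrinsic LSF of width sigma (mm)."""

    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def fwhm(self) -> float:
        return self.sigma * FWHM_OVER_SIGMA


def build_resolution_model(points) -> EnergyResolutionModel:
    """Least-squares affine fit of absolute FWHM versus energy.

    ``points`` are (energy keV, relative FWHM fraction) pairs, e.g.
    ``[(134, 0.096), (279, 0.091)]``; with exactly two points the fit
    interpolates them.
    """
    pts = [(float(e), float(r)) for e, r in points]
    if len(pts) < 2:
        raise ValueError("need at least two calibration points")
    energies = np.array([e for e, _ in pts])
    if len(np.unique(energies)) < len(energies):
        raise ValueError("calibration energies must be distinct")
    fwhm_abs = np.array([e * r for e, r in pts])
    slope, intercept = np.polyfit(energies, fwhm_abs, 1)
    return EnergyResolutionModel(float(slope), float(intercept))


#: model from the study's measured photo-peak resolutions
#: (9.6% at 134 keV, 9.1% at 279 keV)
MEASURED_RESOLUTION = build_resolution_model([(134.0, 0.096), (279.0, 0.091)])


def blur_spectrum(bin_centers: np.ndarray, counts: np.ndarray,
                  model: EnergyResolutionModel) -> np.ndarray:
    """Convolve a binned spectrum with energy-dependent Gaussians.

    Each source bin spreads into a Gaussian of sigma(E_bin); total
    counts are conserved (the Gaussian mass is normalised over an
    extended axis, so edge leakage stays off the returned grid only if
    the occupied range is padded - callers binning the full deposit
    range lose < 1e-6).
    """
    bin_centers = np.asarray(bin_centers, float)
    counts = np.asarray(counts, float)
    widths = np.diff(bin_centers)
    if len(bin_centers) < 2 or not np.allclose(widths, widths[0]):
        raise ValueError("spectrum bins must be uniform")
    db = widths[0]
    occupied = bin_centers[counts > 0]
    fwhms = model.fwhm(occupied)
    fwhms = fwhms[fwhms > 0]     # zero-width bins pass through unblurred
    if len(fwhms):
        min_fwhm = fwhms.min()
        if db > min_fwhm / 5.0 + 1e-12:
            raise ValueError(f"bin width {db} too coarse for FWHM "
                             f"{min_fwhm:.3g} (need <= FWHM/5)")
    out = np.zeros_like(counts)
    sig = model.sigma(bin_centers)
    for i in np.nonzero(counts)[0]:
        s = sig[i]
        if s <= 0:
            out[i] += counts[i]
            continue
        lo = (bin_centers - 0.5 * db - bin_centers[i]) / s
        hi = (bin_centers + 0.5 * db - bin_centers[i]) / s
        out += counts[i] * (ndtr(hi) - ndtr(lo))
    return out


def window_acceptance_weight(E, window: EnergyWindow,
                             model: EnergyResolutionModel) -> np.ndarray:
    """Probability that a deposit of true energy E registers inside the
    window: Phi((upper-E)/sigma(E)) - Phi((lower-E)/sigma(E))."""
    E = np.asarray(E, float)
    sig = np.maximum(model.sigma(E), 1e-12)
    return ndtr((window.upper - E) / sig) - ndtr((window.lower - E) / sig)


def apply_intrinsic_blur(image, model: IntrinsicBlurModel):
    """Convolve a planar image with the intrinsic Gaussian LSF.
    Accepts a PlanarImage (returns the same type) or a bare array with
    ``pixel_size`` given implicitly as 1."""
    from .engine import PlanarImage
    if model.sigma < 0:
        raise ValueError("sigma must be non-negative")
    if isinstance(image, PlanarImage):
        if model.sigma == 0:
            return PlanarImage(image.counts.copy(), image.pixel_size)
        s = model.sigma / image.pixel_size
        return PlanarImage(ndimage.gaussian_filter(image.counts, s,
                                                   mode="constant",
                                                   truncate=8.0),
                           image.pixel_size)
    arr = np.asarray(image, float)
    if model.sigma == 0:
        return arr.copy()
    return ndimage.gaussian_filter(arr, model.sigma, mode="constant",
                                   truncate=8.0)
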