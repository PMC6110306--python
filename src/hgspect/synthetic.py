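"""Pseudo-measurement generation with known ground truth.

No measured camera data ships with this package; instead, "measured"
datasets are emulated from raw simulation output by applying the same
degradations the analysis assumes real data to contain: an intrinsic
Gaussian blur of known width and Poisson counting noise at a chosen
count level.  Because the injected parameters are recorded alongside,
every analysis stage (MTF recovery, photopeak fitting, reconstruction
metrics) can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import digitizer as dg
from .engine import PlanarImage
from .geometry import bar_mask_blocked


@dataclass
class PseudoMeasurementSpec:
    """Degradation recipe: intrinsic blur sigma (mm), expected total
    counts, and the noise seed."""

    injected_sigma: float
    count_scale: float
    seed: int = 0

    def __post_init__(self):
        if self.injected_sigma < 0:
            raise ValueError("injected sigma must be >= 0")
        if self.count_scale <= 0:
            raise ValueError("count scale must be positive")


@dataclass
class PseudoMeasurement:
    data: object                      # PlanarImage or ndarray
    truth: PseudoMeasurementSpec


def make_pseudo_measurement(base, spec: PseudoMeasurementSpec,
                            poisson: bool = True,
                            pixel_size: float = 1.0) -> PseudoMeasurement:
    """Blur ``base`` (a PlanarImage, spectrum array or projection
    stack) with the injected sigma, scale it to the requested expected
    total counts and draw Poisson counts per bin.  For bare arrays the
    injected sigma (mm) is converted with ``pixel_size``."""
    rng = np.random.default_rng(spec.seed)
    if isinstance(base, PlanarImage):
        blurred = dg.apply_intrinsic_blur(
            base, dg.IntrinsicBlurModel(spec.injected_sigma)).counts
    else:
        arr = np.asarray(base, float)
        model = dg.IntrinsicBlurModel(spec.injected_sigma / pixel_size)
        if arr.ndim == 3:      # projection stack: blur per view
            blurred = np.stack([dg.apply_intrinsic_blur(a, model)
                                for a in arr])
        else:
            blurred = dg.apply_intrinsic_blur(arr, model)
    tot = blurred.sum()
    if tot <= 0:
        raise ValueError("base dataset has no counts")
    expected = blurred * (spec.count_scale / tot)
    out = rng.poisson(expected).astype(float) if poisson else expected
    if isinstance(base, PlanarImage):
        return PseudoMeasurement(PlanarImage(out, base.pixel_size), spec)
    return PseudoMeasurement(out, spec)


def make_toy_scene(kind: str, matrix: int = 128, pixel_size: float = 1.0,
                   **kw) -> PlanarImage:
    """Closed-form test images.

    kinds: ``point`` (delta at ``at`` pixel), ``disk`` (uniform disk of
    ``radius`` mm), ``two_blobs`` (Gaussian blobs of ``sigma`` mm
    separated by ``separation`` mm), ``bar_mask_only`` (ideal binary
    transmission image of the four-quadrant bar mask).
    """
    img = np.zeros((matrix, matrix))
    half = (matrix - 1) / 2.0
    yy, xx = np.meshgrid(*(np.arange(matrix),) * 2, indexing="ij")
    y = (yy - half) * pixel_size
    x = (xx - half) * pixel_size
    if kind == "point":
        iy, ix = kw.get("at", (matrix // 2, matrix // 2))
        img[iy, ix] = kw.get("amplitude", 1.0)
    elif kind == "disk":
        r = kw.get("radius", 10.0)
        img[x**2 + y**2 <= r**2] = 1.0
    elif kind == "two_blobs":
        sep = kw.get("separation", 30.0)
        sig = kw.get("sigma", 4.0)
        for cx in (-sep / 2, sep / 2):
            img += np.exp(-((x - cx) ** 2 + y**2) / (2 * sig**2))
    elif kind == "bar_mask_only":
        img = (~bar_mask_blocked(x, y,
                                 half_x=kw.get("half_x", 60.0),
                                 half_y=kw.get("half_y", 40.0))).astype(float)
        img[(np.abs(x) > kw.get("half_x", 60.0))
            | (np.abs(y) > kw.get("half_y", 40.0))] = 0.0
    else:
        raise ValueError(f"unknown toy scene kind {kind!r}")
    return PlanarImage(img, pixel_size)
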