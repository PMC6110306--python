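"""Dual-head SPECT acquisition, OSEM reconstruction and source metrics.

Two opposed heads rotate around the phantom's axial (x) axis; in the
simulation the phantom co-rotates instead, which is equivalent.  Each
head records planar projections in its own detector frame; posterior
views are, for a parallel-hole geometry, identical to anterior views
from the opposite gantry angle, so the combined projection set spans
360 degrees.

Reconstruction is plain OSEM (ordered-subsets expectation maximisation)
with a pixel-driven rotate-and-sum projector whose backprojector is the
exact matrix transpose - this guarantees the MLEM likelihood ascent
property.  No attenuation, scatter or collimator-resolution modelling
is applied, matching the study's reconstruction settings (the vendor's
resolution-recovering algorithm is deliberately replaced by this
generic OSEM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import digitizer as dg
from . import engine
from .geometry import PhantomScene
from .nuclide import SourceMixture, line_weights


@dataclass
class ProjectionSet:
    """Stack of planar projections: ``images[k, iy, ix]`` with iy the
    trans-axial detector pixel and ix the axial one."""

    images: np.ndarray
    angles_deg: np.ndarray
    pixel_size: float
    head: str = "anterior"

    def __post_init__(self):
        self.images = np.asarray(self.images, float)
        self.angles_deg = np.asarray(self.angles_deg, float)
        if len(self.images) != len(self.angles_deg):
            raise ValueError("one angle per projection required")
        d = np.diff(self.angles_deg)
        if len(d) and not np.allclose(d, d[0]):
            raise ValueError("angle spacing must be uniform")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    def combined_with(self, posterior: "ProjectionSet") -> "ProjectionSet":
        """Merge anterior and posterior sets into one 360-degree set
        (posterior views enter as gantry angle + 180 degrees)."""
        if self.images.shape != posterior.images.shape:
            raise ValueError("projection shapes differ")
        return ProjectionSet(
            np.concatenate([self.images, posterior.images]),
            np.concatenate([self.angles_deg, posterior.angles_deg + 180.0]),
            self.pixel_size, "combined")


@dataclass
class ReconVolume:
    """Reconstructed voxel grid: ``data[s, iy, iz]`` for axial slice
    index ``axial_indices[s]``; voxel size equals the projection pixel
    size."""

    data: np.ndarray
    voxel_size: float
    axial_indices: np.ndarray = None

    def __post_init__(self):
        if np.any(self.data < 0):
            raise ValueError("reconstruction must be non-negative")
        if self.axial_indices is None:
            self.axial_indices = np.arange(self.data.shape[0])

    def central_slice(self) -> np.ndarray:
        return self.data[len(self.data) // 2]


def geometric_mean(ant, post, flip_posterior: bool = True):
    """Per-pixel sqrt(anterior * posterior) conjugate-view image.

    The posterior image is recorded in its own detector frame (mirrored
    trans-axially); ``flip_posterior`` maps it into the anterior frame
    before combining.
    """
    a = ant.counts if isinstance(ant, engine.PlanarImage) else np.asarray(ant)
    b = post.counts if isinstance(post, engine.PlanarImage) \
        else np.asarray(post)
    if a.shape != b.shape:
        raise ValueError("geometric mean requires matching shapes")
    if flip_posterior:
        b = b[::-1, :]
    g = np.sqrt(a * b)
    if isinstance(ant, engine.PlanarImage):
        return engine.PlanarImage(g, ant.pixel_size)
    return g


# ---------------------------------------------------------------------------
# Acquisition

def acquire_projections(scene: PhantomScene, mixture: SourceMixture,
                        t_h: float = 0.0, n_per_channel: int | dict = 200_000,
                        seed: int = 0, n_positions: int = 45,
                        arc_deg: float = 180.0, matrix: int = 64,
                        pixel_size: float = 6.39,
                        windows=dg.STUDY_WINDOWS,
                        resolution_model=dg.MEASURED_RESOLUTION,
                        intrinsic=dg.IntrinsicBlurModel(1.82),
                        energies=(70.0, 77.0, 134.0, 279.0),
                        cones: dict | None = None):
    """Simulate a dual-head SPECT acquisition of the abdominal scene.

    The gantry steps through ``n_positions`` angles over ``arc_deg``;
    per angle the four mono-energetic channels are simulated, weighted
    by the source's line weights at time ``t_h``, window-accepted
    (summed over the acquisition windows) and intrinsically blurred.
    Returns (anterior, posterior) :class:`ProjectionSet`.
    """
    if scene.kind != "abdominal":
        raise ValueError("SPECT acquisition requires the abdominal scene")
    weights = line_weights(mixture, t_h)
    angles = np.arange(n_positions) * (arc_deg / n_positions)
    stacks = {0: [], 1: []}
    for k, ang in enumerate(angles):
        scene.rotation_deg = float(ang)
        ev = engine.run_channels(scene, energies, n_per_channel,
                                 seed + 10007 * k, cones)
        for head in (0, 1):
            img = np.zeros((matrix, matrix))
            for E, events in ev.items():
                sel = events.select(events.head == head)
                per_em = events.n_histories
                for wdw in windows:
                    sub = engine.bin_events_to_image(
                        sel, matrix, pixel_size, wdw, resolution_model)
                    img += sub.counts * (weights[E] / per_em)
            if intrinsic is not None and intrinsic.sigma > 0:
                img = ndimage.gaussian_filter(
                    img, intrinsic.sigma / pixel_size, mode="constant")
            stacks[head].append(img)
    scene.rotation_deg = 0.0
    return (ProjectionSet(np.array(stacks[0]), angles, pixel_size,
                          "anterior"),
            ProjectionSet(np.array(stacks[1]), angles, pixel_size,
                          "posterior"))


# ---------------------------------------------------------------------------
# OSEM with an exact adjoint pair

class _Projector:
    """Rotate-and-sum parallel projector for one grid size; forward and
    backprojection share the same bilinear weights (exact transpose)."""

    def __init__(self, n: int, angles_deg):
        self.n = n
        self.angles = np.asarray(angles_deg, float)
        self._taps = [self._build(a) for a in self.angles]

    def _build(self, ang_deg):
        n = self.n
        a = math.radians(ang_deg)
        c, s = math.cos(a), math.sin(a)
        half = (n - 1) / 2.0
        iy, iz = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        y = iy - half
        z = iz - half
        # sample the phantom-frame image at the rotated coordinates
        py = c * y - s * z + half
        pz = s * y + c * z + half
        y0 = np.floor(py).astype(np.int64)
        z0 = np.floor(pz).astype(np.int64)
        fy = py - y0
        fz = pz - z0
        taps = []
        for dy, dz, w in ((0, 0, (1 - fy) * (1 - fz)),
                          (0, 1, (1 - fy) * fz),
                          (1, 0, fy * (1 - fz)),
                          (1, 1, fy * fz)):
            yy = y0 + dy
            zz = z0 + dz
            ok = (yy >= 0) & (yy < n) & (zz >= 0) & (zz < n)
            idx = np.where(ok, yy * n + zz, 0)
            taps.append((idx.ravel(), np.where(ok, w, 0.0).ravel()))
        return taps

    def rotate(self, f: np.ndarray, k: int) -> np.ndarray:
        out = np.zeros(self.n * self.n)
        flat = f.ravel()
        for idx, w in self._taps[k]:
            out += flat[idx] * w
        return out.reshape(self.n, self.n)

    def forward(self, f: np.ndarray, k: int) -> np.ndarray:
        """Line integrals at angle k: sum of the rotated image over z."""
        return self.rotate(f, k).sum(axis=1)

    def back(self, q: np.ndarray, k: int) -> np.ndarray:
        """Exact adjoint of :meth:`forward`."""
        g = np.repeat(q[:, None], self.n, axis=1).ravel()
        out = np.zeros(self.n * self.n)
        for idx, w in self._taps[k]:
            np.add.at(out, idx, g * w)
        return out.reshape(self.n, self.n)


def poisson_loglikelihood(sino: np.ndarray, f: np.ndarray,
                          projector: _Projector) -> float:
    """sum_k sum_u [ p log(Af) - Af ], the Poisson data likelihood."""
    ll = 0.0
    for k in range(len(projector.angles)):
        fp = projector.forward(f, k)
        ll += float((sino[k] * np.log(fp + 1e-12) - fp).sum())
    return ll


def osem_slice(sino: np.ndarray, angles_deg, subsets: int = 2,
               iterations: int = 8, projector: _Projector | None = None,
               track_likelihood: bool = False):
    """OSEM reconstruction of one trans-axial slice.

    ``sino`` has shape (n_views, n_u).  Views are assigned to subsets
    round-robin; with ``subsets=1`` the update is plain MLEM.  Returns
    the (n_u, n_u) slice, plus the per-update likelihood trace when
    requested.
    """
    sino = np.asarray(sino, float)
    n_views, n = sino.shape
    if n_views % subsets:
        raise ValueError("subset count must divide the number of views")
    if np.any(sino < 0):
        raise ValueError("projections must be non-negative")
    if projector is None:
        projector = _Projector(n, angles_deg)
    subsets_idx = [[k for k in range(n_views) if k % subsets == s]
                   for s in range(subsets)]
    sens = []
    ones = np.ones(n)
    for views in subsets_idx:
        s = np.zeros((n, n))
        for k in views:
            s += projector.back(ones, k)
        sens.append(s)
    f = np.full((n, n), max(sino.sum(), 1e-12) / (n * n * n_views))
    trace = []
    for _ in range(iterations):
        for s, views in enumerate(subsets_idx):
            acc = np.zeros((n, n))
            for k in views:
                fp = projector.forward(f, k)
                acc += projector.back(sino[k] / (fp + 1e-12), k)
            with np.errstate(invalid="ignore"):
                f = np.where(sens[s] > 1e-9, f * acc / sens[s], 0.0)
            if track_likelihood:
                trace.append(poisson_loglikelihood(sino, f, projector))
    if track_likelihood:
        return f, trace
    return f


def osem_reconstruct(projections: ProjectionSet, subsets: int = 2,
                     iterations: int = 8,
                     axial_slices=None) -> ReconVolume:
    """OSEM reconstruction of a combined 360-degree projection set.

    ``axial_slices`` selects the axial (ix) rows to reconstruct; by
    default a central band of 5 slices.  Each trans-axial slice is
    reconstructed independently (parallel-hole geometry).
    """
    n = projections.images.shape[1]
    if axial_slices is None:
        mid = projections.images.shape[2] // 2
        axial_slices = np.arange(mid - 2, mid + 3)
    axial_slices = np.asarray(axial_slices)
    projector = _Projector(n, projections.angles_deg)
    out = np.empty((len(axial_slices), n, n))
    for i, ix in enumerate(axial_slices):
        sino = projections.images[:, :, ix]
        out[i] = osem_slice(sino, projections.angles_deg, subsets,
                            iterations, projector)
    return ReconVolume(out, projections.pixel_size, axial_slices)


# ---------------------------------------------------------------------------
# Source metrics

@dataclass
class SourceMetrics:
    centroids_mm: dict[str, tuple[float, float]]
    distances_mm: dict[tuple[str, str], float]
    widths_mm: dict[str, float]


def _refine_centroid(img, seed_yx, pixel, radius=18.0, iters=3):
    n = img.shape[0]
    half = (n - 1) / 2.0
    cy, cz = seed_yx
    for _ in range(iters):
        iy, iz = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        y = (iy - half) * pixel
        z = (iz - half) * pixel
        sel = (y - cy) ** 2 + (z - cz) ** 2 <= radius**2
        w = np.where(sel, img, 0.0)
        tot = w.sum()
        if tot <= 0:
            return None
        cy = float((w * y).sum() / tot)
        cz = float((w * z).sum() / tot)
    return cy, cz


def _profile_fwhm(vals, coords_mm, peak_near_mm, search_mm=20.0):
    """FWHM of the local peak nearest ``peak_near_mm`` along a sampled
    profile (half of the local maximum, linear interpolation)."""
    sel = np.abs(coords_mm - peak_near_mm) <= search_mm
    if not sel.any():
        return None
    i_peak = np.flatnonzero(sel)[np.argmax(vals[sel])]
    peak = vals[i_peak]
    if peak <= 0:
        return None
    half = peak / 2.0
    left = None
    for i in range(i_peak, 0, -1):
        if vals[i - 1] < half <= vals[i]:
            frac = (vals[i] - half) / (vals[i] - vals[i - 1])
            left = coords_mm[i] + frac * (coords_mm[i - 1] - coords_mm[i])
            break
    right = None
    for i in range(i_peak, len(vals) - 1):
        if vals[i + 1] < half <= vals[i]:
            frac = (vals[i] - half) / (vals[i] - vals[i + 1])
            right = coords_mm[i] + frac * (coords_mm[i + 1] - coords_mm[i])
            break
    if left is None or right is None:
        return None
    return abs(right - left)


def source_metrics(volume: ReconVolume | np.ndarray, expected_centroids,
                   pixel_size: float | None = None) -> SourceMetrics:
    """Centroids, pairwise distances and profile widths of point-like /
    cylindrical sources in a reconstructed trans-axial slice.

    ``expected_centroids`` maps labels to (y, z) seed positions in mm
    (phantom frame).  Centroids refine the seeds by local centre of
    mass; widths are FWHM along the lines connecting neighbouring
    centroids.  Raises when a source has no signal near its seed.
    """
    if isinstance(volume, ReconVolume):
        # the sources are uniform along the reconstructed axial band:
        # averaging the slices suppresses per-slice Poisson noise
        img = volume.data.mean(axis=0)
        pixel = volume.voxel_size
    else:
        img = np.asarray(volume, float)
        if pixel_size is None:
            raise ValueError("pixel_size required for bare arrays")
        pixel = pixel_size
    if len(expected_centroids) < 2:
        raise ValueError("need at least two sources")
    n = img.shape[0]
    half = (n - 1) / 2.0
    centroids = {}
    for label, seed in expected_centroids.items():
        c = _refine_centroid(img, seed, pixel)
        if c is None or math.hypot(c[0] - seed[0], c[1] - seed[1]) > 20.0:
            raise ValueError(f"source {label} not detected near {seed}")
        centroids[label] = c
    labels = list(centroids)
    dists = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            dists[(a, b)] = math.hypot(
                centroids[a][0] - centroids[b][0],
                centroids[a][1] - centroids[b][1])
    pts = np.array([centroids[lab] for lab in labels])
    widths = {}
    for i in range(len(labels)):
        lab = labels[i]
        # profile direction: toward the nearest other centroid
        j = min((k for k in range(len(labels)) if k != i),
                key=lambda k: math.hypot(*(pts[i] - pts[k])))
        d = pts[j] - pts[i]
        d = d / np.linalg.norm(d)
        ts = np.arange(-30.0, 30.0 + 0.25, 0.25)
        ys = pts[i][0] + ts * d[0]
        zs = pts[i][1] + ts * d[1]
        vals = ndimage.map_coordinates(
            img, [ys / pixel + half, zs / pixel + half], order=1)
        w = _profile_fwhm(vals, ts, 0.0)
        if w is not None:
            widths[lab] = w
    return SourceMetrics(centroids, dists, widths)
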