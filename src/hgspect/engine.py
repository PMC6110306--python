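"""Monte Carlo driver: photon histories from emission to detection.

Each history is emitted from the scene's active volumes, transported
through phantom, collimator and layered head, and - if it deposits any
energy in the NaI crystal - recorded as a single pooled detection event
(energy-weighted centroid position, summed deposit), mirroring a real
camera's one-pulse-per-photon readout.

Angular importance sampling ("cone sampling") restricts emission to a
cone (or double cone) about the detector normal and carries the solid
angle fraction as a statistical weight.  It is an optional variance
reduction; the default per-channel cone half-angles are wide enough
that paths excluded from the cone contribute negligibly at the
respective energy.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from . import digitizer as dg
from .geometry import CylinderVolume, BoxVolume, PhantomScene, \
    planar_bar_scene
from .physics import standard_materials

#: kernel material-id order
_MAT_ORDER = ("air", "lead", "nai", "water", "pmma", "aluminum", "bsc")

_N_GRID = 512
_E_LO, _E_HI = 20.0, 700.0

ORIGIN_CLASSES = ("direct", "phantom", "upstream", "downstream")

#: default emission-cone half-angles (radians) per simulated channel.
#: Low-energy channels cannot reach the crystal at large obliquity
#: (septal attenuation), so narrow cones are safe; the 279 keV channel
#: samples a full hemisphere (planar) / sphere (tomographic).
PLANAR_CONES = {70.0: 0.15, 77.0: 0.15, 134.0: 0.6, 279.0: math.pi / 2}
#: tomographic double cones about +-z; spectrum/scatter analyses should
#: pass isotropic cones (math.pi) instead - the narrow defaults trade a
#: small scatter-background deficit for projection statistics
TOMO_CONES = {70.0: 0.12, 77.0: 0.12, 134.0: 0.35, 279.0: 0.9}

_tables_cache = None


def material_tables():
    """Linear-attenuation tables (1/mm) resampled on a common
    log-energy grid for the kernels: (mu_pe, mu_inc, lne0, dln)."""
    global _tables_cache
    if _tables_cache is None:
        mats = standard_materials()
        grid = np.geomspace(_E_LO, _E_HI, _N_GRID)
        mu_pe = np.zeros((len(_MAT_ORDER), _N_GRID))
        mu_inc = np.zeros_like(mu_pe)
        for i, name in enumerate(_MAT_ORDER):
            m = mats[name]
            mu_pe[i] = m.mu(grid, "pe")
            mu_inc[i] = m.mu(grid, "incoherent")
        lne0 = math.log(_E_LO)
        dln = (math.log(_E_HI) - lne0) / (_N_GRID - 1)
        pb = mats["lead"].fluorescence
        fl_e = np.array(pb.line_energies)
        fl_cum = np.cumsum(pb.line_intensities)
        _tables_cache = (mu_pe, mu_inc, lne0, dln, fl_e, fl_cum,
                         pb.k_edge_keV, pb.k_yield)
    return _tables_cache


def compile_scene(scene: PhantomScene, cone_half_angle: float,
                  energy_cutoff: float = 20.0) -> np.ndarray:
    """Flatten a scene into the kernel parameter array."""
    head = scene.head
    lb = head.layer_boundaries
    cyls = [v for v in scene.volumes if isinstance(v, CylinderVolume)]
    geo = np.zeros(K.G_CYL0 + K.CYL_STRIDE * max(1, len(cyls)))
    geo[K.G_KIND] = 0.0 if scene.kind == "planar_bar" else 1.0
    geo[K.G_COL_LEN] = head.collimator.hole_length
    geo[K.G_PITCH] = head.collimator.pitch
    geo[K.G_F2F] = head.collimator.flat_to_flat
    geo[K.G_FHX] = head.face_half_x
    geo[K.G_FHY] = head.face_half_y
    geo[K.G_ZCOV] = lb["cover"][1]
    geo[K.G_ZCRY] = lb["crystal"][1]
    geo[K.G_ZCOUP] = lb["coupling"][1]
    geo[K.G_ZBSC] = lb["bsc"][1]
    geo[K.G_ZBACK] = lb["backshield"][1]
    geo[K.G_SIDE_T] = head.sideshield_thickness
    geo[K.G_CUTOFF] = energy_cutoff
    _, _, _, _, _, _, edge, kyield = material_tables()
    geo[K.G_PB_EDGE] = edge
    geo[K.G_PB_YIELD] = kyield
    if scene.kind == "planar_bar":
        geo[K.G_MASK] = 1.0 if scene.mask_enabled else 0.0
        geo[K.G_P0:K.G_P0 + 4] = scene.bar_periods
        geo[K.G_MHX] = scene.mask_half_x
        geo[K.G_MHY] = scene.mask_half_y
        src = next(v for v in scene.volumes if isinstance(v, BoxVolume))
        geo[K.G_SHX], geo[K.G_SHY] = src.half[0], src.half[1]
        geo[K.G_SZLO] = src.center[2] - src.half[2]
        geo[K.G_SZHI] = src.center[2] + src.half[2]
        geo[K.G_DOUBLE] = 0.0
    else:
        geo[K.G_HDIST] = scene.head_distance
        slab = next(v for v in scene.volumes
                    if isinstance(v, BoxVolume) and v.label == "phantom")
        geo[K.G_SLHX], geo[K.G_SLHY], geo[K.G_SLHZ] = slab.half
        tables = [v for v in scene.volumes
                  if isinstance(v, BoxVolume) and v.label == "table"]
        if tables:
            tb = tables[0]
            geo[K.G_TZLO] = tb.center[2] - tb.half[2]
            geo[K.G_TZHI] = tb.center[2] + tb.half[2]
            geo[K.G_THX], geo[K.G_THY] = tb.half[0], tb.half[1]
        else:
            geo[K.G_TZLO], geo[K.G_TZHI] = 1e6, 1e6  # degenerate, never hit
        ang = math.radians(scene.rotation_deg)
        geo[K.G_CROT], geo[K.G_SROT] = math.cos(ang), math.sin(ang)
        geo[K.G_NCYL] = len(cyls)
        acts = np.array([c.activity for c in cyls], float)
        cum = np.cumsum(acts) / acts.sum()
        for k, c in enumerate(cyls):
            base = K.G_CYL0 + K.CYL_STRIDE * k
            geo[base:base + 5] = (c.y, c.z, c.radius, c.half_length, cum[k])
        geo[K.G_DOUBLE] = 1.0
    geo[K.G_CONE_CMIN] = math.cos(min(cone_half_angle, math.pi))
    if cone_half_angle >= math.pi - 1e-9:
        geo[K.G_CONE_CMIN] = -1.0
        geo[K.G_DOUBLE] = 0.0
    return geo


@dataclass
class EventList:
    """Detected events from one mono-energetic run (structure-of-arrays).

    Positions are head-local detector coordinates (mm); ``origin`` holds
    scatter-origin class indices into :data:`ORIGIN_CLASSES`; ``septa``
    the number of lead septa crossed before the first crystal deposit.
    """

    x: np.ndarray
    y: np.ndarray
    energy: np.ndarray
    weight: np.ndarray
    origin: np.ndarray
    septa: np.ndarray
    head: np.ndarray
    source_energy: float
    n_histories: int
    seed: int
    tallies: dict = field(default_factory=dict)
    geometry_hash: str = ""

    def __len__(self):
        return len(self.x)

    @property
    def emitted_weight(self) -> float:
        return self.tallies.get("emitted", 0.0)

    def select(self, mask: np.ndarray) -> "EventList":
        return EventList(self.x[mask], self.y[mask], self.energy[mask],
                         self.weight[mask], self.origin[mask],
                         self.septa[mask], self.head[mask],
                         self.source_energy, self.n_histories, self.seed,
                         dict(self.tallies), self.geometry_hash)

    @staticmethod
    def concatenate(parts: list["EventList"]) -> "EventList":
        first = parts[0]
        tall = {}
        for p in parts:
            for k, v in p.tallies.items():
                tall[k] = tall.get(k, 0.0) + v
        return EventList(
            *(np.concatenate([getattr(p, f) for p in parts])
              for f in ("x", "y", "energy", "weight", "origin",
                        "septa", "head")),
            first.source_energy,
            sum(p.n_histories for p in parts),
            first.seed, tall, first.geometry_hash)

    def save(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            for name in ("x", "y", "energy", "weight", "origin",
                         "septa", "head"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["source_energy"] = self.source_energy
            f.attrs["n_histories"] = self.n_histories
            f.attrs["seed"] = self.seed
            f.attrs["geometry_hash"] = self.geometry_hash
            for k, v in self.tallies.items():
                f.attrs[f"tally_{k}"] = v

    @staticmethod
    def load(path) -> "EventList":
        import h5py
        with h5py.File(path, "r") as f:
            arrays = {n: f[n][:] for n in ("x", "y", "energy", "weight",
                                           "origin", "septa", "head")}
            tall = {k[6:]: float(v) for k, v in f.attrs.items()
                    if k.startswith("tally_")}
            return EventList(**arrays,
                             source_energy=float(f.attrs["source_energy"]),
                             n_histories=int(f.attrs["n_histories"]),
                             seed=int(f.attrs["seed"]), tallies=tall,
                             geometry_hash=str(f.attrs["geometry_hash"]))


_TALLY_NAMES = ("emitted", "masked", "absorbed", "escaped", "cutoff")


def run_monoenergetic(scene: PhantomScene, E: float, n_histories: int,
                      seed: int, cone_half_angle: float | None = None,
                      chunk: int = 2_000_000) -> EventList:
    """Simulate ``n_histories`` photons of energy ``E`` keV.

    ``cone_half_angle`` overrides the per-channel emission-cone default
    (``math.pi`` disables variance reduction).  Runs are reproducible
    for a fixed (seed, n_histories) pair.
    """
    if n_histories <= 0:
        raise ValueError("n_histories must be positive")
    if not scene.active_volumes:
        raise ValueError("scene has no active volume")
    if cone_half_angle is None:
        cones = PLANAR_CONES if scene.kind == "planar_bar" else TOMO_CONES
        if float(E) not in cones:
            raise ValueError(f"no default emission cone for channel {E} keV; "
                             f"pass cone_half_angle explicitly")
        cone_half_angle = cones[float(E)]
    geo = compile_scene(scene, cone_half_angle)
    mu_pe, mu_inc, lne0, dln, fl_e, fl_cum, _, _ = material_tables()
    ghash = hashlib.sha1(geo.tobytes() + np.float64(E).tobytes()).hexdigest()[:12]

    ss = np.random.SeedSequence(seed)
    parts = []
    remaining = n_histories
    while remaining > 0:
        n = min(chunk, remaining)
        cap = max(20_000, n // 5)
        ev_x = np.empty(cap)
        ev_y = np.empty(cap)
        ev_e = np.empty(cap)
        ev_w = np.empty(cap)
        ev_o = np.empty(cap, np.int8)
        ev_s = np.empty(cap, np.int16)
        ev_h = np.empty(cap, np.int8)
        tall = np.zeros(5)
        sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
        n_done, nev = K.run_histories(
            n, sub, float(E), geo, mu_pe, mu_inc, lne0, dln, fl_e, fl_cum,
            ev_x, ev_y, ev_e, ev_w, ev_o, ev_s, ev_h, tall)
        parts.append(EventList(
            ev_x[:nev].copy(), ev_y[:nev].copy(), ev_e[:nev].copy(),
            ev_w[:nev].copy(), ev_o[:nev].copy(), ev_s[:nev].copy(),
            ev_h[:nev].copy(), float(E), n_done, seed,
            dict(zip(_TALLY_NAMES, tall)), ghash))
        remaining -= n_done
    return parts[0] if len(parts) == 1 else EventList.concatenate(parts)


def run_channels(scene: PhantomScene, energies=(70.0, 77.0, 134.0, 279.0),
                 n_per_channel: int | dict = 1_000_000, seed: int = 0,
                 cones: dict | None = None) -> dict[float, EventList]:
    """Run each mono-energetic channel separately (the per-channel
    event lists can then be reweighted for any activity ratio)."""
    out = {}
    for i, E in enumerate(energies):
        n = n_per_channel[E] if isinstance(n_per_channel, dict) \
            else n_per_channel
        cone = None if cones is None else cones.get(E)
        out[E] = run_monoenergetic(scene, E, n, seed + 1000 * (i + 1),
                                   cone_half_angle=cone)
    return out


# ---------------------------------------------------------------------------
# Imaging

@dataclass
class PlanarImage:
    """A planar count image.  Pixels are square, the grid is centred on
    the detector axis and pixel [0, 0] is the lowest (x, y) corner;
    ``counts[iy, ix]``."""

    counts: np.ndarray
    pixel_size: float

    @property
    def matrix(self) -> tuple[int, int]:
        return self.counts.shape

    def extent(self):
        ny, nx = self.counts.shape
        return (-nx * self.pixel_size / 2, nx * self.pixel_size / 2,
                -ny * self.pixel_size / 2, ny * self.pixel_size / 2)

    def x_centers(self):
        nx = self.counts.shape[1]
        return (np.arange(nx) - nx / 2 + 0.5) * self.pixel_size

    def y_centers(self):
        ny = self.counts.shape[0]
        return (np.arange(ny) - ny / 2 + 0.5) * self.pixel_size


def bin_events_to_image(events: EventList, matrix: int = 1024,
                        pixel_size: float = 0.314,
                        window: "dg.EnergyWindow | None" = None,
                        resolution_model: "dg.EnergyResolutionModel | None" = None,
                        head: int | None = None,
                        weight_scale: float = 1.0) -> PlanarImage:
    """Histogram detected events into a planar image.

    Each event contributes ``weight * window acceptance`` to the pixel
    containing its centroid; boundaries follow the half-open convention
    (a point exactly between two pixels goes to the higher index).
    """
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    w = events.weight * weight_scale
    if window is not None:
        if resolution_model is None:
            raise ValueError("window acceptance requires a resolution model")
        w = w * dg.window_acceptance_weight(events.energy, window,
                                            resolution_model)
    sel = np.ones(len(events), bool)
    if head is not None:
        sel &= events.head == head
    half = matrix * pixel_size / 2.0
    ix = np.floor((events.x + half) / pixel_size).astype(np.int64)
    iy = np.floor((events.y + half) / pixel_size).astype(np.int64)
    sel &= (ix >= 0) & (ix < matrix) & (iy >= 0) & (iy < matrix)
    counts = np.zeros((matrix, matrix))
    np.add.at(counts, (iy[sel], ix[sel]), w[sel])
    return PlanarImage(counts, pixel_size)


def combine_channel_images(images: dict[float, PlanarImage],
                           channel_weights: dict[float, float],
                           per_emitted: dict[float, float]) -> PlanarImage:
    """Weight per-channel images into one full-source image.

    ``channel_weights`` are photons per disintegration for each channel
    (from :func:`hgspect.nuclide.line_weights`); ``per_emitted``
    normalises each channel image by its emitted weight so channels
    simulated with different history counts combine correctly.
    """
    first = next(iter(images.values()))
    out = np.zeros_like(first.counts)
    for E, img in images.items():
        out += img.counts * (channel_weights[E] / per_emitted[E])
    return PlanarImage(out, first.pixel_size)


# ---------------------------------------------------------------------------
# Septal penetration

def septal_penetration_survey(collimator_name: str = "lehr",
                              E: float = 279.0, n: int = 500_000,
                              seed: int = 0, max_septa: int = 60,
                              mask_enabled: bool = False) -> np.ndarray:
    """Weighted distribution of septa crossed by photons that reach and
    interact in the crystal (straight ray-trace tally, no scattering).

    Photons start in the planar flask source; each contributes its
    survival probability through the traversed lead times the crystal
    interaction probability to its septa-count bin.  Returns the
    histogram (index = septa crossed).
    """
    scene = planar_bar_scene(collimator_name, mask_enabled=mask_enabled)
    geo = compile_scene(scene, math.pi / 2)
    mu_pe, mu_inc, lne0, dln, *_ = material_tables()
    hist = np.zeros(max_septa + 1)
    K.septal_survey(n, seed % (2**31 - 1), float(E), geo, mu_pe, mu_inc,
                    lne0, dln, hist)
    return hist
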