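"""Camera-head and phantom geometry.

Coordinate convention (right handed): for each camera head, ``z`` runs
along the head's outward normal with the collimator entrance face at
``z = 0`` and the head body at ``z > 0``; ``x`` is the axial detector
direction (40.6 cm face), ``y`` trans-axial (54 cm face).

The collimator is a lead slab perforated by a triangular lattice of
hexagonal holes.  Hexagons are flat-topped (flat sides parallel to the
x axis) and one hole is centred on the lattice origin; the lattice pitch
is flat-to-flat plus one septal thickness.  Both the hexagon orientation
and the lattice phase are fixed conventions of this package - Moire
patterns in bar-phantom images depend on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

COS30 = math.cos(math.pi / 6.0)
SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class CollimatorSpec:
    """Parallel-hole collimator: hole length, circumscribed-circle
    diameter of the hexagonal hole, and septal thickness, all in mm."""

    name: str
    hole_length: float
    hole_circumdiameter: float
    septal_thickness: float

    def __post_init__(self):
        for v in (self.hole_length, self.hole_circumdiameter,
                  self.septal_thickness):
            if v <= 0:
                raise ValueError("collimator dimensions must be positive")

    @property
    def flat_to_flat(self) -> float:
        return self.hole_circumdiameter * COS30

    @property
    def pitch(self) -> float:
        """Distance between neighbouring hole centres."""
        return self.flat_to_flat + self.septal_thickness

    @property
    def open_fraction(self) -> float:
        """Areal fraction of the face occupied by holes."""
        hex_area = (SQRT3 / 2.0) * self.flat_to_flat**2
        cell_area = (SQRT3 / 2.0) * self.pitch**2
        return hex_area / cell_area


#: Vendor dimensions of the two collimators studied (mm).
LEHR = CollimatorSpec("lehr", 27.0, 1.22, 0.152)
HEGP = CollimatorSpec("hegp", 58.4, 3.81, 1.730)


def collimator(name: str) -> CollimatorSpec:
    try:
        return {"lehr": LEHR, "hegp": HEGP}[name.lower()]
    except KeyError:
        raise ValueError(f"unknown collimator {name!r}") from None


@dataclass(frozen=True)
class CameraHead:
    """Layered gamma-camera head, interior outwards: collimator,
    aluminium cover, NaI crystal, optical coupling, backscatter
    compartment (BSC), lead back/side shielding."""

    collimator: CollimatorSpec
    cover_thickness: float = 1.5          # mm aluminium
    crystal_thickness: float = 9.5        # mm NaI
    coupling_thickness: float = 9.0       # mm light guide (PMMA equivalent)
    bsc_thickness: float = 150.0          # mm, density 1.05 g/cm3
    backshield_thickness: float = 20.0    # mm lead
    sideshield_thickness: float = 20.0    # mm lead
    face_half_x: float = 203.0            # 40.6 cm axial face
    face_half_y: float = 270.0            # 54 cm trans-axial face

    @property
    def layer_boundaries(self) -> dict[str, tuple[float, float]]:
        """z-extent of each layer (mm from the collimator entrance)."""
        z = 0.0
        out = {}
        for name, t in [("collimator", self.collimator.hole_length),
                        ("cover", self.cover_thickness),
                        ("crystal", self.crystal_thickness),
                        ("coupling", self.coupling_thickness),
                        ("bsc", self.bsc_thickness),
                        ("backshield", self.backshield_thickness)]:
            out[name] = (z, z + t)
            z += t
        return out

    @property
    def depth(self) -> float:
        return self.layer_boundaries["backshield"][1]

    @property
    def crystal_z(self) -> tuple[float, float]:
        return self.layer_boundaries["crystal"]


# ---------------------------------------------------------------------------
# Hexagonal lattice

def hole_center(i: int, j: int, pitch: float) -> tuple[float, float]:
    """Centre of lattice hole (i, j): a1 = pitch*(sqrt3/2, 1/2),
    a2 = pitch*(0, 1)."""
    return (pitch * COS30 * i, pitch * (0.5 * i + j))


def nearest_hole(x: float, y: float, spec: CollimatorSpec
                 ) -> tuple[int, int] | None:
    """Lattice indices of the hole containing (x, y), or None if the
    point lies in a septum."""
    p = spec.pitch
    fi = x / (p * COS30)
    fj = y / p - 0.5 * fi
    best = None
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            i, j = round(fi) + di, round(fj) + dj
            cx, cy = hole_center(i, j, p)
            if point_in_hex(x - cx, y - cy, spec.flat_to_flat):
                best = (i, j)
    return best


def point_in_hex(x: float, y: float, flat_to_flat: float) -> bool:
    """Point-in-hexagon test for a flat-topped hexagon centred at the
    origin (flat sides parallel to x)."""
    h = flat_to_flat / 2.0
    return (abs(y) <= h and abs(SQRT3 * x + y) <= 2.0 * h
            and abs(SQRT3 * x - y) <= 2.0 * h)


def _hex_ray_interval(x0, y0, dx, dy, cx, cy, flat_to_flat):
    """Parameter interval [t0, t1] where the 2-D ray is inside the
    hexagon at (cx, cy); returns None when it misses."""
    h = flat_to_flat / 2.0
    px, py = x0 - cx, y0 - cy
    t_lo, t_hi = -math.inf, math.inf
    # three slab constraints: n.p in [-h, h]
    for nx, ny in ((0.0, 1.0), (SQRT3 / 2.0, 0.5), (-SQRT3 / 2.0, 0.5)):
        num = nx * px + ny * py
        den = nx * dx + ny * dy
        if abs(den) < 1e-15:
            if abs(num) > h:
                return None
            continue
        ta, tb = (-h - num) / den, (h - num) / den
        if ta > tb:
            ta, tb = tb, ta
        t_lo, t_hi = max(t_lo, ta), min(t_hi, tb)
        if t_lo >= t_hi:
            return None
    return (t_lo, t_hi)


def trace_collimator(entry_point, direction, spec: CollimatorSpec):
    """Segment a straight chord through the collimator slab into hole
    (air) and septum (lead) pieces.

    ``entry_point`` is an (x, y, z) position with z inside [0, hole
    length]; ``direction`` must have a positive z component (toward the
    crystal).  Returns ``(segments, septa_crossed)`` where segments is a
    list of ``(material, length_mm)`` with material ``"air_hole"`` or
    ``"lead"``, ordered along the ray and partitioning the chord, and
    septa_crossed counts the maximal lead segments entered.
    """
    x0, y0, z0 = (float(v) for v in entry_point)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    dx, dy, dz = d
    if dz <= 1e-12:
        raise ValueError("direction must point toward the crystal (dz > 0)")
    T = (spec.hole_length - z0) / dz
    intervals = _air_intervals(x0, y0, dx, dy, T, spec)
    segments = []
    septa = 0
    t = 0.0
    for a, b in intervals:
        if a > t + 1e-9:
            segments.append(("lead", a - t))
            septa += 1
        segments.append(("air_hole", b - a))
        t = b
    if t < T - 1e-9:
        segments.append(("lead", T - t))
        septa += 1
    return segments, septa


def _air_intervals(x0, y0, dx, dy, T, spec: CollimatorSpec):
    """Sorted disjoint [t_in, t_out] intervals (clipped to [0, T]) where
    the ray's lateral position lies inside a hexagonal hole."""
    p = spec.pitch
    f2f = spec.flat_to_flat
    len2d = math.hypot(dx, dy) * T
    nstep = int(len2d / (p / 2.0)) + 1
    seen = set()
    for k in range(nstep + 1):
        t = T * k / nstep
        x, y = x0 + dx * t, y0 + dy * t
        fi = x / (p * COS30)
        fj = y / p - 0.5 * fi
        for di in (-2, -1, 0, 1, 2):
            for dj in (-2, -1, 0, 1, 2):
                seen.add((round(fi) + di, round(fj) + dj))
    out = []
    for (i, j) in seen:
        cx, cy = hole_center(i, j, p)
        iv = _hex_ray_interval(x0, y0, dx, dy, cx, cy, f2f)
        if iv is None:
            continue
        a, b = max(iv[0], 0.0), min(iv[1], T)
        if b - a > 1e-12:
            out.append((a, b))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Phantom scenes

@dataclass(frozen=True)
class CylinderVolume:
    """Cylinder with axis along x (phantom frame): centre (y, z),
    radius and half-length in mm, plus a uniform activity."""

    label: str
    y: float
    z: float
    radius: float
    half_length: float
    material: str = "water"
    activity: float = 0.0

    @property
    def volume(self) -> float:
        return math.pi * self.radius**2 * 2.0 * self.half_length

    def contains(self, x, y, z) -> bool:
        return (abs(x) <= self.half_length
                and (y - self.y) ** 2 + (z - self.z) ** 2 <= self.radius**2)


@dataclass(frozen=True)
class BoxVolume:
    """Axis-aligned box (phantom frame): centre and half-widths, mm."""

    label: str
    center: tuple[float, float, float]
    half: tuple[float, float, float]
    material: str = "water"
    activity: float = 0.0

    @property
    def volume(self) -> float:
        return 8.0 * self.half[0] * self.half[1] * self.half[2]

    def contains(self, x, y, z) -> bool:
        cx, cy, cz = self.center
        hx, hy, hz = self.half
        return (abs(x - cx) <= hx and abs(y - cy) <= hy and abs(z - cz) <= hz)


#: bar-phantom quadrant periods, mm: (x<0, y>0), (x>=0, y>0),
#: (x<0, y<0), (x>=0, y<0)
BAR_PERIODS = (4.0, 6.0, 8.0, 10.0)


@dataclass
class PhantomScene:
    """A measurement setup: either the planar bar-phantom geometry or
    the abdominal SPECT slab, plus the camera head(s)."""

    kind: str                              # "planar_bar" | "abdominal"
    head: CameraHead
    volumes: list = field(default_factory=list)
    bar_periods: tuple = BAR_PERIODS
    mask_half_x: float = 60.0
    mask_half_y: float = 40.0
    mask_enabled: bool = True
    head_distance: float = 200.0           # tomo: entrance face to axis, mm
    rotation_deg: float = 0.0              # tomo: gantry angle

    @property
    def active_volumes(self):
        return [v for v in self.volumes if v.activity > 0]

    def total_activity(self) -> float:
        return sum(v.activity for v in self.active_volumes)


def bar_mask_blocked(x, y, periods=BAR_PERIODS,
                     half_x: float = 60.0, half_y: float = 40.0):
    """True where the bar phantom's lead stripes block transmission.

    Stripes run along y (modulation along x) with 50% duty cycle; the
    stripe phase is anchored at each quadrant's inner (x = 0) edge, with
    an open half-period first.  Outside the mask extent nothing blocks.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    q = np.where(y >= 0,
                 np.where(x < 0, 0, 1),
                 np.where(x < 0, 2, 3))
    p = np.asarray(periods, float)[q]
    frac = np.mod(np.abs(x), p) / p
    blocked = frac >= 0.5
    inside = (np.abs(x) <= half_x) & (np.abs(y) <= half_y)
    return blocked & inside


def planar_bar_scene(collimator_name: str = "lehr",
                     mask_enabled: bool = True,
                     activity: float = 1.0) -> PhantomScene:
    """Planar setup: a 12 cm x 8 cm x 4 mm aqueous source layer lying
    directly on the four-quadrant bar mask at the collimator face."""
    head = CameraHead(collimator(collimator_name))
    source = BoxVolume("flask", center=(0.0, 0.0, -2.0),
                       half=(60.0, 40.0, 2.0), material="water",
                       activity=activity)
    return PhantomScene("planar_bar", head, [source],
                        mask_enabled=mask_enabled)


#: abdominal source set: inner diameters 19 / 27 / 5 mm.  Activity
#: concentrations (arbitrary units per mm^3) are a package choice -- the
#: study filled the three containers with "varying" concentrations.
ABDOMINAL_SOURCES = (
    # label, y, z, radius, half_length, concentration
    ("V25", -70.0, 0.0, 13.5, 22.0, 0.5),
    ("V11", 0.0, 0.0, 9.5, 20.0, 1.0),
    ("SYR", 65.0, 0.0, 2.5, 30.0, 2.0),
)


def abdominal_scene(head_distance: float = 200.0,
                    sources=ABDOMINAL_SOURCES,
                    with_table: bool = True) -> PhantomScene:
    """Tomographic setup: a 30 x 20 x 8 cm PMMA slab holding three
    cylindrical sources, on a 2 cm PMMA-equivalent patient table, imaged
    by two opposed LEHR heads."""
    head = CameraHead(LEHR)
    vols = [CylinderVolume(lbl, y, z, r, hl, "water",
                           activity=c * math.pi * r**2 * 2 * hl)
            for lbl, y, z, r, hl, c in sources]
    vols.append(BoxVolume("phantom", center=(0.0, 0.0, 0.0),
                          half=(100.0, 150.0, 40.0), material="pmma"))
    if with_table:
        vols.append(BoxVolume("table", center=(0.0, 0.0, -52.0),
                              half=(150.0, 200.0, 10.0), material="pmma"))
    return PhantomScene("abdominal", head, vols,
                        head_distance=head_distance)


def _rot_x(y, z, angle_deg):
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return c * y - s * z, s * y + c * z


def locate(point, scene: PhantomScene) -> tuple[str, str]:
    """Innermost volume label and material name at a lab-frame point.

    In the tomographic scene the phantom (and table) are rotated by
    ``-rotation_deg`` about the x axis relative to the heads; the point
    is mapped into the phantom frame before containment checks.
    """
    x, y, z = (float(v) for v in point)
    if scene.kind == "abdominal":
        py, pz = _rot_x(y, z, scene.rotation_deg)
    else:
        py, pz = y, z
    cylinders = [v for v in scene.volumes if isinstance(v, CylinderVolume)]
    boxes = [v for v in scene.volumes if isinstance(v, BoxVolume)]
    for v in cylinders:
        if v.contains(x, py, pz):
            return v.label, v.material
    for v in boxes:
        if v.contains(x, py, pz):
            return v.label, v.material
    for hz, hy in _head_frames(scene):
        lx, ly, lz = hz(x, y, z)
        lbl = _locate_head(lx, ly, lz, scene.head)
        if lbl is not None:
            return lbl
    return "air", "air"


def _head_frames(scene: PhantomScene):
    """Lab -> head-local transforms, one per head."""
    if scene.kind == "planar_bar":
        return [(lambda x, y, z: (x, y, z), None)]
    hd = scene.head_distance
    return [(lambda x, y, z: (x, y, z - hd), None),          # anterior
            (lambda x, y, z: (x, -y, -z - hd), None)]        # posterior


def _locate_head(lx, ly, lz, head: CameraHead):
    t = head.sideshield_thickness
    if not (0.0 <= lz <= head.depth):
        return None
    if abs(lx) > head.face_half_x + t or abs(ly) > head.face_half_y + t:
        return None
    if abs(lx) > head.face_half_x or abs(ly) > head.face_half_y:
        return "sideshield", "lead"
    mats = {"collimator": "lead", "cover": "aluminum", "crystal": "nai",
            "coupling": "pmma", "bsc": "bsc", "backshield": "lead"}
    for name, (z0, z1) in head.layer_boundaries.items():
        if z0 <= lz < z1:
            return name, mats[name]
    return "backshield", "lead"


def sample_emission_point(scene: PhantomScene, rng: np.random.Generator,
                          n: int = 1):
    """Uniform emission positions over the active volumes, chosen
    proportionally to each volume's total activity.  Returns
    ``(positions (n,3) in the phantom frame, labels)``."""
    active = scene.active_volumes
    if not active:
        raise ValueError("scene has no active volume")
    acts = np.array([v.activity for v in active])
    idx = rng.choice(len(active), size=n, p=acts / acts.sum())
    pos = np.empty((n, 3))
    labels = []
    for k, i in enumerate(idx):
        v = active[i]
        labels.append(v.label)
        if isinstance(v, BoxVolume):
            cx, cy, cz = v.center
            hx, hy, hz = v.half
            pos[k] = (cx + rng.uniform(-hx, hx),
                      cy + rng.uniform(-hy, hy),
                      cz + rng.uniform(-hz, hz))
        else:
            while True:
                u, w = rng.uniform(-1, 1, 2)
                if u * u + w * w <= 1.0:
                    break
            pos[k] = (rng.uniform(-v.half_length, v.half_length),
                      v.y + u * v.radius, v.z + w * v.radius)
    return pos, labels
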