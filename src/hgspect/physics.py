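"""Photon interaction physics for the 20-700 keV imaging range.

Materials carry tabulated photoelectric and incoherent mass attenuation
coefficients (cm^2/g) on an energy grid; lookups interpolate log-log and
reproduce the table nodes exactly.  Compton scattering uses free-electron
Klein-Nishina kinematics; photoelectric absorption in lead above the
K edge can re-emit a characteristic K X-ray.  Electrons are not
transported: every non-radiated energy transfer deposits locally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

M_E_C2 = 511.0          # electron rest energy, keV
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.35482

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class Fluorescence:
    """K-shell fluorescence data: edge energy, effective emission
    probability per photoelectric absorption above the edge, and the
    K-line energies with relative intensities (normalised)."""

    k_edge_keV: float
    k_yield: float
    line_energies: tuple[float, ...]
    line_intensities: tuple[float, ...]


@dataclass
class Material:
    """Tabulated material. Coefficients are mass attenuation (cm^2/g);
    ``mu`` returns linear attenuation in 1/mm."""

    name: str
    density: float                       # g/cm^3
    energy_keV: np.ndarray               # strictly increasing grid
    mu_pe: np.ndarray                    # photoelectric, cm^2/g
    mu_incoh: np.ndarray                 # incoherent, cm^2/g
    mu_coh: np.ndarray = None            # coherent (optional, unused by default)
    fluorescence: Fluorescence | None = None

    def __post_init__(self):
        self.energy_keV = np.asarray(self.energy_keV, float)
        if np.any(np.diff(self.energy_keV) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if self.density <= 0:
            raise ValueError("density must be positive")
        for arr in (self.mu_pe, self.mu_incoh):
            if np.any(np.asarray(arr) < 0):
                raise ValueError("attenuation coefficients must be >= 0")
        if self.mu_coh is None:
            self.mu_coh = np.zeros_like(self.energy_keV)

    def _interp(self, table: np.ndarray, E) -> np.ndarray:
        E = np.asarray(E, float)
        lo, hi = self.energy_keV[0], self.energy_keV[-1]
        if np.any(E < lo - 1e-9) or np.any(E > hi + 1e-9):
            raise ValueError(f"energy {E} outside table range "
                             f"[{lo}, {hi}] keV for {self.name}")
        logt = np.log(np.maximum(table, 1e-30))
        return np.exp(np.interp(np.log(np.clip(E, lo, hi)),
                                np.log(self.energy_keV), logt))

    def mass_coefficient(self, E, kind: str = "total") -> np.ndarray:
        """Mass attenuation coefficient (cm^2/g), log-log interpolated."""
        if kind == "total":
            return (self._interp(self.mu_pe, E)
                    + self._interp(self.mu_incoh, E))
        table = {"pe": self.mu_pe, "incoherent": self.mu_incoh,
                 "coherent": self.mu_coh}[kind]
        return self._interp(table, E)

    def mu(self, E, kind: str = "total") -> np.ndarray:
        """Linear attenuation coefficient, 1/mm."""
        return self.mass_coefficient(E, kind) * self.density / 10.0


def load_material(name: str, path: str | Path | None = None) -> Material:
    """Load a packaged material table (delimited text, '#' headers)."""
    path = Path(path) if path is not None else _DATA_DIR / f"{name}.csv"
    meta = {}
    for line in path.read_text().splitlines():
        if line.startswith("#") and ":" in line:
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    rows = [line for line in path.read_text().splitlines()
            if line and not line.startswith("#")
            and not line.startswith("energy")]
    arr = np.loadtxt(rows, delimiter=",")
    arr = {"energy_keV": arr[:, 0], "mu_pe": arr[:, 1],
           "mu_incoh": arr[:, 2], "mu_coh": arr[:, 3]}
    fluor = None
    if "K_lines_keV" in meta:
        pairs = [p.split(":") for p in meta["K_lines_keV"].split(",")]
        energies = tuple(float(e) for e, _ in pairs)
        intens = np.array([float(i) for _, i in pairs])
        intens = intens / intens.sum()
        fluor = Fluorescence(float(meta["K_edge_keV"]),
                             float(meta["K_yield"]),
                             energies, tuple(intens))
    return Material(name, float(meta["density_g_cm3"]),
                    arr["energy_keV"], arr["mu_pe"], arr["mu_incoh"],
                    arr["mu_coh"], fluor)


def vacuum() -> Material:
    """Non-interacting placeholder material."""
    grid = np.array([20.0, 700.0])
    return Material("vacuum", 1e-30, grid, np.zeros(2), np.zeros(2))


MATERIAL_NAMES = ("lead", "nai", "water", "pmma", "aluminum", "air", "bsc")


def standard_materials() -> dict[str, Material]:
    mats = {n: load_material(n) for n in MATERIAL_NAMES}
    mats["vacuum"] = vacuum()
    return mats


# ---------------------------------------------------------------------------
# Compton kinematics and sampling

def compton_scatter_energy(E: float, theta) -> np.ndarray:
    """Scattered photon energy after a Compton event at angle theta.

    ``E' = E / (1 + (E / m_e c^2)(1 - cos theta))``; monotone decreasing
    in theta, with E'(0) = E.
    """
    return E / (1.0 + (E / M_E_C2) * (1.0 - np.cos(theta)))


def klein_nishina_differential(E: float, theta) -> np.ndarray:
    """Unnormalised Klein-Nishina differential cross section
    d(sigma)/d(Omega) as a function of polar angle."""
    r = compton_scatter_energy(E, theta) / E
    return 0.5 * r**2 * (r + 1.0 / r - np.sin(theta) ** 2)


def sample_compton_angle(E: float, rng: np.random.Generator) -> float:
    """Sample a Compton polar angle from the Klein-Nishina distribution
    by rejection on a uniform cos(theta) proposal."""
    fmax = klein_nishina_differential(E, 0.0)
    while True:
        c = rng.uniform(-1.0, 1.0)
        theta = math.acos(c)
        if rng.uniform(0.0, fmax) <= klein_nishina_differential(E, theta):
            return theta


@dataclass(frozen=True)
class InteractionOutcome:
    """Result of one sampled interaction.  Energy is conserved:
    incident = deposited + emitted."""

    kind: str                      # photoelectric | compton | fluorescence_emission
    deposited_energy: float        # keV, local deposit
    new_energy: float | None = None
    new_direction: tuple[float, float, float] | None = None


def _rotate(direction, theta, phi):
    """Rotate a unit vector by polar angle theta about itself with
    azimuth phi (standard scatter-frame rotation)."""
    d = np.asarray(direction, float)
    # build orthonormal frame around d
    if abs(d[2]) < 0.999:
        u = np.cross(d, [0.0, 0.0, 1.0])
    else:
        u = np.cross(d, [1.0, 0.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    st = math.sin(theta)
    out = math.cos(theta) * d + st * (math.cos(phi) * u + math.sin(phi) * v)
    return tuple(out / np.linalg.norm(out))


def sample_interaction(material: Material, E: float,
                       rng: np.random.Generator) -> InteractionOutcome:
    """Sample one interaction in ``material`` at energy ``E``.

    The interaction type is drawn proportionally to the partial linear
    attenuation coefficients.  Compton events sample the Klein-Nishina
    angular distribution; photoelectric events in a fluorescent material
    above its K edge re-emit a K X-ray isotropically with the configured
    yield.
    """
    mu_pe = float(material.mu(E, "pe"))
    mu_inc = float(material.mu(E, "incoherent"))
    total = mu_pe + mu_inc
    if total <= 0:
        raise ValueError(f"material {material.name} has no cross section at {E} keV")
    if rng.uniform(0.0, total) < mu_pe:
        fl = material.fluorescence
        if fl is not None and E > fl.k_edge_keV and rng.uniform() < fl.k_yield:
            idx = rng.choice(len(fl.line_energies), p=fl.line_intensities)
            e_line = fl.line_energies[idx]
            costh = rng.uniform(-1.0, 1.0)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            st = math.sqrt(1.0 - costh**2)
            return InteractionOutcome(
                "fluorescence_emission", E - e_line, e_line,
                (st * math.cos(phi), st * math.sin(phi), costh))
        return InteractionOutcome("photoelectric", E)
    theta = sample_compton_angle(E, rng)
    e_new = float(compton_scatter_energy(E, theta))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    return InteractionOutcome("compton", E - e_new, e_new,
                              _rotate((0.0, 0.0, 1.0), theta, phi))


def sample_interaction_along(material: Material, E: float, direction,
                             rng: np.random.Generator) -> InteractionOutcome:
    """Like :func:`sample_interaction` but rotating the sampled scatter
    relative to an arbitrary incident direction."""
    out = sample_interaction(material, E, rng)
    if out.kind == "compton":
        theta = math.acos(min(1.0, max(-1.0,
                 (1.0 - (E / out.new_energy - 1.0) * M_E_C2 / E))))
        phi = rng.uniform(0.0, 2.0 * math.pi)
        return InteractionOutcome(out.kind, out.deposited_energy,
                                  out.new_energy,
                                  _rotate(direction, theta, phi))
    return out


def free_path_length(material: Material, E: float,
                     rng: np.random.Generator) -> float:
    """Exponential free path (mm) at energy E; infinite when the
    material does not attenuate."""
    mu = float(material.mu(E, "total"))
    if mu <= 1e-20:
        return math.inf
    return rng.exponential(1.0 / mu)


def klein_nishina_total(E) -> np.ndarray:
    """Total Klein-Nishina cross section per electron (barn); used to
    build incoherent columns and as a quadrature cross-check."""
    a = np.asarray(E, float) / M_E_C2
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = -(1 + 3 * a) / (1 + 2 * a) ** 2
    return 0.75 * 0.66524587 * (t1 + t2 + t3)
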