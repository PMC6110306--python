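"""Two-isomer radiomercury source model.

Mercury-197 exists as a long-lived ground state (T1/2 = 64.1 h, EC to
Au-197) and a shorter-lived metastable state (T1/2 = 23.8 h) that decays
to the ground state by internal transition with a branching fraction of
0.91.  Imaging studies characterise a sample by the activity ratio
``R_a = A(ground) / A(metastable)``, which grows with time because the
metastable state decays faster.

Mono-energetic simulations are combined into a full-source prediction by
weighting each simulated channel (70, 77, 134, 279 keV) with the summed
photon intensities of the emission lines assigned to it, scaled by the
activity share of the parent isomer at the requested time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

LN2 = math.log(2.0)

_DEFAULT_CONFIG = Path(__file__).parent / "data" / "hg197m.yaml"


@dataclass(frozen=True)
class IsomerSpec:
    """One nuclear state: name, half-life in hours, and (for the
    metastable state) the branching fraction of its decays that feed the
    ground state."""

    name: str
    half_life_h: float
    branching_to_ground: float = 0.0

    def __post_init__(self):
        if self.half_life_h <= 0:
            raise ValueError(f"half-life must be positive, got {self.half_life_h}")
        if not 0.0 <= self.branching_to_ground <= 1.0:
            raise ValueError("branching fraction must lie in [0, 1]")

    @property
    def decay_constant(self) -> float:
        """lambda = ln2 / T1/2, per hour."""
        return LN2 / self.half_life_h


@dataclass(frozen=True)
class EmissionLine:
    """A single photon emission: energy (keV), intensity in photons per
    disintegration of the parent isomer, and the parent's name."""

    energy_keV: float
    intensity: float
    parent: str
    label: str = ""

    def __post_init__(self):
        if self.energy_keV <= 0:
            raise ValueError("emission energy must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass
class SourceMixture:
    """A two-isomer source: isomer specs, emission lines, the activity
    ratio at a reference time, and the line -> simulated-channel map."""

    isomers: list[IsomerSpec]
    lines: list[EmissionLine]
    activity_ratio_ref: float
    reference_time_h: float = 0.0
    channel_assignment: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.activity_ratio_ref <= 0:
            raise ValueError("activity_ratio_ref must be positive")
        names = {iso.name for iso in self.isomers}
        for line in self.lines:
            if line.parent not in names:
                raise ValueError(f"line {line} has unknown parent {line.parent!r}")

    def isomer(self, name: str) -> IsomerSpec:
        for iso in self.isomers:
            if iso.name == name:
                return iso
        raise KeyError(name)

    @property
    def ground(self) -> IsomerSpec:
        return next(i for i in self.isomers if i.branching_to_ground == 0.0)

    @property
    def metastable(self) -> IsomerSpec:
        return next(i for i in self.isomers if i.branching_to_ground > 0.0)

    def with_activity_ratio(self, ratio: float, reference_time_h: float = 0.0
                            ) -> "SourceMixture":
        return SourceMixture(self.isomers, self.lines, ratio,
                             reference_time_h, dict(self.channel_assignment))


def load_mixture(path: str | Path | None = None) -> SourceMixture:
    """Load a source mixture from YAML (the packaged Hg-197(m) defaults
    if no path is given)."""
    path = Path(path) if path is not None else _DEFAULT_CONFIG
    cfg = yaml.safe_load(path.read_text())
    isomers = [IsomerSpec(d["name"], d["half_life_h"],
                          d.get("branching_to_ground", 0.0))
               for d in cfg["isomers"]]
    lines = [EmissionLine(d["energy_keV"], d["intensity"], d["parent"],
                          d.get("label", ""))
             for d in cfg["lines"]]
    return SourceMixture(isomers, lines,
                         cfg.get("activity_ratio_ref", 1.0),
                         cfg.get("reference_time_h", 0.0),
                         dict(cfg.get("channel_assignment", {})))


def default_mixture(activity_ratio: float = 1.0) -> SourceMixture:
    """Packaged Hg-197(m) source with a chosen activity ratio at t=0."""
    return load_mixture().with_activity_ratio(activity_ratio)


def evolve_activity_ratio(mixture: SourceMixture, t_h: float,
                          mode: str = "simple") -> float:
    """Activity ratio R_a at time ``t_h`` hours after the reference time.

    mode="simple" propagates both isomers independently:
    ``R_a(t) = R_a(0) * exp((lambda_m - lambda_g) t)``.

    mode="bateman" additionally feeds the ground state with the
    metastable decays that branch to it (fraction 0.91), using the
    closed-form Bateman solution for a two-member chain.  The result is
    always >= the simple mode for t > 0, because ingrowth only adds
    ground-state activity.
    """
    if t_h < 0:
        raise ValueError("time must be non-negative")
    g, m = mixture.ground, mixture.metastable
    lam_g, lam_m = g.decay_constant, m.decay_constant
    r0 = mixture.activity_ratio_ref
    if mode == "simple":
        return r0 * math.exp((lam_m - lam_g) * t_h)
    if mode == "bateman":
        # activities at t relative to A_m(0) = 1, A_g(0) = r0
        am = math.exp(-lam_m * t_h)
        # ingrown ground-state nuclei from the metastable feed:
        # A_g^in(t) = b * lam_g/(lam_g - lam_m) * (exp(-lam_m t) - exp(-lam_g t))
        b = m.branching_to_ground
        ag = r0 * math.exp(-lam_g * t_h)
        ag += b * lam_g / (lam_g - lam_m) * (math.exp(-lam_m * t_h)
                                             - math.exp(-lam_g * t_h))
        return ag / am
    raise ValueError(f"unknown mode {mode!r}")


def activity_fractions(mixture: SourceMixture, t_h: float,
                       mode: str = "simple") -> dict[str, float]:
    """Fraction of total activity (disintegration rate) per isomer at t."""
    ra = evolve_activity_ratio(mixture, t_h, mode)
    return {mixture.ground.name: ra / (1.0 + ra),
            mixture.metastable.name: 1.0 / (1.0 + ra)}


def line_weights(mixture: SourceMixture, t_h: float = 0.0,
                 mode: str = "simple") -> dict[float, float]:
    """Per-channel photon weights per total disintegration at time t.

    Each emission line contributes ``intensity * activity_fraction(parent)``
    to the simulated channel it is assigned to.  Raises if any line with
    non-zero intensity has no channel assignment.
    """
    frac = activity_fractions(mixture, t_h, mode)
    weights: dict[float, float] = {}
    orphans = []
    for line in mixture.lines:
        key = line.label or f"{line.energy_keV:g}"
        if key not in mixture.channel_assignment:
            if line.intensity > 0:
                orphans.append(key)
            continue
        ch = float(mixture.channel_assignment[key])
        weights[ch] = weights.get(ch, 0.0) + line.intensity * frac[line.parent]
    if orphans:
        raise ValueError(f"emission lines not mapped to any simulated "
                         f"channel: {orphans}")
    return dict(sorted(weights.items()))
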