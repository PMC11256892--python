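"""Charge-regulated collagen-mimetic rod model.

A collagen molecule is coarse-grained as a flexible bead-spring rod that
carries a sequence of discrete charges.  Acidic and basic sites titrate with
the solution pH (deterministic Henderson-Hasselbalch rounding), which is the
single control parameter that drives disassembly (acidic, net-positive rods
repel) and reassembly (neutral pH, amphoteric rods attract).

Interactions:

* screened electrostatics between charged beads (Debye-Hueckel),
* a generic nonspecific attraction between all beads (Lennard-Jones 12-6),
* harmonic stretch/bend terms along each rod,
* an exponential electrostatic surface term: the negatively charged substrate
  (mica) attracts positive beads and repels negative ones.

Energies are expressed in units of kT at the simulation temperature; all
lengths are in nanometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import constants

__all__ = [
    "ChargeSite",
    "ChargedRod",
    "ElectrostaticParams",
    "LJParams",
    "SurfaceParams",
    "BufferSpec",
    "ConfigurationError",
    "assign_charges",
    "ionic_strength",
    "debye_length",
    "bjerrum_length",
    "pair_energy_dh",
    "pair_energy_lj",
    "surface_energy",
    "collagen_mimetic_rod",
    "default_electrostatics",
    "default_lj",
    "default_surface",
]

ACIDIC = "acidic"
BASIC = "basic"
NEUTRAL = "neutral"


class ConfigurationError(ValueError):
    """Raised for inconsistent model configuration (e.g. a titratable site
    without a pKa)."""


@dataclass(frozen=True)
class ChargeSite:
    """One titratable (or permanently neutral) bead position along a rod.

    ``charge`` is the current protonation-state charge in elementary-charge
    units; allowed values depend on ``site_class``:
    acidic -> {-1, 0}, basic -> {0, +1}, neutral -> {0}.
    """

    index: int
    site_class: str
    pKa: float | None = None
    charge: int = 0

    def __post_init__(self) -> None:
        if self.site_class not in (ACIDIC, BASIC, NEUTRAL):
            raise ConfigurationError(f"unknown site_class {self.site_class!r}")
        allowed = {ACIDIC: (-1, 0), BASIC: (0, 1), NEUTRAL: (0,)}[self.site_class]
        if self.charge not in allowed:
            raise ConfigurationError(
                f"{self.site_class} site at index {self.index} cannot carry "
                f"charge {self.charge}"
            )
        if self.site_class != NEUTRAL and self.pKa is not None and not math.isfinite(self.pKa):
            raise ConfigurationError("pKa must be finite")


@dataclass(frozen=True)
class ChargedRod:
    """Bead-spring rod template: the collagen-mimetic molecule.

    Parameters
    ----------
    n_beads:
        Number of beads (>= 2).
    bead_spacing, bead_diameter:
        Rest bond length and excluded-volume diameter, nm.
    sites:
        Charge sites; at most one per bead index.
    bond_stiffness:
        Harmonic stretch constant, kT/nm^2.
    bend_stiffness:
        Harmonic bending constant about the straight configuration, kT/rad^2.
    """

    n_beads: int
    bead_spacing: float = 1.5
    bead_diameter: float = 1.5
    sites: tuple[ChargeSite, ...] = field(default_factory=tuple)
    bond_stiffness: float = 60.0
    bend_stiffness: float = 20.0

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ConfigurationError("a rod needs at least 2 beads")
        if self.bead_spacing <= 0 or self.bead_diameter <= 0:
            raise ConfigurationError("bead_spacing and bead_diameter must be > 0")
        if len(self.sites) > self.n_beads:
            raise ConfigurationError("more charge sites than beads")
        idx = [s.index for s in self.sites]
        if len(set(idx)) != len(idx):
            raise ConfigurationError("duplicate charge-site index")
        if idx and (min(idx) < 0 or max(idx) >= self.n_beads):
            raise ConfigurationError("charge-site index out of range")

    @property
    def length(self) -> float:
        """Contour length (nm) of the straight rod, end bead centre to centre."""
        return (self.n_beads - 1) * self.bead_spacing

    def charge_array(self) -> np.ndarray:
        """Per-bead charge vector (length ``n_beads``) in elementary charges."""
        q = np.zeros(self.n_beads)
        for s in self.sites:
            q[s.index] = s.charge
        return q

    def total_charge(self) -> float:
        return float(self.charge_array().sum())


def assign_charges(rod_template: ChargedRod, pH: float) -> ChargedRod:
    """Return a copy of the rod with site charges set by the pH.

    Deterministic rounding of the Henderson-Hasselbalch occupancy: an acidic
    site is deprotonated (charge -1) iff pH > pKa, a basic site is protonated
    (charge +1) iff pH < pKa.  At pH == pKa exactly, the site is neutral (tie
    broken toward zero charge).  Neutral sites are untouched.  Idempotent.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    new_sites = []
    for s in rod_template.sites:
        if s.site_class == NEUTRAL:
            new_sites.append(s)
            continue
        if s.pKa is None:
            raise ConfigurationError(
                f"titratable ({s.site_class}) site at index {s.index} has no pKa"
            )
        if s.site_class == ACIDIC:
            q = -1 if pH > s.pKa else 0
        else:  # basic
            q = +1 if pH < s.pKa else 0
        new_sites.append(replace(s, charge=q))
    return replace(rod_template, sites=tuple(new_sites))


# ---------------------------------------------------------------------------
# Buffer -> screening length
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BufferSpec:
    """Electrolyte composition: list of (name, molar concentration, charge).

    ``relative_permittivity`` defaults to bulk water at 25 C; it enters only
    through the Debye and Bjerrum lengths.
    """

    species: tuple[tuple[str, float, int], ...]
    temperature: float = 300.0
    relative_permittivity: float = 78.54

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be > 0")
        for name, conc, _z in self.species:
            if conc < 0:
                raise ConfigurationError(f"negative concentration for {name}")


def ionic_strength(buffer: BufferSpec) -> float:
    """I = 1/2 sum_i c_i z_i^2, in mol/L."""
    return 0.5 * sum(c * z * z for _n, c, z in buffer.species)


def debye_length(buffer: BufferSpec) -> float:
    """Debye screening length kappa^-1 in nm.

    kappa^-1 = sqrt(eps_r eps_0 kB T / (2 NA e^2 I)) with I in mol/m^3.
    """
    I = ionic_strength(buffer)
    if I <= 0:
        raise ValueError("zero ionic strength: unscreened regime unsupported")
    I_si = I * 1000.0 * constants.N_A  # ions / m^3
    k2 = 2.0 * constants.e**2 * I_si / (
        constants.epsilon_0 * buffer.relative_permittivity
        * constants.k * buffer.temperature
    )
    return 1e9 / math.sqrt(k2)


def bjerrum_length(buffer: BufferSpec) -> float:
    """Bjerrum length e^2 / (4 pi eps_0 eps_r kB T) in nm (~0.71 nm in water)."""
    lb = constants.e**2 / (
        4.0 * math.pi * constants.epsilon_0 * buffer.relative_permittivity
        * constants.k * buffer.temperature
    )
    return lb * 1e9


# ---------------------------------------------------------------------------
# Pair and surface potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrostaticParams:
    """Debye-Hueckel parameters (nm).  ``bjerrum_length`` is the coupling
    strength; for lumped coarse-grained charges it may exceed the bare water
    value."""

    debye_length: float
    bjerrum_length: float
    cutoff: float

    def __post_init__(self) -> None:
        if min(self.debye_length, self.bjerrum_length, self.cutoff) <= 0:
            raise ConfigurationError("electrostatic lengths must be > 0")
        if self.cutoff < 3.0 * self.debye_length:
            raise ConfigurationError("cutoff must be >= 3 x debye_length")


@dataclass(frozen=True)
class LJParams:
    sigma: float
    epsilon: float
    cutoff: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if self.epsilon < 0:
            raise ConfigurationError("epsilon must be >= 0")
        if self.cutoff <= self.sigma:
            raise ConfigurationError("cutoff must exceed sigma")


@dataclass(frozen=True)
class SurfaceParams:
    """Exponential electrostatic substrate term at the plane z = 0.

    The substrate is negatively charged, so a bead of charge q has energy
    E(z) = -strength * q * exp(-z/decay_length): attraction for q > 0,
    repulsion of the same form for q < 0.  Hard exclusion below the bead
    radius is enforced kinematically by the integrator's reflecting wall.
    """

    strength: float = 2.0
    decay_length: float = 1.0
    mode: str = "on"
    surface_charge_sign: str = "negative"

    def __post_init__(self) -> None:
        if self.strength < 0 or self.decay_length <= 0:
            raise ConfigurationError("bad surface parameters")
        if self.mode not in ("on", "off"):
            raise ConfigurationError("surface mode must be 'on' or 'off'")
        if self.surface_charge_sign != "negative":
            raise ConfigurationError("only a negative substrate is modelled")


def pair_energy_dh(q1: float, q2: float, r, params: ElectrostaticParams):
    """Screened-Coulomb pair energy in kT, cut and shifted at the cutoff.

    u(r) = lB q1 q2 [exp(-r/lD)/r - exp(-rc/lD)/rc]  for r < rc, else 0.
    The shift makes the energy continuous at rc; the force is unaffected.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    rc, lD, lB = params.cutoff, params.debye_length, params.bjerrum_length
    shift = math.exp(-rc / lD) / rc
    u = lB * q1 * q2 * (np.exp(-r / lD) / r - shift)
    return np.where(r < rc, u, 0.0)[()]


def pair_energy_lj(r, params: LJParams):
    """12-6 Lennard-Jones pair energy in kT, cut and shifted at the cutoff.

    The shift is the constant 4 eps [(s/rc)^12 - (s/rc)^6]; at r = sigma the
    shifted value therefore differs from zero by exactly that constant.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    s6 = (params.sigma / r) ** 6
    sc6 = (params.sigma / params.cutoff) ** 6
    u = 4.0 * params.epsilon * (s6 * s6 - s6) - 4.0 * params.epsilon * (sc6 * sc6 - sc6)
    return np.where(r < params.cutoff, u, 0.0)[()]


def surface_energy(z, q, params: SurfaceParams):
    """Per-bead substrate energy in kT (vectorised over z, q)."""
    if params.mode == "off":
        return np.zeros_like(np.broadcast_arrays(np.asarray(z, float), np.asarray(q, float))[0])[()]
    z = np.asarray(z, dtype=float)
    q = np.asarray(q, dtype=float)
    return (-params.strength * q * np.exp(-z / params.decay_length))[()]


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------

#: Repeating 10-bead charge motif: a lysine/arginine-like basic block, an
#: aspartate/glutamate-like acidic block, one histidine-like site (neutral at
#: pH 7.4, protonated under acid) and neutral spacers.  The true collagen
#: charge sequence is not modelled; this motif reproduces the qualitative
#: titration behaviour (amphoteric at neutral pH, purely cationic under acid).
DEFAULT_MOTIF: tuple[tuple[str, float | None], ...] = (
    (BASIC, 10.5),
    (BASIC, 10.5),
    (BASIC, 10.5),
    (NEUTRAL, None),
    (ACIDIC, 4.2),
    (ACIDIC, 4.2),
    (ACIDIC, 4.2),
    (BASIC, 6.0),  # histidine-like
    (NEUTRAL, None),
    (NEUTRAL, None),
)


def collagen_mimetic_rod(
    n_beads: int = 30,
    bead_spacing: float = 1.5,
    bead_diameter: float = 1.5,
    motif: tuple[tuple[str, float | None], ...] = DEFAULT_MOTIF,
    bond_stiffness: float = 60.0,
    bend_stiffness: float = 20.0,
) -> ChargedRod:
    """Default collagen-mimetic rod: the charge motif tiled along the beads."""
    sites = []
    for i in range(n_beads):
        cls, pka = motif[i % len(motif)]
        if cls != NEUTRAL:
            sites.append(ChargeSite(index=i, site_class=cls, pKa=pka))
    return ChargedRod(
        n_beads=n_beads,
        bead_spacing=bead_spacing,
        bead_diameter=bead_diameter,
        sites=tuple(sites),
        bond_stiffness=bond_stiffness,
        bend_stiffness=bend_stiffness,
    )


def default_electrostatics(debye_length_nm: float = 1.5,
                           bjerrum_length_nm: float = 7.0,
                           cutoff_nm: float = 6.0) -> ElectrostaticParams:
    """Default screened-electrostatics parameters.

    The Bjerrum coupling is an *effective* value: each charged bead lumps
    several residue charges, so the bead-bead coupling exceeds the bare
    aqueous Bjerrum length (~0.71 nm).
    """
    return ElectrostaticParams(debye_length=debye_length_nm,
                               bjerrum_length=bjerrum_length_nm,
                               cutoff=cutoff_nm)


def default_lj(sigma_nm: float = 1.5, epsilon_kT: float = 0.25,
               cutoff_nm: float = 3.75) -> LJParams:
    return LJParams(sigma=sigma_nm, epsilon=epsilon_kT, cutoff=cutoff_nm)


def default_surface(strength_kT: float = 2.0, decay_nm: float = 1.0,
                    mode: str = "on") -> SurfaceParams:
    return SurfaceParams(strength=strength_kT, decay_length=decay_nm, mode=mode)
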