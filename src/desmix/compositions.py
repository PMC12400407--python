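"""Composition algebra for the hexanoic-acid/imidazole deep eutectic solvent.

The solvent simplex contains the hydrogen-bond donor HexA (hexanoic
acid), the acceptor IMID (imidazole), their proton-transfer products
HexA- (hexanoate) and IMID+ (imidazolium), and water.  Mole fractions
are defined over these solvent species only; extraction oils (OLEC,
LINO) are carried as a mass loading (g oil / g solvent) and never enter
the solvent simplex, because extraction studies vary chi_IMID at fixed
oil mass.

The module provides

* :func:`make_composition` -- build a solvent composition from chi_IMID
  and chi_H2O, the remainder being HexA;
* :func:`apply_reaction_extent` -- the stepwise DES -> ionic-liquid
  proton transfer IMID + HexA -> IMID+ + HexA-;
* :func:`regeneration_mass_balance` -- how much HexA must be added to
  dilute chi_IMID back below the phase-separation threshold, and the
  resulting solvent mass growth factor;
* :func:`build_campaign` -- the simulation-campaign planner that
  enumerates (composition, temperature, size, replica[, acceleration])
  grids with deterministic per-cell seeds.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace

from .errors import DomainError

__all__ = [
    "Species",
    "Composition",
    "SimPlan",
    "CampaignManifest",
    "DEFAULT_REGISTRY",
    "ATOMISTIC_MASSES",
    "CG_BEAD_MASSES",
    "make_composition",
    "apply_reaction_extent",
    "regeneration_mass_balance",
    "build_campaign",
    "complete_reaction_boundary",
]

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class Species:
    """A named mixture component.

    Parameters
    ----------
    name : str
        Short identifier, unique within a registry.
    molar_mass : float
        Mass per mole in g/mol; must be positive.
    charge_state : str
        One of ``neutral``, ``cation``, ``anion``.
    role : str
        One of ``solvent``, ``HBA``, ``HBD``, ``oil``, ``water``.
    """

    name: str
    molar_mass: float
    charge_state: str = "neutral"
    role: str = "solvent"

    def __post_init__(self):
        if self.molar_mass <= 0:
            raise DomainError(f"molar_mass of {self.name!r} must be > 0")
        if self.charge_state not in ("neutral", "cation", "anion"):
            raise DomainError(f"unknown charge_state {self.charge_state!r}")
        if self.role not in ("solvent", "HBA", "HBD", "oil", "water"):
            raise DomainError(f"unknown role {self.role!r}")


#: Atomistic molar masses (g/mol) of the component set.
ATOMISTIC_MASSES = {
    "HexA": 116.16,
    "HexA-": 115.15,
    "IMID": 68.08,
    "IMID+": 69.09,
    "water": 18.02,
    "OLEC": 282.47,
    "LINO": 280.45,
}

#: Coarse-grained bead masses (amu) under the standard 72/54/36 amu
#: regular/small/tiny bead convention: HexA maps to one regular plus one
#: small bead, IMID to three tiny beads, water to a single regular bead
#: standing in for four molecules; the charged forms keep the masses of
#: their neutral parents (the reaction is a bead-identity swap).
CG_BEAD_MASSES = {
    "HexA": 126.0,
    "HexA-": 126.0,
    "IMID": 108.0,
    "IMID+": 108.0,
    "water": 72.0,
    "OLEC": 288.0,
    "LINO": 288.0,
}

MASS_MODELS = {"atomistic": ATOMISTIC_MASSES, "cg-bead": CG_BEAD_MASSES}

DEFAULT_REGISTRY = {
    "HexA": Species("HexA", ATOMISTIC_MASSES["HexA"], "neutral", "HBD"),
    "HexA-": Species("HexA-", ATOMISTIC_MASSES["HexA-"], "anion", "HBD"),
    "IMID": Species("IMID", ATOMISTIC_MASSES["IMID"], "neutral", "HBA"),
    "IMID+": Species("IMID+", ATOMISTIC_MASSES["IMID+"], "cation", "HBA"),
    "water": Species("water", ATOMISTIC_MASSES["water"], "neutral", "water"),
    "OLEC": Species("OLEC", ATOMISTIC_MASSES["OLEC"], "neutral", "oil"),
    "LINO": Species("LINO", ATOMISTIC_MASSES["LINO"], "neutral", "oil"),
}


@dataclass(frozen=True)
class Composition:
    """Mole fractions of solvent species plus reaction/oil bookkeeping.

    ``fractions`` maps species name to mole fraction; all fractions are
    non-negative and sum to one within 1e-9.  ``extent_of_reaction`` is
    the fraction xi of IMID converted to IMID+ (with matched HexA ->
    HexA-).  ``oil_loading`` is the oil mass per solvent mass (g/g), or
    ``None`` when no oil phase is present.
    """

    fractions: dict[str, float]
    extent_of_reaction: float = 0.0
    oil_loading: float | None = None

    def __post_init__(self):
        for name, x in self.fractions.items():
            if x < -_FRACTION_TOL:
                raise DomainError(f"fraction of {name!r} is negative: {x}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise DomainError(f"fractions sum to {total}, expected 1")
        if not 0.0 <= self.extent_of_reaction <= 1.0:
            raise DomainError(
                f"extent_of_reaction must be in [0,1], got {self.extent_of_reaction}"
            )
        if self.oil_loading is not None and self.oil_loading < 0:
            raise DomainError("oil_loading must be >= 0")

    def fraction(self, name: str) -> float:
        return self.fractions.get(name, 0.0)

    @property
    def chi_imid_total(self) -> float:
        """Combined imidazole fraction, neutral plus protonated."""
        return self.fraction("IMID") + self.fraction("IMID+")

    def solvent_mass_per_mole(self, masses: dict[str, float] | None = None) -> float:
        """Mean solvent molar mass (g per mole of solvent particles)."""
        masses = ATOMISTIC_MASSES if masses is None else masses
        return sum(x * masses[name] for name, x in self.fractions.items())

    def oil_moles_per_solvent_mole(
        self,
        oil_species: str = "OLEC",
        masses: dict[str, float] | None = None,
    ) -> float:
        """Moles of oil per mole of solvent implied by the oil loading."""
        if self.oil_loading is None:
            return 0.0
        masses = ATOMISTIC_MASSES if masses is None else masses
        return self.oil_loading * self.solvent_mass_per_mole(masses) / masses[oil_species]


def make_composition(
    chi_imid: float,
    chi_water: float = 0.1,
    oil_loading: float | None = None,
) -> Composition:
    """Build an unreacted solvent composition from chi_IMID and chi_H2O.

    The HexA fraction is the simplex remainder ``1 - chi_imid - chi_water``.

    Raises
    ------
    DomainError
        If any fraction falls outside [0, 1] or the pair sums above 1.
    """
    if not 0.0 <= chi_imid <= 1.0:
        raise DomainError(f"chi_imid must be in [0,1], got {chi_imid}")
    if not 0.0 <= chi_water <= 1.0:
        raise DomainError(f"chi_water must be in [0,1], got {chi_water}")
    chi_hexa = 1.0 - chi_imid - chi_water
    if chi_hexa < -_FRACTION_TOL:
        raise DomainError(
            f"chi_HexA would be negative ({chi_hexa:.6g}): "
            f"chi_imid={chi_imid} + chi_water={chi_water} exceeds 1"
        )
    return Composition(
        fractions={"HexA": max(chi_hexa, 0.0), "IMID": chi_imid, "water": chi_water},
        oil_loading=oil_loading,
    )


def apply_reaction_extent(comp: Composition, xi: float) -> Composition:
    """Advance the proton-transfer reaction IMID + HexA -> IMID+ + HexA-.

    The reacted amount is ``min(xi * n_IMID, n_HexA)`` per mole of
    mixture: conversion is mole-for-mole and stops when HexA runs out,
    so compositions with more IMID than HexA retain unreacted IMID even
    at xi = 1.  Total moles are conserved (bead-identity swap, no mass
    or volume change is modelled).
    """
    if not 0.0 <= xi <= 1.0:
        raise DomainError(f"extent of reaction must be in [0,1], got {xi}")
    n_imid = comp.fraction("IMID")
    n_hexa = comp.fraction("HexA")
    reacted = min(xi * n_imid, n_hexa)
    new = dict(comp.fractions)
    new["IMID"] = n_imid - reacted
    new["HexA"] = n_hexa - reacted
    if reacted > 0 or "IMID+" in new or "HexA-" in new:
        new["IMID+"] = comp.fraction("IMID+") + reacted
        new["HexA-"] = comp.fraction("HexA-") + reacted
    return replace(comp, fractions=new, extent_of_reaction=xi)


def complete_reaction_boundary(
    chi_water: float = 0.1, resolution: float = 0.01
) -> float:
    """Largest chi_IMID (on a grid of the given resolution) at which a
    full-extent reaction still converts every IMID molecule.

    With chi_H2O fixed, IMID outnumbers HexA once chi_IMID exceeds the
    equimolar point (1 - chi_water)/2, leaving unreacted excess; the
    boundary is 0.45 for chi_H2O = 0.1.
    """
    n = int(round(1.0 / resolution))
    boundary = None
    for i in range(n + 1):
        chi = i * resolution
        if chi + chi_water > 1.0 + _FRACTION_TOL:
            break
        reacted = apply_reaction_extent(make_composition(chi, chi_water), 1.0)
        if reacted.fraction("IMID") <= _FRACTION_TOL:
            boundary = chi
        else:
            break
    if boundary is None:
        raise DomainError("no complete-reaction composition on the grid")
    return boundary


def regeneration_mass_balance(
    start: Composition,
    target_chi_imid: float,
    mass_model: str = "atomistic",
    include_oil: bool = False,
    oil_species: str = "OLEC",
) -> dict:
    """HexA addition needed to dilute chi_IMID down to a target.

    Solves, per mole of initial solvent, for the added HexA moles x in
    ``chi_target = n_IMID / (1 + x)`` where n_IMID counts both neutral
    and protonated imidazole.  The mass factor is the ratio of final to
    initial solvent mass; oil mass is excluded by default and can be
    folded into both sides with ``include_oil=True``.

    Returns a dict with ``added_moles_HexA`` (per initial solvent mole),
    ``mass_factor``, and the conventions used.
    """
    if mass_model not in MASS_MODELS:
        raise DomainError(f"mass_model must be one of {sorted(MASS_MODELS)}")
    masses = MASS_MODELS[mass_model]
    chi0 = start.chi_imid_total
    if target_chi_imid >= chi0 - _FRACTION_TOL:
        raise DomainError(
            f"target chi_IMID {target_chi_imid} must be below the current {chi0}"
        )
    if target_chi_imid <= 0:
        raise DomainError("target chi_IMID must be positive")
    added = chi0 / target_chi_imid - 1.0
    solvent_mass = start.solvent_mass_per_mole(masses)
    added_mass = added * masses["HexA"]
    base = solvent_mass
    if include_oil and start.oil_loading is not None:
        base = solvent_mass * (1.0 + start.oil_loading)
    mass_factor = (base + added_mass) / base
    return {
        "added_moles_HexA": added,
        "mass_factor": mass_factor,
        "mass_model": mass_model,
        "oil_included": include_oil and start.oil_loading is not None,
        "target_chi_imid": target_chi_imid,
    }


@dataclass(frozen=True)
class SimPlan:
    """Grid specification for a simulation campaign.

    ``per_run_length_ns`` is the production length of one run;
    ``acceleration_rates`` (nm/ps^2) switches the plan to the
    periodic-perturbation viscometry protocol.
    """

    compositions: tuple[float, ...]
    temperatures: tuple[float, ...]
    system_sizes: tuple[int, ...] = (1,)
    replicas: int = 1
    per_run_length_ns: float = 300.0
    acceleration_rates: tuple[float, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "compositions", tuple(self.compositions))
        object.__setattr__(self, "temperatures", tuple(self.temperatures))
        object.__setattr__(self, "system_sizes", tuple(self.system_sizes))
        if self.acceleration_rates is not None:
            object.__setattr__(
                self, "acceleration_rates", tuple(self.acceleration_rates)
            )
        for dim, vals in (
            ("compositions", self.compositions),
            ("temperatures", self.temperatures),
            ("system_sizes", self.system_sizes),
        ):
            if len(vals) == 0:
                raise DomainError(f"empty grid dimension: {dim}")
        if self.acceleration_rates is not None and len(self.acceleration_rates) == 0:
            raise DomainError("empty grid dimension: acceleration_rates")
        if self.replicas < 1:
            raise DomainError("replicas must be >= 1")
        if any(
            b <= a for a, b in zip(self.temperatures[:-1], self.temperatures[1:])
        ):
            raise DomainError("temperatures must be strictly increasing")


@dataclass
class CampaignManifest:
    runs: list[dict] = field(default_factory=list)
    total_runs: int = 0
    total_time_ns: float = 0.0

    @property
    def total_time_us(self) -> float:
        return self.total_time_ns / 1000.0


def _cell_seed(base_seed: int, indices: tuple[int, ...]) -> int:
    """Deterministic per-cell seed from the base seed and cell indices."""
    payload = repr((int(base_seed), tuple(int(i) for i in indices))).encode()
    digest = hashlib.blake2b(payload, digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


def build_campaign(plan: SimPlan, base_seed: int = 0) -> CampaignManifest:
    """Enumerate every cell of the campaign grid.

    Each record carries the cell coordinates and a deterministic seed
    derived from ``base_seed`` and the cell indices, so re-planning with
    the same base seed reproduces every run seed bit-for-bit.
    """
    axes: list[tuple] = [plan.compositions, plan.temperatures, plan.system_sizes]
    names = ["chi_imid", "temperature_K", "n_particles"]
    if plan.acceleration_rates is not None:
        axes.append(plan.acceleration_rates)
        names.append("acceleration_nm_ps2")
    axes.append(tuple(range(plan.replicas)))
    names.append("replica")

    manifest = CampaignManifest()
    for indices in itertools.product(*(range(len(ax)) for ax in axes)):
        record = {name: axes[k][i] for k, (name, i) in enumerate(zip(names, indices))}
        record["seed"] = _cell_seed(base_seed, indices)
        record["length_ns"] = plan.per_run_length_ns
        manifest.runs.append(record)
    manifest.total_runs = len(manifest.runs)
    manifest.total_time_ns = manifest.total_runs * plan.per_run_length_ns
    return manifest
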