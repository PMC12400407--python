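"""Synthetic-data engine: a desk-scale Langevin soft-sphere mixture
simulator plus direct stochastic generators.

The analysis stages in this package (contact miscibility, Einstein
diffusion, periodic-perturbation viscometry, density profiles) were
designed for coarse-grained MD output.  This module produces small
trajectories with the same statistical structure from first principles:

* :func:`run_langevin` integrates a labelled soft-sphere mixture whose
  cross-species attraction can be weakened to drive demixing -- a
  tunable analogue of self- vs cross-affinity in CG force fields;
* :func:`gen_brownian_ensemble` produces random walks with exactly
  known diffusion coefficients, optionally split into compartments with
  distinct mobility and Poisson-rate exchange, for validating the MSD
  and per-phase diffusion estimators;
* :func:`gen_cosine_flow` emits velocity frames with a prescribed
  cos(2*pi*z/Lz) flow profile for the viscometry fits;
* :func:`gen_density_series` emits density-vs-temperature tables with a
  prescribed thermal expansion coefficient.

Units are nm / ps / amu / kJ/mol / K throughout (see
:mod:`desmix.units`); periodic boxes are orthorhombic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compositions import Composition
from .errors import DomainError, IntegrationError, PlacementError
from .units import KB

__all__ = [
    "BoxGeometry",
    "Frame",
    "Trajectory",
    "ToyForceField",
    "build_random_config",
    "build_slab_config",
    "relax_config",
    "run_langevin",
    "gen_brownian_ensemble",
    "gen_cosine_flow",
    "gen_density_series",
]


@dataclass(frozen=True)
class BoxGeometry:
    """Orthorhombic periodic box with edges in nm."""

    lx: float
    ly: float
    lz: float
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self):
        if min(self.lx, self.ly, self.lz) <= 0:
            raise DomainError("box edges must be positive")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz])

    @property
    def volume(self) -> float:
        return self.lx * self.ly * self.lz

    @property
    def elongation(self) -> float:
        """Lz/Lx ratio (3.0 for the viscometry geometry)."""
        return self.lz / self.lx

    @classmethod
    def cubic(cls, edge: float) -> "BoxGeometry":
        return cls(edge, edge, edge)

    @classmethod
    def elongated(cls, edge: float, ratio: float = 3.0) -> "BoxGeometry":
        """1:1:ratio box used for periodic-perturbation viscometry."""
        return cls(edge, edge, edge * ratio)

    def wrap(self, coords: np.ndarray) -> np.ndarray:
        return np.mod(coords, self.lengths)

    def min_image(self, disp: np.ndarray) -> np.ndarray:
        l = self.lengths
        return disp - l * np.round(disp / l)


@dataclass
class Frame:
    """One configuration of a labelled particle system.

    ``coords`` are wrapped into the box; ``unwrapped`` (when present)
    are image-consistent coordinates for displacement analysis.
    ``molecule_ids`` group beads into molecules; with the default
    single-bead molecules they are just 0..N-1.
    """

    coords: np.ndarray
    species: np.ndarray
    box: BoxGeometry
    time: float = 0.0
    velocities: np.ndarray | None = None
    unwrapped: np.ndarray | None = None
    molecule_ids: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.species = np.asarray(self.species)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DomainError("coords must have shape (N, 3)")
        if len(self.species) != len(self.coords):
            raise DomainError("species labels and coords must have equal length")
        if self.molecule_ids is None:
            self.molecule_ids = np.arange(len(self.coords))
        else:
            self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
            if len(self.molecule_ids) != len(self.coords):
                raise DomainError("molecule_ids and coords must have equal length")

    @property
    def n_particles(self) -> int:
        return len(self.coords)

    def species_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(str(s), None)
        return list(seen)


@dataclass
class Trajectory:
    """Time-ordered frames with constant particle count and labels."""

    frames: list[Frame]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.frames:
            raise DomainError("trajectory must contain at least one frame")
        times = self.times
        if np.any(np.diff(times) <= 0) and len(times) > 1:
            raise DomainError("frame times must be strictly increasing")
        n0 = self.frames[0].n_particles
        if any(f.n_particles != n0 for f in self.frames):
            raise DomainError("particle count must be constant across frames")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def species(self) -> np.ndarray:
        return self.frames[0].species

    @property
    def box(self) -> BoxGeometry:
        return self.frames[0].box

    def coords_array(self, unwrapped: bool = False) -> np.ndarray:
        """(n_frames, N, 3) array of coordinates."""
        if unwrapped:
            if any(f.unwrapped is None for f in self.frames):
                raise DomainError("trajectory has no unwrapped coordinates")
            return np.stack([f.unwrapped for f in self.frames])
        return np.stack([f.coords for f in self.frames])


# ---------------------------------------------------------------------------
# configuration builders


def _species_counts(comp: Composition, n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n particles to mole fractions."""
    names = [s for s, x in comp.fractions.items() if x > 0]
    exact = np.array([comp.fractions[s] * n for s in names])
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = n - counts.sum()
    for i in np.argsort(-remainder)[:short]:
        counts[i] += 1
    return dict(zip(names, counts.tolist()))


def _insert_random(
    n: int,
    box: BoxGeometry,
    rng: np.random.Generator,
    min_dist: float,
    region: tuple[int, float, float] | None = None,
    existing: np.ndarray | None = None,
    max_tries_per_particle: int = 200,
) -> np.ndarray:
    """Sequential random insertion with a periodic minimum-distance check.

    ``region`` optionally restricts one axis to [lo, hi).  Uses a coarse
    cell grid so insertion stays O(n).
    """
    lengths = box.lengths
    cell = max(min_dist, 1e-9)
    ncell = np.maximum((lengths / cell).astype(int), 1)
    cell_size = lengths / ncell
    grid: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def key_of(p):
        return tuple((p // cell_size).astype(int) % ncell)

    def ok(p):
        kx, ky, kz = key_of(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    k = ((kx + dx) % ncell[0], (ky + dy) % ncell[1], (kz + dz) % ncell[2])
                    for q in grid.get(k, ()):
                        d = box.min_image(p - q)
                        if d @ d < min_dist * min_dist:
                            return False
        return True

    if existing is not None:
        for q in existing:
            grid.setdefault(key_of(q), []).append(q)

    placed = np.empty((n, 3))
    for i in range(n):
        for _ in range(max_tries_per_particle):
            p = rng.uniform(0.0, lengths)
            if region is not None:
                ax, lo, hi = region
                p[ax] = rng.uniform(lo, hi)
            if ok(p):
                placed[i] = p
                grid.setdefault(key_of(p), []).append(p)
                break
        else:
            raise PlacementError(
                f"could not place particle {i + 1}/{n} at min distance "
                f"{min_dist} nm; density too high"
            )
    return placed


def build_random_config(
    comp: Composition,
    n_particles: int,
    density: float,
    seed: int,
    min_dist: float = 0.25,
    box: BoxGeometry | None = None,
) -> Frame:
    """Random mixed configuration realizing a composition.

    Species counts are apportioned by largest remainder; positions are
    uniform in a cubic box of volume ``n_particles / density`` (unless a
    box is given) subject to a minimum insertion distance.
    """
    if n_particles < 1:
        raise DomainError("n_particles must be >= 1")
    if density <= 0:
        raise DomainError("density must be positive")
    if box is None:
        box = BoxGeometry.cubic((n_particles / density) ** (1.0 / 3.0))
    rng = np.random.default_rng(seed)
    counts = _species_counts(comp, n_particles)
    species = np.concatenate([np.full(c, s) for s, c in counts.items()])
    coords = _insert_random(n_particles, box, rng, min_dist)
    return Frame(
        coords=coords,
        species=species,
        box=box,
        unwrapped=coords.copy(),
        metadata={"composition": dict(comp.fractions), "seed": seed},
    )


def build_slab_config(
    comp: Composition,
    n_particles: int,
    box: BoxGeometry,
    interface_axis: int = 2,
    slab_species: str | None = None,
    slab_fraction: float | None = None,
    outside_fraction: float = 0.0,
    seed: int = 0,
    min_dist: float = 0.25,
) -> Frame:
    """Demixed slab configuration with known ground truth.

    One species is confined to a contiguous slab ``[0, f*L)`` along the
    interface axis (f defaults to its mole fraction); the remaining
    species fill the complement.  ``outside_fraction`` deliberately
    places that share of the slab species outside its slab -- the ground
    truth for pollutant-fraction analyses.  Slab bounds and the per-particle
    in/out truth are stored in frame metadata.
    """
    names = [s for s, x in comp.fractions.items() if x > 0]
    if len(names) < 2:
        raise DomainError("slab construction needs at least two species")
    if slab_species is None:
        slab_species = names[-1]
    if slab_species not in names:
        raise DomainError(f"slab species {slab_species!r} not in composition")
    if not 0.0 <= outside_fraction <= 1.0:
        raise DomainError("outside_fraction must be in [0,1]")
    f = comp.fractions[slab_species] if slab_fraction is None else slab_fraction
    if not 0.0 < f <= 1.0:
        raise DomainError("slab fraction must be in (0,1]")

    rng = np.random.default_rng(seed)
    counts = _species_counts(comp, n_particles)
    l_ax = box.lengths[interface_axis]
    hi = f * l_ax

    coords_list, species_list, inside_list = [], [], []
    n_slab = counts[slab_species]
    n_out = int(round(outside_fraction * n_slab))
    n_in = n_slab - n_out
    placed = None
    if n_in:
        pts = _insert_random(n_in, box, rng, min_dist, region=(interface_axis, 0.0, hi))
        coords_list.append(pts)
        species_list.append(np.full(n_in, slab_species))
        inside_list.append(np.ones(n_in, bool))
        placed = pts
    if n_out:
        if hi >= l_ax:
            raise DomainError("cannot place particles outside a full-box slab")
        pts = _insert_random(
            n_out, box, rng, min_dist, region=(interface_axis, hi, l_ax), existing=placed
        )
        coords_list.append(pts)
        species_list.append(np.full(n_out, slab_species))
        inside_list.append(np.zeros(n_out, bool))
        placed = np.concatenate(coords_list)
    for s in names:
        if s == slab_species:
            continue
        region = (interface_axis, hi, l_ax) if hi < l_ax else None
        pts = _insert_random(counts[s], box, rng, min_dist, region=region, existing=placed)
        coords_list.append(pts)
        species_list.append(np.full(counts[s], s))
        inside_list.append(np.zeros(counts[s], bool))
        placed = np.concatenate(coords_list)

    coords = np.concatenate(coords_list)
    species = np.concatenate(species_list)
    return Frame(
        coords=coords,
        species=species,
        box=box,
        unwrapped=coords.copy(),
        metadata={
            "slab_species": slab_species,
            "slab_axis": interface_axis,
            "slab_bounds": (0.0, hi),
            "inside_slab": np.concatenate(inside_list),
            "outside_fraction": outside_fraction,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# toy force field and integrator


@dataclass
class ToyForceField:
    """Soft repulsive core plus a finite attractive well.

    The pair potential is C1-continuous and bounded:

    * ``U = k_rep/2 (sigma - r)^2 - eps_ij``       for r < sigma
    * ``U = -eps_ij cos^2(pi (r - sigma)/(2 w))``  for sigma <= r < sigma + w
    * ``U = 0``                                    beyond the cutoff sigma + w

    Bounded forces keep large time steps stable while the well depth
    ratio between like and unlike pairs (``kappa``) controls demixing,
    mimicking self- vs cross-affinity in CG force fields.
    """

    species: tuple[str, ...]
    epsilon: np.ndarray
    sigma: float = 0.47
    well_width: float = 0.35
    k_rep: float = 400.0
    masses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        ns = len(self.species)
        if self.epsilon.shape != (ns, ns):
            raise DomainError("epsilon must be (n_species, n_species)")
        if not np.allclose(self.epsilon, self.epsilon.T):
            raise DomainError("epsilon must be symmetric (eps_ij = eps_ji)")
        for s in self.species:
            self.masses.setdefault(s, 72.0)

    @property
    def cutoff(self) -> float:
        return self.sigma + self.well_width

    @classmethod
    def binary(
        cls,
        eps_self: float = 4.0,
        kappa: float = 1.0,
        species: tuple[str, str] = ("A", "B"),
        **kw,
    ) -> "ToyForceField":
        """Symmetric binary mixture; unlike-pair well depth = kappa * eps_self."""
        eps = np.array(
            [[eps_self, kappa * eps_self], [kappa * eps_self, eps_self]]
        )
        return cls(species=species, epsilon=eps, **kw)

    @classmethod
    def from_pairs(cls, pair_eps: dict, default: float = 0.0, **kw) -> "ToyForceField":
        names = sorted({s for pair in pair_eps for s in pair})
        idx = {s: i for i, s in enumerate(names)}
        eps = np.full((len(names), len(names)), default)
        for (a, b), e in pair_eps.items():
            eps[idx[a], idx[b]] = eps[idx[b], idx[a]] = e
        return cls(species=tuple(names), epsilon=eps, **kw)

    def species_index(self, species: np.ndarray) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.species)}
        try:
            return np.array([lookup[str(s)] for s in species])
        except KeyError as e:
            raise DomainError(f"species {e} not covered by the force field") from e

    def mass_array(self, species: np.ndarray) -> np.ndarray:
        return np.array([self.masses[str(s)] for s in species])


def _forces_energy_virial(coords, box: BoxGeometry, sidx, ff: ToyForceField):
    """All-pairs minimum-image forces; suited to desk-scale N."""
    if ff.k_rep == 0.0 and not np.any(ff.epsilon):
        return np.zeros_like(coords), 0.0, 0.0  # ideal gas
    disp = coords[:, None, :] - coords[None, :, :]
    disp = box.min_image(disp)
    r2 = np.einsum("ijk,ijk->ij", disp, disp)
    far = (ff.cutoff + 1.0) ** 2  # finite sentinel for self-distances
    np.fill_diagonal(r2, far)
    r = np.sqrt(r2)

    eps = ff.epsilon[sidx[:, None], sidx[None, :]]
    sigma, w, k = ff.sigma, ff.well_width, ff.k_rep
    fmag = np.zeros_like(r)  # radial force; >0 repulsive
    energy_m = np.zeros_like(r)

    core = r < sigma
    fmag[core] = k * (sigma - r[core])
    energy_m[core] = 0.5 * k * (sigma - r[core]) ** 2 - eps[core]

    shell = (r >= sigma) & (r < sigma + w)
    x = np.pi * (r[shell] - sigma) / (2.0 * w)
    fmag[shell] = -eps[shell] * (np.pi / (2.0 * w)) * np.sin(2.0 * x)
    energy_m[shell] = -eps[shell] * np.cos(x) ** 2

    fvec = (fmag / r)[:, :, None] * disp
    forces = fvec.sum(axis=1)
    energy = 0.5 * energy_m.sum()
    virial = 0.5 * (fmag * r).sum()
    return forces, energy, virial


def relax_config(
    frame: Frame, ff: ToyForceField, n_steps: int = 200, step: float = 0.01
) -> Frame:
    """Steepest-descent-style relaxation to remove insertion overlaps.

    Displaces each particle along the force with a capped step length;
    a convenience mirroring the usual minimize-then-equilibrate routine
    before production runs.
    """
    coords = frame.coords.copy()
    sidx = ff.species_index(frame.species)
    for _ in range(n_steps):
        f, _, _ = _forces_energy_virial(coords, frame.box, sidx, ff)
        norm = np.linalg.norm(f, axis=1, keepdims=True)
        move = np.where(norm > 0, f / np.maximum(norm, 1e-12), 0.0) * np.minimum(
            norm * step, step
        )
        coords = frame.box.wrap(coords + move)
    return Frame(
        coords=coords,
        species=frame.species.copy(),
        box=frame.box,
        time=frame.time,
        unwrapped=coords.copy(),
        molecule_ids=frame.molecule_ids.copy(),
        metadata=dict(frame.metadata),
    )


def run_langevin(
    start: Frame,
    ff: ToyForceField,
    temperature: float = 300.0,
    dt: float = 0.01,
    n_steps: int = 1000,
    sample_every: int = 10,
    thermostat: bool = True,
    gamma: float = 2.0,
    barostat: bool = False,
    pressure: float = 0.06,
    tau_p: float = 5.0,
    compressibility: float = 0.3,
    cosine_acceleration: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """Integrate the soft-sphere mixture with (optionally) a Langevin
    thermostat, a weak-coupling barostat, and a cosine acceleration field.

    Velocity Verlet with the BAOAB splitting of the
    Ornstein-Uhlenbeck friction step; ``thermostat=False`` reduces it to
    plain NVE velocity Verlet.  ``cosine_acceleration`` A adds the
    external field a_x(z) = A cos(2 pi z / Lz) used by the
    periodic-perturbation viscometry protocol.  During cosine-flow runs
    the thermostat acts on peculiar velocities (the instantaneous
    uniform + cosine x-flow modes are projected out before the friction
    step and restored after): a profile-unbiased thermostat.  Naive
    Langevin friction would itself damp the driven mode and the
    apparent viscosity would be dominated by the thermostat drag
    rho*gamma/k^2 instead of momentum transport through the fluid.
    Per-sample temperature,
    potential/kinetic energy and box volume series are returned in
    trajectory metadata; unwrapped coordinates are carried for MSD work.

    Stability requires dt well below the core oscillation period
    2*pi*sqrt(m/k_rep) (~2.7 ps at default mass and stiffness); a
    per-step displacement beyond half the box raises
    :class:`IntegrationError`.
    """
    if dt <= 0 or n_steps < 1:
        raise DomainError("dt must be > 0 and n_steps >= 1")
    box = start.box
    if ff.cutoff > 0.5 * min(box.lengths):
        raise DomainError("force-field cutoff exceeds half the shortest box edge")
    rng = np.random.default_rng(seed)
    sidx = ff.species_index(start.species)
    m = ff.mass_array(start.species)[:, None]
    coords = box.wrap(start.coords.copy())
    unwrapped = (start.unwrapped if start.unwrapped is not None else coords).copy()
    if start.velocities is not None:
        vel = start.velocities.copy()
    else:
        vel = rng.normal(0.0, np.sqrt(KB * temperature / m), size=coords.shape)
        vel -= vel.mean(axis=0)

    c1 = np.exp(-gamma * dt) if thermostat else 1.0
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0))
    sig_v = np.sqrt(KB * temperature / m)
    half_box = 0.5 * min(box.lengths)

    def ext_accel(wrapped):
        if cosine_acceleration == 0.0:
            return 0.0
        a = np.zeros_like(wrapped)
        a[:, 0] = cosine_acceleration * np.cos(2.0 * np.pi * wrapped[:, 2] / box.lz)
        return a

    forces, energy, virial = _forces_energy_virial(coords, box, sidx, ff)
    frames = []
    scalars = {"time": [], "temperature": [], "potential": [], "kinetic": [], "volume": []}

    def record(step):
        t = step * dt
        ke = 0.5 * float(np.sum(m * vel**2))
        frames.append(
            Frame(
                coords=coords.copy(),
                species=start.species.copy(),
                box=box,
                time=t,
                velocities=vel.copy(),
                unwrapped=unwrapped.copy(),
                molecule_ids=start.molecule_ids.copy(),
            )
        )
        scalars["time"].append(t)
        scalars["temperature"].append(2.0 * ke / (3.0 * len(coords) * KB))
        scalars["potential"].append(energy)
        scalars["kinetic"].append(ke)
        scalars["volume"].append(box.volume)

    mw = m[:, 0]

    def streaming_field(wrapped, v):
        """Uniform + cosine x-flow modes (mass-weighted LSQ), as a velocity field."""
        c = np.cos(2.0 * np.pi * wrapped[:, 2] / box.lz)
        sw, swc, swcc = mw.sum(), (mw * c).sum(), (mw * c * c).sum()
        swv, swvc = (mw * v[:, 0]).sum(), (mw * v[:, 0] * c).sum()
        det = sw * swcc - swc * swc
        c0 = (swcc * swv - swc * swvc) / det
        amp = (sw * swvc - swc * swv) / det
        field = np.zeros_like(v)
        field[:, 0] = c0 + amp * c
        return field

    record(0)
    for step in range(1, n_steps + 1):
        accel = forces / m + ext_accel(coords)
        vel = vel + 0.5 * dt * accel
        delta = 0.5 * dt * vel
        if thermostat:
            if cosine_acceleration != 0.0:
                flow = streaming_field(coords, vel)
                pec = vel - flow
                vel = flow + c1 * pec + c2 * sig_v * rng.standard_normal(vel.shape)
            else:
                vel = c1 * vel + c2 * sig_v * rng.standard_normal(vel.shape)
        delta = delta + 0.5 * dt * vel
        if np.max(np.abs(delta)) > half_box:
            raise IntegrationError(
                f"step {step}: displacement exceeded half the box; reduce dt"
            )
        unwrapped = unwrapped + delta
        coords = box.wrap(coords + delta)

        if barostat:
            ke = 0.5 * float(np.sum(m * vel**2))
            p_inst = (2.0 * ke / 3.0 + virial / 3.0) / box.volume
            mu = (1.0 - compressibility * dt / tau_p * (pressure - p_inst)) ** (1.0 / 3.0)
            box = BoxGeometry(box.lx * mu, box.ly * mu, box.lz * mu, box.periodic)
            coords = box.wrap(coords * mu)
            unwrapped = unwrapped * mu
            half_box = 0.5 * min(box.lengths)

        forces, energy, virial = _forces_energy_virial(coords, box, sidx, ff)
        vel = vel + 0.5 * dt * (forces / m + ext_accel(coords))
        if step % sample_every == 0:
            record(step)

    comp = start.metadata.get("composition")
    return Trajectory(
        frames=frames,
        metadata={
            "scalars": {k: np.array(v) for k, v in scalars.items()},
            "temperature_K": temperature,
            "seed": seed,
            "composition": comp,
            "cosine_acceleration": cosine_acceleration,
            "dt": dt,
        },
    )


# ---------------------------------------------------------------------------
# direct stochastic generators


def gen_brownian_ensemble(
    n_walkers: int,
    d_true: float | dict[str, float],
    dt: float,
    n_steps: int,
    box: BoxGeometry,
    seed: int = 0,
    compartments: tuple[float, float] | None = None,
    exchange_rate: float = 0.0,
    sample_every: int = 1,
) -> Trajectory:
    """Random walks with exactly known diffusion coefficients.

    ``d_true`` is either one coefficient (nm^2/ps) for a single species
    "A", or a map species -> D with walkers split evenly.  Displacements
    are Gaussian with per-axis variance 2*D*dt, so the MSD estimators
    have a closed-form ground truth.

    Compartment mode (``compartments=(D0, D1)``) instead tags each
    walker with a phase label that sets its local mobility; labels flip
    at the Poisson rate ``exchange_rate`` (per ps).  Rate zero makes the
    compartments impermeable.  The per-frame label history is stored in
    ``metadata["labels"]`` as ground truth for per-phase analyses.
    """
    if n_walkers < 1 or n_steps < 1:
        raise DomainError("need at least one walker and one step")
    rng = np.random.default_rng(seed)

    if compartments is not None:
        d0, d1 = compartments
        if d0 < 0 or d1 < 0:
            raise DomainError("diffusion coefficients must be >= 0")
        species = np.full(n_walkers, "A")
        labels = (np.arange(n_walkers) % 2).astype(np.int8)
        d_map = np.array([d0, d1])
    else:
        if np.isscalar(d_true):
            d_true = {"A": float(d_true)}
        for s, d in d_true.items():
            if d < 0:
                raise DomainError(f"negative D for species {s!r}")
        names = list(d_true)
        splits = np.array_split(np.arange(n_walkers), len(names))
        species = np.empty(n_walkers, dtype=object)
        d_per = np.empty(n_walkers)
        for name, idx in zip(names, splits):
            species[idx] = name
            d_per[idx] = d_true[name]
        species = species.astype(str)
        labels = None

    pos = rng.uniform(0.0, box.lengths, size=(n_walkers, 3))
    unwrapped = pos.copy()
    frames = [
        Frame(
            coords=pos.copy(),
            species=species.copy(),
            box=box,
            time=0.0,
            unwrapped=unwrapped.copy(),
        )
    ]
    label_hist = [labels.copy()] if labels is not None else None
    p_flip = 1.0 - np.exp(-exchange_rate * dt) if exchange_rate > 0 else 0.0

    for step in range(1, n_steps + 1):
        if compartments is not None:
            sigma = np.sqrt(2.0 * d_map[labels] * dt)[:, None]
        else:
            sigma = np.sqrt(2.0 * d_per * dt)[:, None]
        unwrapped = unwrapped + rng.normal(0.0, 1.0, size=(n_walkers, 3)) * sigma
        pos = box.wrap(unwrapped)
        if compartments is not None and p_flip > 0:
            flip = rng.random(n_walkers) < p_flip
            labels = np.where(flip, 1 - labels, labels).astype(np.int8)
        if step % sample_every == 0:
            frames.append(
                Frame(
                    coords=pos.copy(),
                    species=species.copy(),
                    box=box,
                    time=step * dt,
                    unwrapped=unwrapped.copy(),
                )
            )
            if label_hist is not None:
                label_hist.append(labels.copy())

    meta = {"d_true": d_true if compartments is None else compartments, "seed": seed}
    if label_hist is not None:
        meta["labels"] = np.stack(label_hist)
        meta["exchange_rate"] = exchange_rate
    return Trajectory(frames=frames, metadata=meta)


def gen_cosine_flow(
    n_particles: int,
    box: BoxGeometry,
    amplitude: float,
    noise_sigma: float = 0.0,
    n_frames: int = 1,
    mode: int = 1,
    seed: int = 0,
    mass: float = 72.0,
) -> Trajectory:
    """Frames with a steady cosine velocity profile u_x(z) = V cos(m k z).

    Positions are uniform; x-velocities follow the profile plus Gaussian
    thermal noise.  ``mode`` > 1 generates an orthogonal higher
    harmonic, useful for checking mode selectivity of the profile fit.
    """
    if amplitude < 0 or noise_sigma < 0:
        raise DomainError("amplitude and noise must be >= 0")
    rng = np.random.default_rng(seed)
    k = 2.0 * np.pi * mode / box.lz
    species = np.full(n_particles, "A")
    frames = []
    for i in range(n_frames):
        pos = rng.uniform(0.0, box.lengths, size=(n_particles, 3))
        vel = rng.normal(0.0, noise_sigma, size=(n_particles, 3))
        vel[:, 0] += amplitude * np.cos(k * pos[:, 2])
        frames.append(
            Frame(coords=pos, species=species.copy(), box=box, time=float(i), velocities=vel)
        )
    return Trajectory(
        frames=frames,
        metadata={"amplitude": amplitude, "mode": mode, "seed": seed, "mass": mass},
    )


def gen_density_series(
    alpha_true: float,
    rho0: float,
    temperatures,
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """Density-vs-temperature table with a known expansion coefficient.

    rho(T) = rho0 * exp(-alpha_true * T), optionally with multiplicative
    Gaussian noise of relative width ``noise_sigma``.  Returns a pandas
    DataFrame with columns T, rho.
    """
    import pandas as pd

    temperatures = np.asarray(temperatures, dtype=float)
    if temperatures.size == 0:
        raise DomainError("temperature grid must be non-empty")
    rho = rho0 * np.exp(-alpha_true * temperatures)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        rho = rho * (1.0 + rng.normal(0.0, noise_sigma, size=rho.shape))
    return pd.DataFrame({"T": temperatures, "rho": rho})
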