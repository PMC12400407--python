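"""File formats, configuration and pipeline plumbing.

Conventions: coordinates are nm and times ps everywhere, particle
indices are 0-based, bins are half-open ``[lo, hi)``.  Single
configurations travel as GRO; trajectories as XYZ or extended-XYZ
(with box, time and optional velocity columns in the comment-line
``Lattice``/``Properties`` dialect).  Results are CSV/JSON; run
configuration is YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import DomainError, ParseError
from .toysim import BoxGeometry, Frame, Trajectory

__all__ = [
    "read_structure",
    "write_structure",
    "read_gro",
    "write_gro",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "RunConfig",
    "load_config",
    "save_config",
    "ResultRecord",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# GRO


def write_gro(frame: Frame, path, title: str = "desmix configuration") -> None:
    """Write a single frame in GROMACS GRO format (nm, nm/ps).

    Molecule ids map to residue numbers and species names to residue
    names (truncated to 5 characters).  Velocities are written when the
    frame has them.
    """
    path = Path(path)
    coords = frame.box.wrap(frame.coords)
    has_vel = frame.velocities is not None
    lines = [title, f"{frame.n_particles:5d}"]
    for i in range(frame.n_particles):
        res = int(frame.molecule_ids[i]) + 1
        name = str(frame.species[i])[:5]
        x, y, z = coords[i]
        line = f"{res % 100000:5d}{name:<5s}{name:>5s}{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
        if has_vel:
            vx, vy, vz = frame.velocities[i]
            line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
        lines.append(line)
    lx, ly, lz = frame.box.lengths
    lines.append(f"{lx:10.5f}{ly:10.5f}{lz:10.5f}")
    path.write_text("\n".join(lines) + "\n")


def read_gro(path) -> Frame:
    """Read a GRO configuration through MDAnalysis.

    MDAnalysis works in Angstrom internally; coordinates and velocities
    are converted back to nm and nm/ps.  Species come from residue
    names, molecule ids from residue numbering (made 0-based).
    """
    import warnings

    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
            coords = u.atoms.positions / 10.0
            species = np.array([str(r) for r in u.atoms.resnames])
            mol_ids = u.atoms.resids.astype(int) - 1
            box_dims = u.dimensions
            vel = None
            if u.trajectory.ts.has_velocities:
                vel = u.atoms.velocities / 10.0
    except (ValueError, OSError, EOFError, IndexError) as e:
        raise ParseError(f"malformed GRO file {path}: {e}") from e
    if box_dims is None or box_dims[0] == 0:
        raise ParseError(f"GRO file {path} has no box line")
    box = BoxGeometry(*(float(x) / 10.0 for x in box_dims[:3]))
    return Frame(coords=coords.astype(float), species=species, box=box,
                 velocities=None if vel is None else vel.astype(float),
                 molecule_ids=mol_ids)


# ---------------------------------------------------------------------------
# XYZ / extended XYZ


def write_xyz_trajectory(traj: Trajectory, path, extended: bool = True) -> None:
    """Write a trajectory as (extended) XYZ, coordinates in nm.

    The extended dialect stores the box as ``Lattice="..."``, the frame
    time as ``Time=``, and appends velocity columns when present.
    Plain XYZ keeps only species and positions.
    """
    path = Path(path)
    out = []
    for f in traj.frames:
        out.append(str(f.n_particles))
        coords = f.box.wrap(f.coords)
        has_vel = extended and f.velocities is not None
        if extended:
            lx, ly, lz = f.box.lengths
            props = "species:S:1:pos:R:3" + (":vel:R:3" if has_vel else "")
            out.append(
                f'Lattice="{lx:.8g} 0 0 0 {ly:.8g} 0 0 0 {lz:.8g}" '
                f"Properties={props} Time={f.time:.8g}"
            )
        else:
            out.append(f"t={f.time:.8g}")
        for i in range(f.n_particles):
            x, y, z = coords[i]
            line = f"{str(f.species[i]):<8s} {x:15.8f} {y:15.8f} {z:15.8f}"
            if has_vel:
                vx, vy, vz = f.velocities[i]
                line += f" {vx:15.8f} {vy:15.8f} {vz:15.8f}"
            out.append(line)
    path.write_text("\n".join(out) + "\n")


def _parse_lattice(comment: str):
    box = time = None
    has_vel = False
    if 'Lattice="' in comment:
        try:
            lat = comment.split('Lattice="', 1)[1].split('"', 1)[0]
            vals = [float(v) for v in lat.split()]
            box = BoxGeometry(vals[0], vals[4], vals[8])
        except (IndexError, ValueError) as e:
            raise ParseError(f"bad Lattice entry: {comment!r}") from e
    if "Time=" in comment:
        try:
            time = float(comment.split("Time=", 1)[1].split()[0])
        except (IndexError, ValueError) as e:
            raise ParseError(f"bad Time entry: {comment!r}") from e
    if "Properties=" in comment:
        has_vel = ":vel:R:3" in comment.split("Properties=", 1)[1].split()[0]
    return box, time, has_vel


def read_xyz_trajectory(path, box: BoxGeometry | None = None,
                        molecule_ids: np.ndarray | None = None) -> Trajectory:
    """Read an (extended) XYZ trajectory written by this package.

    Plain XYZ carries no box; supply one via ``box``.  Molecule ids
    default to one molecule per particle unless a sidecar map is given.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    t_fallback = 0.0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError("expected atom count", line=i + 1) from None
        if i + 1 + n >= len(lines) + 1 and i + 1 + n > len(lines):
            raise ParseError(
                f"truncated frame: expected {n} atom lines", line=min(len(lines), i + 2)
            )
        fbox, ftime, has_vel = _parse_lattice(lines[i + 1]) if i + 1 < len(lines) else (None, None, False)
        use_box = fbox or box
        if use_box is None:
            raise ParseError("no box in file and none supplied", line=i + 2)
        species, coords, vels = [], [], []
        for j in range(n):
            ln = i + 2 + j
            if ln >= len(lines):
                raise ParseError("truncated frame", line=len(lines))
            parts = lines[ln].split()
            want = 7 if has_vel else 4
            if len(parts) < want:
                raise ParseError(
                    f"atom line has {len(parts)} fields, expected >= {want}", line=ln + 1
                )
            try:
                species.append(parts[0])
                coords.append([float(v) for v in parts[1:4]])
                if has_vel:
                    vels.append([float(v) for v in parts[4:7]])
            except ValueError:
                raise ParseError("non-numeric coordinate", line=ln + 1) from None
        frames.append(
            Frame(
                coords=np.array(coords),
                species=np.array(species),
                box=use_box,
                time=ftime if ftime is not None else t_fallback,
                velocities=np.array(vels) if vels else None,
                molecule_ids=molecule_ids,
            )
        )
        t_fallback = frames[-1].time + 1.0
        i += 2 + n
    if not frames:
        raise ParseError(f"no frames found in {path}")
    return Trajectory(frames=frames)


def write_structure(frame: Frame, path, fmt: str | None = None) -> None:
    """Write a single frame; format from extension (.gro/.xyz) or ``fmt``."""
    fmt = fmt or Path(path).suffix.lstrip(".").lower()
    if fmt == "gro":
        write_gro(frame, path)
    elif fmt in ("xyz", "extxyz"):
        write_xyz_trajectory(Trajectory(frames=[frame]), path, extended=True)
    else:
        raise DomainError(f"unsupported structure format {fmt!r}")


def read_structure(path, fmt: str | None = None, box: BoxGeometry | None = None) -> Frame:
    """Read a single configuration (GRO or XYZ dialects) as a Frame."""
    fmt = fmt or Path(path).suffix.lstrip(".").lower()
    if fmt == "gro":
        return read_gro(path)
    if fmt in ("xyz", "extxyz"):
        return read_xyz_trajectory(path, box=box).frames[0]
    raise DomainError(f"unsupported structure format {fmt!r}")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Validated analysis/pipeline configuration.

    ``species`` maps name -> {molar_mass, charge_state, role};
    ``parameters`` holds analysis defaults (cutoffs in nm, windows as
    fractions); ``seed`` feeds every stochastic stage.
    """

    species: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    _BOUNDS = {
        "contact_cutoff": (0.0, 10.0),
        "phase_radius": (0.0, 10.0),
        "equilibration_discard": (0.0, 1.0),
        "chi_water": (0.0, 1.0),
    }

    def __post_init__(self):
        for name, spec in self.species.items():
            mm = spec.get("molar_mass")
            if mm is None or mm <= 0:
                raise DomainError(f"species {name!r} needs a positive molar_mass")
        for key, (lo, hi) in self._BOUNDS.items():
            if key in self.parameters and not lo <= self.parameters[key] <= hi:
                raise DomainError(f"parameter {key}={self.parameters[key]} outside [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "parameters": self.parameters,
            "paths": self.paths,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            species=d.get("species", {}),
            parameters=d.get("parameters", {}),
            paths=d.get("paths", {}),
            seed=int(d.get("seed", 0)),
            output_dir=d.get("output_dir", "."),
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# result records and manifests


@dataclass
class ResultRecord:
    """Provenance of one pipeline stage (deterministic given inputs+seed)."""

    stage: str
    parameters: dict
    outputs: list[str]
    input_hash: str = ""
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(
            {
                "stage": self.stage,
                "parameters": self.parameters,
                "outputs": self.outputs,
                "input_hash": self.input_hash,
                "version": self.version,
            },
            sort_keys=True,
        )


def hash_inputs(*payloads) -> str:
    h = hashlib.blake2b(digest_size=16)
    for p in payloads:
        h.update(repr(p).encode())
    return h.hexdigest()


def write_manifest(manifest, jsonl_path, csv_path=None) -> None:
    """Emit a campaign manifest as JSON lines and optionally CSV."""
    import pandas as pd

    with open(jsonl_path, "w") as fh:
        for rec in manifest.runs:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    if csv_path is not None:
        pd.DataFrame(manifest.runs).to_csv(csv_path, index=False)
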