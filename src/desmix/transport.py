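"""Mean-squared-displacement transport analysis.

Diffusion coefficients follow from the Einstein relation: in three
dimensions the long-time MSD of species A grows as ``6 D_A t``, so D is
one sixth of the slope of a linear fit over an intermediate lag window.
Finite simulation boxes depress D; measured values at several particle
counts N are extrapolated linearly in N^(-1/3) to the infinite-system
intercept.

Per-phase diffusion assigns each molecule to a HexA-rich or IMID-rich
phase from the local molecular composition within a 1.2 nm radius and
groups MSD contributions by the phase a molecule occupied at the lag
origin.  Grouping by phase of origin -- rather than by continuous
residence -- avoids survivor bias: a molecule keeps contributing its
full displacement history to its origin phase even after it migrates,
so fast movers that leave a phase are not silently discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DomainError,
    FitError,
    InsufficientDataError,
    UnwrapError,
)
from .toysim import Frame, Trajectory

__all__ = [
    "MSDSeries",
    "DiffusionResult",
    "FiniteSizeFit",
    "PhaseAssignment",
    "compute_msd",
    "einstein_diffusion",
    "finite_size_extrapolate",
    "classify_local_phase",
    "per_phase_diffusion",
    "unwrap_trajectory",
    "aggregate_replicas",
]

#: nm^2/ps expressed in 1e-5 cm^2/s (1 nm^2/ps = 1e-2 cm^2/s).
NM2_PS_TO_1E5_CM2_S = 1.0e3


@dataclass
class MSDSeries:
    """Multi-origin MSD versus lag time for one particle selection.

    ``per_particle`` (n_lags, N), when present, holds each particle's
    own origin-averaged MSD; the spread across particles is what makes
    the diffusion standard error honest, because MSD values at
    different lags share walkers and are strongly correlated.
    """

    lags: np.ndarray  # ps, increasing, lags[0] corresponds to smallest nonzero lag
    msd: np.ndarray  # nm^2
    n_pairs: np.ndarray  # origin-particle pairs per lag
    species: str | None = None
    per_particle: np.ndarray | None = None

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        if np.any(np.diff(self.lags) <= 0):
            raise DomainError("lag grid must be strictly increasing")
        if np.any(self.msd < -1e-12):
            raise DomainError("MSD must be non-negative")


@dataclass
class DiffusionResult:
    """Einstein-relation diffusion coefficient with fit diagnostics."""

    d: float  # nm^2/ps
    d_se: float
    window: tuple[float, float]  # lag range used (ps)
    r_squared: float
    exponent: float  # log-log MSD slope over the window; ~1 for diffusive
    species: str | None = None
    phase: str | None = None
    n_points: int = 0

    @property
    def d_1e5_cm2_s(self) -> float:
        """D in the conventional 1e-5 cm^2/s units."""
        return self.d * NM2_PS_TO_1E5_CM2_S

    @property
    def is_linear(self) -> bool:
        """True when the MSD grows diffusively (exponent within 0.1 of 1)."""
        return abs(self.exponent - 1.0) <= 0.1


@dataclass
class FiniteSizeFit:
    """Linear extrapolation of D versus N^(-1/3) to infinite size."""

    slope: float
    d_infinity: float
    d_infinity_se: float
    points: list = field(default_factory=list)


def unwrap_trajectory(traj: Trajectory) -> np.ndarray:
    """Reconstruct image-consistent coordinates from wrapped frames.

    Applies the minimum-image convention to frame-to-frame
    displacements, which is exact while true displacements stay below
    half the box per frame interval.  Displacements at (or suspiciously
    near) the half-box ambiguity limit raise :class:`UnwrapError`.
    """
    wrapped = traj.coords_array(unwrapped=False)
    box = traj.box
    out = np.empty_like(wrapped)
    out[0] = wrapped[0]
    for i in range(1, len(wrapped)):
        d = box.min_image(wrapped[i] - wrapped[i - 1])
        if np.any(np.abs(d) > 0.49 * box.lengths):
            raise UnwrapError(
                f"frame {i}: inter-frame displacement within 2% of the half-box "
                "ambiguity limit; store unwrapped coordinates or save more often"
            )
        out[i] = out[i - 1] + d
    return out


def _unwrapped_coords(traj: Trajectory) -> np.ndarray:
    try:
        return traj.coords_array(unwrapped=True)
    except DomainError:
        return unwrap_trajectory(traj)


def compute_msd(
    traj: Trajectory,
    species: str | None = None,
    origin_stride: int = 1,
    max_lag_frames: int | None = None,
) -> MSDSeries:
    """Multi-origin MSD for one species (or the whole population).

    Origins are taken every ``origin_stride`` frames; every lag up to
    ``max_lag_frames`` (default: the full frame range) is evaluated.
    Requires uniform frame spacing and unwrapped coordinates (stored or
    reconstructible).
    """
    if origin_stride < 1:
        raise DomainError("origin_stride must be >= 1")
    times = traj.times
    if len(times) < 2:
        raise InsufficientDataError("need at least two frames for an MSD")
    spacing = np.diff(times)
    if not np.allclose(spacing, spacing[0], rtol=1e-6):
        raise DomainError("MSD requires uniform frame spacing")
    coords = _unwrapped_coords(traj)
    if species is not None:
        sel = traj.species.astype(str) == species
        if not np.any(sel):
            raise DomainError(f"no particles of species {species!r}")
        coords = coords[:, sel]
    n_frames = len(coords)
    max_lag = n_frames - 1 if max_lag_frames is None else min(max_lag_frames, n_frames - 1)

    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    n_pairs = np.empty(len(lags), dtype=int)
    per_particle = np.empty((len(lags), coords.shape[1]))
    for k, lag in enumerate(lags):
        origins = np.arange(0, n_frames - lag, origin_stride)
        disp = coords[origins + lag] - coords[origins]
        sq = np.einsum("onk,onk->on", disp, disp)
        per_particle[k] = sq.mean(axis=0)
        msd[k] = sq.mean()
        n_pairs[k] = sq.size
    return MSDSeries(
        lags=lags * spacing[0], msd=msd, n_pairs=n_pairs, species=species,
        per_particle=per_particle,
    )


def _weighted_linfit(x, y, w):
    """Weighted least squares y = a + b x; returns a, b, se_a, se_b, r2."""
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 0:
        raise FitError("degenerate abscissa in linear fit")
    b = (w * (x - xm) * (y - ym)).sum() / sxx
    a = ym - b * xm
    resid = y - (a + b * x)
    dof = max(len(x) - 2, 1)
    s2 = (w * resid**2).sum() / dof
    se_b = np.sqrt(s2 / sxx)
    se_a = np.sqrt(s2 * (1.0 / sw + xm**2 / sxx))
    syy = (w * (y - ym) ** 2).sum()
    r2 = 1.0 - (w * resid**2).sum() / syy if syy > 0 else 1.0
    return a, b, se_a, se_b, r2


def einstein_diffusion(
    msd: MSDSeries,
    window: tuple[float, float] = (0.1, 0.5),
    window_is_fraction: bool = True,
) -> DiffusionResult:
    """Diffusion coefficient D = slope/6 from a windowed linear MSD fit.

    ``window`` selects the lag range, by default the 10-50% span of the
    maximum lag -- late enough to escape the short-time ballistic/cage
    regime, early enough to keep origin statistics.  The fit is weighted
    by per-lag pair counts and allows an additive intercept.  The
    ``exponent`` diagnostic (log-log slope) flags non-diffusive growth.

    When the series carries per-particle MSDs the standard error comes
    from the spread of per-particle slopes (particles are the closest
    thing to independent samples); residual-based fit errors would be
    badly optimistic because MSD values at different lags share
    walkers.
    """
    lo, hi = window
    if window_is_fraction:
        lo, hi = lo * msd.lags[-1], hi * msd.lags[-1]
    if hi <= lo:
        raise FitError("empty fit window")
    mask = (msd.lags >= lo) & (msd.lags <= hi)
    if mask.sum() < 2:
        raise FitError("fewer than 2 lags inside the fit window")
    x, y, w = msd.lags[mask], msd.msd[mask], msd.n_pairs[mask].astype(float)
    _, slope, _, se_slope, r2 = _weighted_linfit(x, y, w)
    if msd.per_particle is not None and msd.per_particle.shape[1] > 1:
        pp = msd.per_particle[mask]
        full = ~np.any(np.isnan(pp), axis=0)
        if full.sum() > 1:
            sw = w.sum()
            xm = (w * x).sum() / sw
            coef = w * (x - xm) / (w * (x - xm) ** 2).sum()
            slopes = coef @ pp[:, full]
            se_slope = slopes.std(ddof=1) / np.sqrt(full.sum())
    pos = y > 0
    if pos.sum() >= 2:
        _, expo, _, _, _ = _weighted_linfit(np.log(x[pos]), np.log(y[pos]), w[pos])
    else:
        expo = 0.0
    return DiffusionResult(
        d=slope / 6.0,
        d_se=se_slope / 6.0,
        window=(float(lo), float(hi)),
        r_squared=float(r2),
        exponent=float(expo),
        species=msd.species,
        n_points=int(mask.sum()),
    )


def finite_size_extrapolate(points) -> FiniteSizeFit:
    """Extrapolate D(N) to infinite system size.

    ``points`` is a sequence of (N, D) or (N, D, SE) tuples.  Fits D
    against N^(-1/3) by (SE-weighted when given) least squares; the
    intercept estimates the infinite-size coefficient with a propagated
    standard error.
    """
    pts = [tuple(p) for p in points]
    ns = np.array([p[0] for p in pts], dtype=float)
    if len(np.unique(ns)) < 2:
        raise FitError("finite-size extrapolation needs >= 2 distinct system sizes")
    d = np.array([p[1] for p in pts], dtype=float)
    se = np.array([p[2] if len(p) > 2 else np.nan for p in pts], dtype=float)
    x = ns ** (-1.0 / 3.0)
    if np.all(np.isfinite(se)) and np.all(se > 0):
        w = 1.0 / se**2
    else:
        w = np.ones_like(d)
    if len(pts) == 2:
        # exact line through two points; SE propagated from input errors only
        slope = (d[1] - d[0]) / (x[1] - x[0])
        intercept = d[0] - slope * x[0]
        if np.all(np.isfinite(se)):
            c0 = x[1] / (x[1] - x[0])
            c1 = -x[0] / (x[1] - x[0])
            se_int = float(np.sqrt((c0 * se[0]) ** 2 + (c1 * se[1]) ** 2))
        else:
            se_int = float("nan")
        return FiniteSizeFit(slope=float(slope), d_infinity=float(intercept),
                             d_infinity_se=se_int, points=pts)
    a, b, se_a, _, _ = _weighted_linfit(x, d, w)
    return FiniteSizeFit(slope=float(b), d_infinity=float(a), d_infinity_se=float(se_a), points=pts)


def aggregate_replicas(results: list[DiffusionResult]) -> DiffusionResult:
    """Combine replica diffusion estimates.

    The combined D is the mean of the replica values; the combined
    standard error averages the replica error variances
    (sqrt(mean(SE_i^2))) rather than shrinking with replica count --
    the convention treats each replica's SE as an estimate of the same
    single-run uncertainty.
    """
    if not results:
        raise InsufficientDataError("no replica results to aggregate")
    d = float(np.mean([r.d for r in results]))
    se = float(np.sqrt(np.mean([r.d_se**2 for r in results])))
    return DiffusionResult(
        d=d,
        d_se=se,
        window=results[0].window,
        r_squared=float(np.mean([r.r_squared for r in results])),
        exponent=float(np.mean([r.exponent for r in results])),
        species=results[0].species,
        phase=results[0].phase,
        n_points=sum(r.n_points for r in results),
    )


# ---------------------------------------------------------------------------
# per-phase analysis


@dataclass
class PhaseAssignment:
    """Per-molecule phase labels at one reference frame."""

    labels: np.ndarray  # e.g. "HexA-rich" | "IMID-rich" | "interfacial"
    molecule_ids: np.ndarray
    radius: float
    threshold: float
    time: float = 0.0
    metadata: dict = field(default_factory=dict)


def _molecule_table(frame: Frame):
    """Molecule ids, centers (periodic circular mean of beads) and species."""
    mol = frame.molecule_ids
    uniq, first_idx, inverse = np.unique(mol, return_index=True, return_inverse=True)
    species = frame.species.astype(str)[first_idx]
    coords = frame.box.wrap(frame.coords)
    if len(uniq) == len(mol):
        centers = coords
    else:
        lengths = frame.box.lengths
        theta = 2.0 * np.pi * coords / lengths
        z = np.exp(1j * theta)
        sums = np.zeros((len(uniq), 3), dtype=complex)
        np.add.at(sums, inverse, z)
        centers = (np.angle(sums) % (2.0 * np.pi)) * lengths / (2.0 * np.pi)
    return uniq, centers, species


def classify_local_phase(
    frame: Frame,
    radius: float = 1.2,
    threshold: float = 0.5,
    phase_species: tuple[str, ...] = ("HexA", "IMID"),
    exclude: tuple[str, ...] = ("water",),
) -> PhaseAssignment:
    """Label every molecule by its local molecular composition.

    Neighbours are molecules whose centers lie within ``radius`` nm
    (default 1.2).  Among non-excluded neighbour species, the majority
    species claims the molecule when its share exceeds ``threshold``
    (strictly, so an exact tie is ambiguous); otherwise, and for empty
    neighbourhoods, the molecule is ``interfacial``.  Water is excluded
    from the vote by default: the phases of interest are HexA-rich vs
    IMID-rich.
    """
    if radius <= 0 or radius > 0.5 * min(frame.box.lengths):
        raise DomainError("radius must be in (0, half shortest box edge]")
    mol_ids, centers, mol_species = _molecule_table(frame)
    lengths = frame.box.lengths
    pts = np.where(centers >= lengths, 0.0, centers)
    tree = cKDTree(pts, boxsize=lengths)
    neighbor_lists = tree.query_ball_point(pts, r=radius)

    votes = [s for s in phase_species if s not in exclude]
    sp_index = {s: i for i, s in enumerate(votes)}
    labels = np.empty(len(mol_ids), dtype=object)
    for i, neigh in enumerate(neighbor_lists):
        counts = np.zeros(len(votes), dtype=int)
        for j in neigh:
            if j == i:
                continue
            k = sp_index.get(mol_species[j])
            if k is not None:
                counts[k] += 1
        total = counts.sum()
        if total == 0:
            labels[i] = "interfacial"
            continue
        order = np.argsort(-counts)
        top = order[0]
        if len(votes) > 1 and counts[top] == counts[order[1]]:
            labels[i] = "interfacial"
        elif counts[top] / total > threshold:
            labels[i] = f"{votes[top]}-rich"
        else:
            labels[i] = "interfacial"
    return PhaseAssignment(
        labels=labels.astype(str),
        molecule_ids=mol_ids,
        radius=radius,
        threshold=threshold,
        time=frame.time,
        metadata={
            "phase_species": votes,
            "excluded_species": list(exclude),
            "rule": "majority share strictly above threshold of non-excluded "
            "neighbours; ties and empty neighbourhoods are interfacial",
        },
    )


def per_phase_diffusion(
    traj: Trajectory,
    species: str | None = None,
    labels: np.ndarray | None = None,
    origin_stride: int = 1,
    window: tuple[float, float] = (0.1, 0.5),
    survivor_biased: bool = False,
    radius: float = 1.2,
    threshold: float = 0.5,
    phase_species: tuple[str, ...] = ("HexA", "IMID"),
    exclude: tuple[str, ...] = ("water",),
) -> dict[str, tuple[MSDSeries, DiffusionResult]]:
    """Diffusion coefficients resolved by phase of origin.

    For each origin frame, molecules are grouped by the phase they
    occupy *at that origin* and contribute their full subsequent
    squared displacements to that group, whatever phases they later
    visit -- the survivor-bias-free convention.  ``labels`` may supply
    per-frame phase labels (shape (n_frames, N), e.g. generator ground
    truth); otherwise :func:`classify_local_phase` is applied per frame.

    ``survivor_biased=True`` switches to the biased convention (a
    molecule contributes to a lag only while it has stayed in its
    origin phase continuously), provided for demonstrating the bias --
    not for production analysis.

    Returns ``{phase: (MSDSeries, DiffusionResult)}``; phases with no
    members at any origin raise :class:`InsufficientDataError`.
    """
    times = traj.times
    spacing = np.diff(times)
    if len(times) < 2 or not np.allclose(spacing, spacing[0], rtol=1e-6):
        raise DomainError("per-phase MSD requires >= 2 uniformly spaced frames")
    coords = _unwrapped_coords(traj)

    if labels is None:
        lab = np.stack(
            [
                classify_local_phase(
                    f, radius=radius, threshold=threshold,
                    phase_species=phase_species, exclude=exclude,
                ).labels
                for f in traj.frames
            ]
        )
    else:
        lab = np.asarray(labels)
        if lab.shape[0] != len(traj.frames) or lab.shape[1] != traj.frames[0].n_particles:
            raise DomainError("labels must have shape (n_frames, n_molecules)")

    if species is not None:
        sel = traj.species.astype(str) == species
        coords = coords[:, sel]
        lab = lab[:, sel]

    n_frames, n_mol = coords.shape[:2]
    phases = sorted({str(x) for x in lab.ravel()})
    lags = np.arange(1, n_frames)
    sums_pm = {p: np.zeros((len(lags), n_mol)) for p in phases}
    counts_pm = {p: np.zeros((len(lags), n_mol), dtype=int) for p in phases}

    for k, lag in enumerate(lags):
        origins = np.arange(0, n_frames - lag, origin_stride)
        disp = coords[origins + lag] - coords[origins]
        sq = np.einsum("onk,onk->on", disp, disp)
        origin_lab = lab[origins]
        if survivor_biased:
            stayed = np.ones_like(sq, dtype=bool)
            for o_i, o in enumerate(origins):
                seg = lab[o : o + lag + 1]
                stayed[o_i] = np.all(seg == seg[0], axis=0)
        for p in phases:
            member = origin_lab == p
            if survivor_biased:
                member = member & stayed
            counts_pm[p][k] = member.sum(axis=0)
            sums_pm[p][k] = np.where(member, sq, 0.0).sum(axis=0)

    out = {}
    for p in phases:
        counts = counts_pm[p].sum(axis=1)
        if counts.sum() == 0:
            raise InsufficientDataError(f"phase {p!r} has no members at any origin")
        valid = counts > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            per_particle = np.where(
                counts_pm[p][valid] > 0,
                sums_pm[p][valid] / np.maximum(counts_pm[p][valid], 1),
                np.nan,
            )
        msd = MSDSeries(
            lags=lags[valid] * spacing[0],
            msd=sums_pm[p][valid].sum(axis=1) / counts[valid],
            n_pairs=counts[valid],
            species=species,
            per_particle=per_particle,
        )
        res = einstein_diffusion(msd, window=window)
        res.phase = p
        out[p] = (msd, res)
    return out
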