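"""Structural analysis of phase-separated mixtures: partial density
profiles along a box axis, radial distribution functions, and
phase-partition ("pollutant fraction") quantification.

In extraction-style systems the IMID-water phase separates from the
HexA/oil phase as chi_IMID grows; the fraction of a species found
outside its majority phase measures how cleanly the separation cuts.
The phase region can be defined either from a density profile (the
contiguous slab where the species' density exceeds half its peak) or
from local-composition phase labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InsufficientDataError
from .toysim import Frame, Trajectory
from .transport import _molecule_table

__all__ = [
    "DensityProfile",
    "RDFSeries",
    "PhasePartition",
    "partial_density_profile",
    "compute_rdf",
    "pollutant_fraction",
]


def _as_frames(obj) -> list[Frame]:
    if isinstance(obj, Frame):
        return [obj]
    return list(obj.frames)


def _circular_mean(values: np.ndarray, length: float) -> float:
    """Periodic mean of coordinates on [0, length)."""
    theta = 2.0 * np.pi * values / length
    mean_angle = np.angle(np.exp(1j * theta).mean())
    return (mean_angle % (2.0 * np.pi)) * length / (2.0 * np.pi)


@dataclass
class DensityProfile:
    """Per-species number density along one box axis."""

    bin_centers: np.ndarray  # nm
    density: dict[str, np.ndarray]  # molecules / nm^3, frame-averaged
    counts: dict[str, np.ndarray]  # summed molecule counts per bin
    bin_width: float
    axis: int
    n_frames: int
    aligned: bool = False

    def normalized(self, species: str) -> np.ndarray:
        """Profile scaled so its peak is 1 (plot convention)."""
        rho = self.density[species]
        peak = rho.max()
        if peak <= 0:
            raise DomainError(f"species {species!r} has an empty profile")
        return rho / peak


def partial_density_profile(
    traj,
    axis: int = 2,
    bin_width: float = 0.1,
    align: bool = False,
    align_species: str | None = None,
) -> DensityProfile:
    """Time-averaged per-species number-density histogram along an axis.

    Molecule centers are binned on [0, L) with half-open bins.  With
    ``align=True`` every frame is re-centered so that the periodic mean
    position of ``align_species`` (default: first species) sits at
    L/2 -- slab drift between frames otherwise washes the interfaces
    out of the average.  Raw densities integrate back to molecule
    counts; use :meth:`DensityProfile.normalized` for the plot-style
    peak-normalized variant.
    """
    frames = _as_frames(traj)
    box = frames[0].box
    length = box.lengths[axis]
    if bin_width <= 0 or bin_width > length:
        raise DomainError("bin_width must be in (0, box edge]")
    n_bins = max(int(round(length / bin_width)), 1)
    edges = np.linspace(0.0, length, n_bins + 1)
    width = edges[1] - edges[0]
    cross_section = box.volume / length
    bin_volume = cross_section * width

    counts: dict[str, np.ndarray] = {}
    for f in frames:
        _, centers, mol_species = _molecule_table(f)
        x = np.mod(centers[:, axis], length)
        if align:
            ref = align_species or str(mol_species[0])
            sel = mol_species == ref
            if not np.any(sel):
                raise DomainError(f"alignment species {ref!r} absent from frame")
            shift = 0.5 * length - _circular_mean(x[sel], length)
            x = np.mod(x + shift, length)
        idx = np.minimum((x / width).astype(int), n_bins - 1)
        for s in np.unique(mol_species):
            h = np.bincount(idx[mol_species == s], minlength=n_bins)
            counts[s] = counts.get(s, np.zeros(n_bins, dtype=int)) + h

    density = {s: c / (len(frames) * bin_volume) for s, c in counts.items()}
    return DensityProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        density=density,
        counts=counts,
        bin_width=width,
        axis=axis,
        n_frames=len(frames),
        aligned=align,
    )


@dataclass
class RDFSeries:
    """Radial distribution function for one species pair."""

    r: np.ndarray  # bin centers, nm
    g: np.ndarray
    pair: tuple[str, str]
    counts: np.ndarray  # raw pair counts per bin, summed over frames
    n_frames: int


def compute_rdf(
    traj,
    pair: tuple[str, str],
    r_max: float,
    dr: float = 0.02,
) -> RDFSeries:
    """Pair correlation g(r) between molecule centers of two species.

    Distances use the minimum-image convention; the histogram is
    normalized by the ideal-gas shell expectation so that g -> 1 at
    large r in a homogeneous fluid.  ``r_max`` may not exceed half the
    shortest box edge.
    """
    frames = _as_frames(traj)
    box = frames[0].box
    if r_max <= 0 or r_max > 0.5 * min(box.lengths):
        raise DomainError("r_max must be in (0, half shortest box edge]")
    if dr <= 0:
        raise DomainError("dr must be positive")
    a, b = pair
    same = a == b
    n_bins = int(np.ceil(r_max / dr))
    edges = np.linspace(0.0, n_bins * dr, n_bins + 1)
    hist = np.zeros(n_bins)
    norm = 0.0

    for f in frames:
        _, centers, mol_species = _molecule_table(f)
        pa = centers[mol_species == a]
        pb = centers[mol_species == b]
        if len(pa) == 0 or len(pb) == 0:
            raise InsufficientDataError(f"species pair {pair} absent from frame")
        if same:
            if len(pa) < 2:
                raise InsufficientDataError(f"need >= 2 molecules of {a!r}")
            iu, ju = np.triu_indices(len(pa), k=1)
            disp = box.min_image(pa[iu] - pa[ju])
            n_ideal_pairs = len(pa) * (len(pa) - 1) / 2.0
        else:
            disp = box.min_image(pa[:, None, :] - pb[None, :, :]).reshape(-1, 3)
            n_ideal_pairs = float(len(pa) * len(pb))
        d = np.linalg.norm(disp, axis=1)
        hist += np.histogram(d, bins=edges)[0]
        norm += n_ideal_pairs / box.volume

    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = hist / (norm * shell)
    return RDFSeries(
        r=0.5 * (edges[:-1] + edges[1:]),
        g=g,
        pair=(a, b),
        counts=hist,
        n_frames=len(frames),
    )


@dataclass
class PhasePartition:
    """In/out partition of a species relative to its majority phase."""

    species: str
    inside: float  # mean molecule count inside the phase region
    outside: float
    total: int
    fraction_outside_pct: float
    fraction_se: float
    method: str
    region: tuple[float, float] | None = None  # along-axis bounds (may wrap)
    per_frame_pct: np.ndarray = field(default_factory=lambda: np.empty(0))


def _half_max_region(x: np.ndarray, length: float, n_bins: int):
    """Contiguous periodic bin run above the half-plateau density.

    The raw histogram is smoothed with a periodic boxcar (~0.5 nm wide)
    so counting noise does not fragment the region, then thresholded
    midway between the plateau level (mean of above-average bins) and
    the background level (mean of the rest); the midpoint crossing of a
    symmetric blur stays at the true interface.  Plateau less than
    twice the background means no usable density contrast.
    """
    width = length / n_bins
    idx = np.minimum((x / width).astype(int), n_bins - 1)
    hist = np.bincount(idx, minlength=n_bins).astype(float)
    win = max(1, int(round(0.5 / width)))
    kernel = np.ones(win) / win
    pad = np.concatenate([hist[-win:], hist, hist[:win]])
    smooth = np.convolve(pad, kernel, mode="same")[win:-win]
    m = smooth.mean()
    hi_bins = smooth > m
    plateau = smooth[hi_bins].mean() if hi_bins.any() else 0.0
    background = smooth[~hi_bins].mean() if (~hi_bins).any() else 0.0
    if plateau < 2.0 * background:
        return None, None  # no contrast
    above = smooth >= 0.5 * (plateau + background)
    # close below-threshold gaps shorter than the smoothing window:
    # counting-noise dips inside the plateau must not split the region
    true_idx = np.flatnonzero(above)
    if len(true_idx) == 0:
        return None, None
    for a, b in zip(true_idx, np.roll(true_idx, -1)):
        gap = (b - a - 1) % n_bins
        if 0 < gap <= win:
            for j in range(a + 1, a + 1 + gap):
                above[j % n_bins] = True
    hist = smooth
    if above.all():
        return None, None
    start = int(np.argmax(hist))
    members = [start]
    i = start
    while True:  # extend forward with wrap
        j = (i + 1) % n_bins
        if j == start or not above[j]:
            break
        members.append(j)
        i = j
    i = start
    while True:  # extend backward with wrap
        j = (i - 1) % n_bins
        if j == start or not above[j] or j in members:
            break
        members.append(j)
        i = j
    mask = np.zeros(n_bins, dtype=bool)
    mask[members] = True
    lo = (min(members) % n_bins) * width
    hi = ((max(members) % n_bins) + 1) * width
    return mask, (lo, hi)


def pollutant_fraction(
    traj,
    species: str,
    labels: np.ndarray | None = None,
    axis: int = 2,
    bin_width: float = 0.1,
) -> PhasePartition:
    """Fraction of a species' molecules found outside its majority phase.

    Two phase definitions are supported:

    * profile threshold (default): per frame, the phase region is the
      contiguous (periodic) slab along ``axis`` where the species'
      density exceeds half its peak; molecules outside it are
      pollutants.  Frames without density contrast raise
      :class:`InsufficientDataError`.
    * local-composition labels: pass ``labels`` from
      :func:`desmix.transport.classify_local_phase` (shape (N,) for a
      single frame or (n_frames, N)); molecules not labelled
      ``"<species>-rich"`` count as outside.

    Returns mean counts, the percentage outside and its SE over frames.
    """
    frames = _as_frames(traj)
    per_frame = []
    inside_mean = outside_mean = 0.0
    total = 0
    region = None

    if labels is not None:
        lab = np.asarray(labels)
        if lab.ndim == 1:
            lab = lab[None, :]
        if lab.shape[0] != len(frames):
            raise DomainError("labels must cover every frame")
        target = f"{species}-rich"
        for f, fl in zip(frames, lab):
            _, _, mol_species = _molecule_table(f)
            sel = mol_species == species
            if not np.any(sel):
                raise InsufficientDataError(f"no molecules of {species!r}")
            out = np.sum(np.asarray(fl)[sel] != target)
            per_frame.append(100.0 * out / sel.sum())
            inside_mean += sel.sum() - out
            outside_mean += out
            total = int(sel.sum())
        method = "local-composition"
    else:
        length = frames[0].box.lengths[axis]
        n_bins = max(int(round(length / bin_width)), 2)
        width = length / n_bins
        for f in frames:
            _, centers, mol_species = _molecule_table(f)
            sel = mol_species == species
            if not np.any(sel):
                raise InsufficientDataError(f"no molecules of {species!r}")
            x = np.mod(centers[sel, axis], length)
            mask, region = _half_max_region(x, length, n_bins)
            if mask is None:
                raise InsufficientDataError(
                    f"no density contrast for {species!r}: phase region undefined"
                )
            idx = np.minimum((x / width).astype(int), n_bins - 1)
            out = np.sum(~mask[idx])
            per_frame.append(100.0 * out / sel.sum())
            inside_mean += sel.sum() - out
            outside_mean += out
            total = int(sel.sum())
        method = "profile-half-max"

    per_frame = np.array(per_frame)
    n = len(per_frame)
    se = per_frame.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
    return PhasePartition(
        species=species,
        inside=inside_mean / n,
        outside=outside_mean / n,
        total=total,
        fraction_outside_pct=float(per_frame.mean()),
        fraction_se=float(se),
        method=method,
        region=region,
        per_frame_pct=per_frame,
    )
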