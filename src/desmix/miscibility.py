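"""Contact counting and the contact-percentage miscibility metric.

Phase separation in the HexA/IMID deep eutectic solvent is quantified
by counting molecular contacts: an unordered pair of molecules is in
contact when any bead of one lies within a cutoff (0.6 nm by default)
of any bead of the other under the minimum-image convention.  The
mixing percentage

    100 * N(HexA-IMID) / (N(HexA-IMID) + N(IMID-IMID))

is high in a well-mixed system and collapses as IMID self-associates.
Percentages map onto three bands: mixed (>50%), partially mixed
(30-45%) and almost biphasic (<30%); values in the unassigned (45, 50]
gap are labelled ``intermediate`` rather than snapped to a band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DomainError, InsufficientDataError, UndefinedMetricError
from .toysim import Frame, Trajectory

__all__ = [
    "ContactReport",
    "count_contacts",
    "mixing_metric",
    "classify_mixing",
    "miscibility_scan",
    "DEFAULT_CUTOFF",
    "DEFAULT_NUMERATOR",
    "DEFAULT_DENOMINATOR",
]

#: Contact cutoff distance in nm.
DEFAULT_CUTOFF = 0.6
DEFAULT_NUMERATOR = ("HexA", "IMID")
DEFAULT_DENOMINATOR = (("HexA", "IMID"), ("IMID", "IMID"))

_BANDS = {"mixed": ">50", "partially_mixed": "30-45", "almost_biphasic": "<30"}


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class ContactReport:
    """Species-pair contact counts for one frame (or frame average)."""

    counts: dict[tuple[str, str], int]
    cutoff: float
    mode: str = "molecule"
    mixing_percentage: float | None = None
    class_label: str | None = None

    def count(self, a: str, b: str) -> int:
        return self.counts.get(_pair_key(a, b), 0)


def count_contacts(
    frame: Frame, cutoff: float = DEFAULT_CUTOFF, mode: str = "molecule"
) -> ContactReport:
    """Count inter- and intra-species contacts in one frame.

    In ``molecule`` mode (default) an unordered molecule pair counts
    once if any bead-bead distance is below the cutoff; ``bead`` mode
    counts every bead pair.  Neighbor search uses a periodic k-d tree;
    the cutoff may not exceed half the shortest box edge (minimum-image
    ambiguity).
    """
    box = frame.box
    if cutoff <= 0:
        raise DomainError("cutoff must be positive")
    if cutoff > 0.5 * min(box.lengths):
        raise DomainError(
            f"cutoff {cutoff} nm exceeds half the shortest box edge "
            f"({0.5 * min(box.lengths):.3g} nm)"
        )
    if mode not in ("molecule", "bead"):
        raise DomainError("mode must be 'molecule' or 'bead'")

    coords = box.wrap(frame.coords)
    # cKDTree requires strictly < boxsize
    coords = np.where(coords >= box.lengths, 0.0, coords)
    tree = cKDTree(coords, boxsize=box.lengths)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")

    species = frame.species.astype(str)
    counts: dict[tuple[str, str], int] = {}
    if mode == "bead":
        for i, j in pairs:
            key = _pair_key(species[i], species[j])
            counts[key] = counts.get(key, 0) + 1
    else:
        mol = frame.molecule_ids
        mi, mj = mol[pairs[:, 0]], mol[pairs[:, 1]]
        keep = mi != mj
        a = np.minimum(mi[keep], mj[keep])
        b = np.maximum(mi[keep], mj[keep])
        mol_pairs = np.unique(np.stack([a, b], axis=1), axis=0) if len(a) else np.empty((0, 2), int)
        # species of a molecule = species of its first bead
        uniq, first_idx = np.unique(mol, return_index=True)
        mol_species = dict(zip(uniq.tolist(), species[first_idx]))
        for i, j in mol_pairs:
            key = _pair_key(mol_species[i], mol_species[j])
            counts[key] = counts.get(key, 0) + 1
    return ContactReport(counts=counts, cutoff=cutoff, mode=mode)


def mixing_metric(
    report: ContactReport,
    numerator: tuple[str, str] = DEFAULT_NUMERATOR,
    denominator: tuple[tuple[str, str], ...] = DEFAULT_DENOMINATOR,
) -> float:
    """Contact percentage 100 * N(numerator) / sum(N(denominator)).

    Raises :class:`UndefinedMetricError` when the denominator is zero --
    an undefined metric is distinct from a measured 0%.
    """
    num = report.count(*numerator)
    den = sum(report.count(*p) for p in denominator)
    if den == 0:
        raise UndefinedMetricError(
            f"no contacts in denominator pairs {denominator}; metric undefined"
        )
    return 100.0 * num / den


def classify_mixing(percentage: float) -> str:
    """Map a contact percentage onto the miscibility bands.

    >50 -> ``mixed``; [30, 45] -> ``partially_mixed``; <30 ->
    ``almost_biphasic``.  The unassigned gap (45, 50] is reported as
    ``intermediate``.
    """
    if not 0.0 <= percentage <= 100.0:
        raise DomainError(f"percentage must be in [0, 100], got {percentage}")
    if percentage > 50.0:
        return "mixed"
    if percentage > 45.0:
        return "intermediate"
    if percentage >= 30.0:
        return "partially_mixed"
    return "almost_biphasic"


def _trajectory_metric_series(
    traj: Trajectory, cutoff, discard, numerator, denominator, mode
) -> np.ndarray:
    n = len(traj)
    start = int(np.floor(discard * n))
    vals = []
    for frame in traj.frames[start:]:
        report = count_contacts(frame, cutoff=cutoff, mode=mode)
        try:
            vals.append(mixing_metric(report, numerator, denominator))
        except UndefinedMetricError:
            warnings.warn("frame with zero denominator contacts skipped", stacklevel=2)
    return np.array(vals)


def miscibility_scan(
    cells: dict[tuple[float, float], list[Trajectory]],
    cutoff: float = DEFAULT_CUTOFF,
    equilibration_discard: float = 0.2,
    numerator: tuple[str, str] = DEFAULT_NUMERATOR,
    denominator: tuple[tuple[str, str], ...] = DEFAULT_DENOMINATOR,
    mode: str = "molecule",
) -> pd.DataFrame:
    """Time-averaged miscibility table over a (chi_IMID, T) grid.

    ``cells`` maps (chi_imid, temperature) to replica trajectories.
    The first ``equilibration_discard`` share of each trajectory's
    frames is dropped; the per-cell value is the mean of per-replica
    time averages, the spread their standard deviation (falling back to
    the per-frame deviation for single replicas).  Returns a DataFrame
    with columns chi_imid, T, mean_pct, sd_pct, n_replicas, class.
    """
    if not 0.0 <= equilibration_discard < 1.0:
        raise DomainError("equilibration_discard must be in [0, 1)")
    rows = []
    for (chi, temp), trajs in cells.items():
        if not trajs:
            raise InsufficientDataError(f"cell ({chi}, {temp}) has no trajectories")
        replica_means, all_vals = [], []
        for traj in trajs:
            vals = _trajectory_metric_series(
                traj, cutoff, equilibration_discard, numerator, denominator, mode
            )
            if len(vals):
                replica_means.append(vals.mean())
                all_vals.append(vals)
        if not replica_means:
            raise InsufficientDataError(
                f"cell ({chi}, {temp}): every frame was discarded or undefined"
            )
        mean = float(np.mean(replica_means))
        if len(replica_means) > 1:
            sd = float(np.std(replica_means, ddof=1))
        else:
            pooled = np.concatenate(all_vals)
            sd = float(np.std(pooled, ddof=1)) if len(pooled) > 1 else 0.0
        rows.append(
            {
                "chi_imid": chi,
                "T": temp,
                "mean_pct": mean,
                "sd_pct": sd,
                "n_replicas": len(replica_means),
                "class": classify_mixing(mean),
            }
        )
    return pd.DataFrame(rows)
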