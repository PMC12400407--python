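"""Thermal expansion from density series and shear viscosity from the
periodic perturbation method.

The thermal expansion coefficient is alpha = -(d ln rho / dT) at
constant pressure, estimated as minus the slope of a (weighted) linear
fit of ln rho against T.

Periodic-perturbation viscometry drives the liquid with an external
acceleration field a_x(z) = A cos(k z), k = 2 pi / Lz, in a box whose
z-edge is elongated (1:1:3 here).  At steady state the Navier-Stokes
momentum balance for the cosine mode reads

    eta * k^2 * V = rho * A        =>        eta = rho * A / (V * k^2),

where V is the amplitude of the steady cosine velocity profile.  V is
measured by projecting mass-weighted particle x-velocities onto
cos(k z) frame by frame after a transient discard, and eta is averaged
over the applied acceleration rates (0.002-0.008 nm/ps^2 in the
reference protocol) with a linearity diagnostic on V vs A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, FitError, InsufficientDataError
from .toysim import Trajectory
from .units import AMU_PER_NM3_TO_KG_PER_M3, viscosity_internal_to_mpas

__all__ = [
    "ExpansionResult",
    "ProfileAmplitude",
    "ViscosityResult",
    "thermal_expansion",
    "fit_velocity_profile",
    "viscosity_periodic_perturbation",
    "eta_from_amplitude",
]


@dataclass
class ExpansionResult:
    """Thermal expansion coefficient (1/K) with fit standard error."""

    alpha: float
    alpha_se: float
    n_points: int
    r_squared: float


def thermal_expansion(series: pd.DataFrame, sigma_column: str | None = None) -> ExpansionResult:
    """alpha = -(d ln rho / dT) from a density-vs-temperature table.

    ``series`` needs columns ``T`` (K) and ``rho`` (any consistent
    density unit; only the log-slope matters).  When ``sigma_column``
    names a per-point density uncertainty, points are weighted by
    1/sigma_lnrho^2.
    """
    t = np.asarray(series["T"], dtype=float)
    rho = np.asarray(series["rho"], dtype=float)
    if len(t) < 2:
        raise InsufficientDataError("need >= 2 temperatures for an expansion fit")
    if np.any(rho <= 0):
        raise DomainError("densities must be positive")
    y = np.log(rho)
    if sigma_column is not None:
        sig = np.asarray(series[sigma_column], dtype=float) / rho
        w = 1.0 / sig**2
    else:
        w = np.ones_like(y)
    sw = w.sum()
    tm = (w * t).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (t - tm) ** 2).sum()
    if sxx <= 0:
        raise FitError("temperatures are degenerate")
    slope = (w * (t - tm) * (y - ym)).sum() / sxx
    resid = y - (ym + slope * (t - tm))
    dof = max(len(t) - 2, 1)
    se = np.sqrt((w * resid**2).sum() / dof / sxx)
    syy = (w * (y - ym) ** 2).sum()
    r2 = 1.0 - (w * resid**2).sum() / syy if syy > 0 else 1.0
    return ExpansionResult(alpha=float(-slope), alpha_se=float(se), n_points=len(t), r_squared=float(r2))


@dataclass
class ProfileAmplitude:
    """Fitted cosine-profile amplitude V (nm/ps) with SE across frames."""

    amplitude: float
    amplitude_se: float
    n_frames: int
    mode: int = 1


def fit_velocity_profile(
    traj: Trajectory,
    axis: int = 0,
    gradient_axis: int = 2,
    mode: int = 1,
    discard: float = 1.0 / 3.0,
    masses: np.ndarray | float | None = None,
) -> ProfileAmplitude:
    """Amplitude of the cosine flow profile from particle velocities.

    Fits mass-weighted velocities (component ``axis``) to
    ``c0 + V cos(m k z)``, z the ``gradient_axis`` coordinate and
    k = 2 pi / L, by weighted least squares per frame.  Fitting the
    uniform term alongside the cosine makes the amplitude exactly
    invariant under Galilean velocity offsets (a bare projection would
    leak an O(1/sqrt(N)) share of any drift into V); Fourier
    orthogonality keeps other harmonics out.  The first ``discard``
    share of frames is dropped as transient; the SE is the standard
    error over the remaining frames.
    """
    if not 0.0 <= discard < 1.0:
        raise DomainError("discard must be in [0, 1)")
    frames = traj.frames[int(np.floor(discard * len(traj))):]
    if not frames:
        raise InsufficientDataError("no frames left after transient discard")
    if any(f.velocities is None for f in frames):
        raise DomainError("velocity data required for a profile fit")
    length = frames[0].box.lengths[gradient_axis]
    k = 2.0 * np.pi * mode / length
    amps = []
    for f in frames:
        z = f.box.wrap(f.coords)[:, gradient_axis]
        v = f.velocities[:, axis]
        if masses is None:
            m = np.ones_like(v)
        elif np.isscalar(masses):
            m = np.full_like(v, float(masses))
        else:
            m = np.asarray(masses, dtype=float)
        c = np.cos(k * z)
        # weighted normal equations for v = c0 + V*c
        sw, swc, swcc = m.sum(), (m * c).sum(), (m * c * c).sum()
        swv, swvc = (m * v).sum(), (m * v * c).sum()
        det = sw * swcc - swc * swc
        amps.append(float((sw * swvc - swc * swv) / det))
    amps = np.array(amps)
    se = amps.std(ddof=1) / np.sqrt(len(amps)) if len(amps) > 1 else float("nan")
    return ProfileAmplitude(
        amplitude=float(amps.mean()), amplitude_se=float(se), n_frames=len(amps), mode=mode
    )


def eta_from_amplitude(
    acceleration: float,
    amplitude: float,
    density: float,
    lz: float,
    density_units: str = "kg/m3",
) -> float:
    """Single-run viscosity eta = rho A / (V k^2), reported in mPa*s.

    ``acceleration`` in nm/ps^2, ``amplitude`` in nm/ps, ``lz`` in nm;
    ``density`` in kg/m^3 (default) or amu/nm^3
    (``density_units="amu/nm3"``).
    """
    if amplitude <= 0:
        raise DomainError("profile amplitude must be positive")
    if density <= 0 or lz <= 0:
        raise DomainError("density and Lz must be positive")
    if density_units == "kg/m3":
        rho = density / AMU_PER_NM3_TO_KG_PER_M3
    elif density_units == "amu/nm3":
        rho = density
    else:
        raise DomainError("density_units must be 'kg/m3' or 'amu/nm3'")
    k = 2.0 * np.pi / lz
    eta_internal = rho * acceleration / (amplitude * k * k)
    return viscosity_internal_to_mpas(eta_internal)


@dataclass
class ViscosityResult:
    """Viscosity averaged over acceleration rates and replicas."""

    eta: float  # mPa*s
    eta_sem: float  # standard error of the mean; NaN for a single run
    per_run: pd.DataFrame = field(default_factory=pd.DataFrame)
    linearity_r_squared: float = float("nan")
    n_runs: int = 0


def viscosity_periodic_perturbation(
    runs,
    density: float,
    lz: float,
    density_units: str = "kg/m3",
) -> ViscosityResult:
    """Combine per-run (acceleration, fitted amplitude) pairs into one
    viscosity estimate.

    ``runs`` is a sequence of (A, V) pairs in nm/ps^2 and nm/ps (one
    per acceleration rate and replica).  Runs with non-positive V are
    excluded with a warning -- they carry no steady-flow signal.  The
    result is the mean of the per-run eta values with the SEM across
    runs, plus a straight-line R^2 of V vs A as a linear-response
    diagnostic.
    """
    kept, eta_vals = [], []
    for a, v in runs:
        if v <= 0:
            warnings.warn(f"run with A={a}: non-positive amplitude excluded", stacklevel=2)
            continue
        kept.append((a, v))
        eta_vals.append(eta_from_amplitude(a, v, density, lz, density_units))
    if not kept:
        raise InsufficientDataError("no runs with positive profile amplitude")
    eta_vals = np.array(eta_vals)
    a_arr = np.array([a for a, _ in kept])
    v_arr = np.array([v for _, v in kept])
    if len(kept) > 1 and len(np.unique(a_arr)) > 1:
        slope, icpt = np.polyfit(a_arr, v_arr, 1)
        pred = icpt + slope * a_arr
        ss_res = float(((v_arr - pred) ** 2).sum())
        ss_tot = float(((v_arr - v_arr.mean()) ** 2).sum())
        lin_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        lin_r2 = float("nan")
    sem = eta_vals.std(ddof=1) / np.sqrt(len(eta_vals)) if len(eta_vals) > 1 else float("nan")
    table = pd.DataFrame(
        {"acceleration_nm_ps2": a_arr, "amplitude_nm_ps": v_arr, "eta_mPas": eta_vals}
    )
    return ViscosityResult(
        eta=float(eta_vals.mean()),
        eta_sem=float(sem),
        per_run=table,
        linearity_r_squared=lin_r2,
        n_runs=len(kept),
    )
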