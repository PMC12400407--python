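# Methods

`desmix` analyses coarse-grained simulations of the hexanoic-acid
(HexA) / imidazole (IMID) deep eutectic solvent: a type V DES whose
phase behaviour — mixing at low IMID content, demixing as χ_IMID grows,
and re-mixing on dilution with HexA — underlies a proposed
liquid–liquid extraction cycle for fatty acids. The package implements
the analysis layer of such a study (miscibility scoring, transport,
viscometry, structure, composition algebra) together with a desk-scale
synthetic-data engine, so that every estimator can be validated against
known ground truth without a large MD engine or a production force
field.

Internal units are the GROMACS/Martini conventions throughout: nm, ps,
amu (g/mol), kJ/mol, K. Boxes are orthorhombic and periodic;
coordinates are stored wrapped, with image-consistent (unwrapped)
coordinates carried alongside wherever displacement analysis needs
them. Bins are half-open `[lo, hi)`; particle indices are 0-based.

## Composition algebra

Solvent compositions live on the mole-fraction simplex over
{HexA, HexA⁻, IMID, IMID⁺, water}; χ_IMID and χ_H₂O parameterize a
system and HexA takes the remainder. Water is fixed at χ_H₂O = 0.1 by
default — the hydration level at which DES properties stop responding
dramatically to added water. Oils (oleic/linoleic acid) are carried as
a mass loading (g oil per g solvent) outside the simplex, because
extraction protocols vary χ_IMID at fixed oil mass.

The DES → ionic-liquid reaction is a mole-for-mole proton transfer
IMID + HexA → IMID⁺ + HexA⁻ at an externally prescribed extent
ξ ∈ [0, 1]; the reacted amount is min(ξ·n_IMID, n_HexA), so above the
equimolar composition (χ_IMID = 0.45 at χ_H₂O = 0.1) full conversion
leaves unreacted IMID. No pKa or speciation chemistry is modelled; in
the CG picture the reaction is a bead-identity swap conserving moles.

`regeneration_mass_balance` answers: how much HexA must be added to
dilute χ_IMID (counting both neutral and protonated imidazole) from a
phase-separated composition back to a mixed one? The added moles
follow from χ_target = χ_0/(1 + x); the reported mass factor is the
ratio of final to initial solvent mass. Because this factor depends on
bookkeeping conventions that are genuinely open — which mass table
(atomistic molar masses vs CG bead masses, where one water bead is four
waters at 72 amu) and whether the oil mass is counted — the operation
exposes both switches instead of hard-coding one. Defaults: atomistic
masses, oil excluded. For the 0.60 → 0.30 dilution these give a factor
of 2.50; CG bead masses (HexA = regular+small bead = 126 amu,
IMID = 3 tiny beads = 108 amu, water = 72 amu) give 2.15.

The campaign planner enumerates full factorial grids
(composition × temperature × size × replica, optionally ×
acceleration rate for viscometry). Each cell receives a deterministic
seed: a 32-bit BLAKE2 digest of (base seed, cell indices), so
re-planning is reproducible and seeds never collide in practice.

## Toy simulator

`run_langevin` integrates single-bead molecules interacting through a
bounded, C¹-continuous pair potential: a harmonic repulsive core
(½·k_rep·(σ−r)² − ε for r < σ) joined to a cos² attractive well of
depth ε_ij and width w (cutoff σ + w). The bounded force keeps large
time steps stable, and scaling the unlike-pair well depth by
κ = ε_cross/ε_self tunes the drive toward demixing — a minimal
analogue of self- vs cross-affinity in CG force fields. Defaults:
σ = 0.47 nm, w = 0.35 nm, k_rep = 400 kJ/mol/nm², mass 72 amu
(Martini-like scales).

Integration is velocity Verlet with the BAOAB splitting of the
Langevin friction step (γ = 2 ps⁻¹ default); with the thermostat off
it reduces to NVE velocity Verlet, which conserves energy to ~10⁻⁵
relative over 10⁴ steps at dt = 0.005 ps. The stability bound is set
by the core frequency √(k_rep/m) (period ≈ 2.7 ps at defaults);
dt = 0.01–0.02 ps is safe. A step that moves any particle more than
half the box raises an integration error rather than silently wrapping.
An isotropic weak-coupling barostat is available but off by default.

During cosine-flow (viscometry) runs the thermostat is
profile-unbiased: the instantaneous uniform and cos(2πz/L_z) x-flow
modes are projected out (mass-weighted least squares) before the
friction/noise step and restored afterwards. This matters: naive
Langevin friction damps the driven mode directly, and the apparent
viscosity is then dominated by the thermostat drag ρ·γ/k² (≈1.6 mPa·s
at default parameters) rather than by momentum transport through the
fluid.

Direct generators bypass dynamics where exact ground truth is wanted:

* `gen_brownian_ensemble` — Gaussian random walks with per-axis step
  variance 2·D·dt; compartment mode tags walkers with a phase label
  controlling their local D, flipping at a Poisson exchange rate
  (rate 0 = impermeable). Label histories are returned as ground truth
  for the per-phase estimators.
* `gen_cosine_flow` — frames with u_x(z) = V·cos(m·k·z) plus thermal
  noise, for the profile-fit estimator.
* `gen_density_series` — ρ(T) = ρ₀·e^(−αT) with optional relative
  Gaussian noise.

What the generators emulate is the *statistical structure* the
estimators assume (known diffusivities, known flow profiles, known
expansion coefficients, constructed slab geometries); they do not
reproduce Martini-level energetics, electrostatics, molecular shape, or
μs-scale kinetics. Passing tests therefore demonstrate estimator
correctness and qualitative trend capture, not quantitative agreement
with production CG simulations.

## Miscibility metric

A contact is an unordered molecule pair with any bead of one within
0.6 nm of any bead of the other (minimum image); a bead-pair counting
mode exists but the molecule-pair reading is the default. Neighbor
search uses a periodic k-d tree and is exactly equal (integer
equality) to an all-pairs double loop on every tested fixture. The
mixing percentage is

    100 · N(HexA–IMID) / (N(HexA–IMID) + N(IMID–IMID)),

with configurable numerator/denominator pairs. A zero denominator
raises an "undefined metric" signal, which is deliberately distinct
from a measured 0 %. Classification bands: mixed (>50 %), partially
mixed (30–45 %), almost biphasic (<30 %); the unassigned gap (45, 50]
is labelled `intermediate` instead of being silently snapped to a
neighbouring band. For an ideal random equimolar mixture of N + N
single-bead molecules the expected percentage is
100·2N/(3N−1) ≈ 66.9 % at N = 100 — comfortably "mixed", as it should
be. Grid scans average over post-discard frames (default: first 20 %
of frames dropped; equilibration plateaus justify a fixed fraction) and
report replicate mean ± standard deviation.

The default demixing demonstration runs the binary equimolar mixture at
ε_self = 4 kJ/mol, T = 300 K, number density 3 nm⁻³, N = 160,
dt = 0.02 ps, 1500 steps, κ ∈ {1.0, 0.6, 0.2}, three seeds, first third
discarded. Measured contact percentages under these conditions span
the three bands (≈68 % → 41 % → 13 %), monotone in κ.

## Transport

MSDs are multi-origin averages (origins every `origin_stride` frames)
over unwrapped coordinates; wrapped-only input is unwrapped by
minimum-image reconstruction, which errors out if any inter-frame
displacement comes within 2 % of the half-box ambiguity limit.
D = slope/6 from a pair-count-weighted linear fit with a free
intercept over the 10–50 % lag window — late enough to escape
short-time ballistic/cage behaviour, early enough to keep origin
statistics. A log-log slope diagnostic flags non-diffusive growth
(|exponent − 1| > 0.1).

Error convention: when per-particle MSDs are available (always, from
`compute_msd`), the slope standard error is the spread of per-particle
slopes divided by √N. Residual-based fit errors are *not* used: MSD
values at different lags share walkers and are strongly correlated, and
the residual SE under-covers badly (9 % empirical coverage of a ±2 SE
interval on Brownian ensembles, versus 93 % for the per-particle
spread). Replica aggregation (`aggregate_replicas`) averages replica
error variances rather than shrinking with replica count.

Finite-size correction fits D against N^(−1/3) (SE-weighted when given)
and reports the intercept as D_∞ with propagated error. No analytic
hydrodynamic correction is applied — the empirical extrapolation is the
method.

Per-phase diffusion: molecules are labelled HexA-rich / IMID-rich /
interfacial from the molecular composition within 1.2 nm of their
center, excluding water from the vote (the phases of interest are the
two organic ones); the majority species claims a molecule when its
share strictly exceeds 0.5, and ties or empty neighbourhoods are
interfacial. MSD contributions are grouped by the phase at each lag
*origin* and the molecule's full subsequent displacement stays with
that group whatever phases it later visits. This is the
survivor-bias-free convention: restricting to molecules that never
leave a phase (available as `survivor_biased=True`, for demonstration
only) systematically overestimates the mobility contrast, as the test
suite shows on exchanging-compartment fixtures. By construction the
pair-count-weighted union of per-phase MSDs reproduces the population
MSD exactly at every lag.

## Thermal expansion and viscometry

α = −(∂ ln ρ/∂T)_p is minus the slope of a (weighted) linear fit of
ln ρ against T; exact on noise-free exponential series and unbiased
under multiplicative noise.

Periodic-perturbation viscometry drives the fluid with
a_x(z) = A·cos(kz), k = 2π/L_z, in a 1:1:3 elongated box. At steady
state the cosine mode of the Navier–Stokes momentum balance gives
η·k²·V = ρ·A, hence η = ρ·A/(V·k²). V is estimated per frame by
mass-weighted least squares of v_x on {1, cos(kz)} — fitting the
uniform mode alongside makes the amplitude exactly Galilean-invariant
and orthogonal to higher harmonics — then averaged over post-transient
frames (default discard: first third of the run). Per-run η values
across the seven acceleration rates (0.002–0.008 nm/ps²) are averaged
(not extrapolated to zero rate; both readings of the protocol are
possible and averaging is the default), with the SEM across runs and a
V-vs-A straight-line R² as the linear-response diagnostic. Internal
η is amu/(nm·ps); reported values are mPa·s
(1 amu/(nm·ps) = 1.6605×10⁻³ mPa·s).

Desk-scale caveat: the toy fluid's intrinsic viscosity is small and its
slow flow modes relax over tens of ps, so single short runs scatter
widely; the simulator-level tests treat viscometry qualitatively
(positivity, paired linear-response doubling, temperature ordering
within 3 SEM) while the quantitative estimator contract is validated on
synthetic flow frames with known amplitude.

## Structure

Density profiles histogram molecule centers along an axis (default bin
0.1 nm), frame-averaged; counts integrate back to molecule totals
exactly. Optional per-frame alignment re-centers the periodic mean of
a chosen species at L/2 so slab drift does not wash out interfaces.
Peak-normalized variants are for plotting; quantitation uses raw
counts. Multi-bead molecule centers use the circular-mean convention
on each periodic axis.

RDFs between molecule centers use minimum-image distances normalized by
the ideal-gas shell expectation (default dr 0.02 nm); same-species
pairs are counted once and normalized by N(N−1)/2. The implementation
is brute-force vectorized — exact by construction at desk scale.

The pollutant fraction of a species is the share of its molecules
outside its majority phase. Two phase definitions are provided:
(a) profile threshold — per frame, the contiguous periodic slab where
the species' boxcar-smoothed (~0.5 nm) histogram exceeds the midpoint
between plateau and background levels, with sub-window gaps closed so
counting noise cannot fragment the region; a plateau below twice the
background is reported as "no density contrast" rather than a number;
(b) local-composition labels from the transport classifier. On sharp
slab fixtures the two agree within ~5 percentage points; single-frame
desk-scale estimates carry a few points of binning noise, so pollutant
fractions should be read at ±5 points.

## Known limitations

* The simulator has no electrostatics, no bonded topologies beyond
  shared molecule ids, and no claim of force-field realism; κ sweeps
  are an analogue of composition sweeps, not a mapping.
* Viscosity from the toy fluid is qualitative at desk scale (see
  above); the temperature trend is weak because the soft-sphere fluid
  at moderate density is kinetics-dominated.
* The profile-based phase region assumes one majority slab; multiple
  droplets of comparable size would need the local-composition route.
* Mole-fraction bookkeeping treats reaction as volume- and mass-free
  (CG bead swap); no eutectic-point thermodynamics is modelled.
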