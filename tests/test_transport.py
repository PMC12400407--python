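"""MSD, Einstein diffusion, finite-size fits, per-phase analysis."""

import numpy as np
import pytest

from desmix.errors import DomainError, FitError, UnwrapError
from desmix.toysim import (
    BoxGeometry,
    Composition,
    Frame,
    Trajectory,
    build_random_config,
    build_slab_config,
    gen_brownian_ensemble,
)
from desmix.transport import (
    MSDSeries,
    classify_local_phase,
    compute_msd,
    einstein_diffusion,
    finite_size_extrapolate,
    per_phase_diffusion,
    unwrap_trajectory,
)


def make_traj(positions, box, species=None, dt=1.0):
    """positions: (F, N, 3) unwrapped."""
    n = positions.shape[1]
    species = np.full(n, "A") if species is None else species
    frames = [
        Frame(coords=box.wrap(p), species=species, box=box, time=i * dt, unwrapped=p)
        for i, p in enumerate(positions)
    ]
    return Trajectory(frames=frames)


class TestComputeMSD:
    def test_stationary_particles_zero_msd(self, cubic_box):
        pos = np.tile(np.random.default_rng(0).uniform(0, 8, (20, 3)), (10, 1, 1))
        msd = compute_msd(make_traj(pos, cubic_box))
        np.testing.assert_allclose(msd.msd, 0.0, atol=1e-14)

    def test_ballistic_motion_quadratic_and_flagged(self, cubic_box):
        v = 0.05
        t = np.arange(30.0)
        pos = np.zeros((30, 5, 3))
        pos[:, :, 0] = v * t[:, None]
        msd = compute_msd(make_traj(pos, cubic_box))
        np.testing.assert_allclose(msd.msd, v**2 * msd.lags**2, rtol=1e-10)
        res = einstein_diffusion(msd)
        assert res.exponent == pytest.approx(2.0, abs=0.05)
        assert not res.is_linear

    def test_brownian_slope_recovers_d(self, cubic_box):
        traj = gen_brownian_ensemble(1000, 0.05, dt=1.0, n_steps=300,
                                     box=cubic_box, seed=3)
        res = einstein_diffusion(compute_msd(traj, origin_stride=10))
        assert res.d == pytest.approx(0.05, rel=0.05)
        assert res.is_linear

    def test_unwrap_reconstruction_matches_stored(self, cubic_box):
        traj = gen_brownian_ensemble(50, 0.01, dt=1.0, n_steps=50,
                                     box=cubic_box, seed=4)
        rebuilt = unwrap_trajectory(traj)
        stored = traj.coords_array(unwrapped=True)
        # reconstruction is exact up to a global image offset fixed at frame 0
        np.testing.assert_allclose(rebuilt - rebuilt[0], stored - stored[0], atol=1e-10)

    def test_half_box_jump_raises(self, cubic_box):
        pos = np.zeros((2, 1, 3))
        pos[1, 0, 0] = 3.993  # 0.499 * 8 nm: inside the ambiguity guard band
        traj = make_traj(pos, cubic_box)
        traj.frames[0].unwrapped = None
        traj.frames[1].unwrapped = None
        with pytest.raises(UnwrapError):
            compute_msd(traj)

    def test_global_translation_invariance(self, cubic_box):
        traj = gen_brownian_ensemble(100, 0.02, dt=1.0, n_steps=60,
                                     box=cubic_box, seed=5)
        msd1 = compute_msd(traj)
        shifted = make_traj(traj.coords_array(unwrapped=True) + 2.5, cubic_box)
        msd2 = compute_msd(shifted)
        np.testing.assert_allclose(msd1.msd, msd2.msd, rtol=1e-12)


class TestEinsteinFit:
    def test_exact_line_gives_exact_d(self):
        lags = np.arange(1.0, 101.0)
        msd = MSDSeries(lags=lags, msd=0.3 * lags, n_pairs=np.full(100, 50))
        assert einstein_diffusion(msd).d == pytest.approx(0.05, rel=1e-12)

    def test_additive_offset_absorbed_by_intercept(self):
        lags = np.arange(1.0, 101.0)
        msd = MSDSeries(lags=lags, msd=1.7 + 0.3 * lags, n_pairs=np.full(100, 50))
        assert einstein_diffusion(msd).d == pytest.approx(0.05, rel=1e-12)

    def test_degenerate_window_rejected(self):
        lags = np.arange(1.0, 11.0)
        msd = MSDSeries(lags=lags, msd=lags, n_pairs=np.full(10, 5))
        with pytest.raises(FitError):
            einstein_diffusion(msd, window=(0.5, 0.1))

    def test_two_se_interval_coverage(self, cubic_box):
        """~95% of independent ensembles cover the true D at +-2 SE."""
        cover = 0
        n_rep = 80
        for s in range(n_rep):
            traj = gen_brownian_ensemble(200, 0.05, dt=1.0, n_steps=100,
                                         box=cubic_box, seed=s)
            r = einstein_diffusion(compute_msd(traj, origin_stride=10))
            cover += abs(r.d - 0.05) <= 2 * r.d_se
        assert 0.85 <= cover / n_rep <= 1.0

    @pytest.mark.parametrize("d_true", [0.001, 0.01, 0.1])
    def test_unbiased_across_magnitudes(self, cubic_box, d_true):
        """Monte-Carlo bias below 2 SE of the mean at each tested D."""
        vals = []
        for s in range(25):
            traj = gen_brownian_ensemble(300, d_true, dt=1.0, n_steps=80,
                                         box=cubic_box, seed=1000 + s)
            vals.append(einstein_diffusion(compute_msd(traj, origin_stride=8)).d)
        mean = np.mean(vals)
        sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - d_true) < 2 * sem + 0.001 * d_true


class TestReplicaAggregation:
    def test_mean_of_variances_convention(self):
        from desmix.transport import DiffusionResult, aggregate_replicas

        reps = [
            DiffusionResult(d=0.04, d_se=0.003, window=(1, 5), r_squared=0.99,
                            exponent=1.0),
            DiffusionResult(d=0.06, d_se=0.004, window=(1, 5), r_squared=0.98,
                            exponent=1.0),
        ]
        agg = aggregate_replicas(reps)
        assert agg.d == pytest.approx(0.05)
        assert agg.d_se == pytest.approx(np.sqrt((0.003**2 + 0.004**2) / 2))

    def test_unit_conversion_to_conventional_scale(self):
        from desmix.transport import DiffusionResult

        r = DiffusionResult(d=1e-4, d_se=0.0, window=(1, 5), r_squared=1.0,
                            exponent=1.0)
        # 1e-4 nm^2/ps = 1e-6 cm^2/s = 0.1 in units of 1e-5 cm^2/s
        assert r.d_1e5_cm2_s == pytest.approx(0.1)


class TestFiniteSize:
    def test_noise_free_line_exact_intercept(self):
        pts = [(n, 5.0 - 2.0 * n ** (-1 / 3)) for n in (10**4, 20**4, 30**4)]
        fit = finite_size_extrapolate(pts)
        assert fit.d_infinity == pytest.approx(5.0, abs=1e-10)
        assert fit.slope == pytest.approx(-2.0, abs=1e-10)

    def test_constant_d_zero_slope(self):
        fit = finite_size_extrapolate([(100, 1.5), (1000, 1.5), (10000, 1.5)])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.d_infinity == pytest.approx(1.5, abs=1e-12)

    def test_single_size_rejected(self):
        with pytest.raises(FitError):
            finite_size_extrapolate([(1000, 1.0), (1000, 1.1)])

    def test_monte_carlo_unbiased_intercept(self):
        rng = np.random.default_rng(6)
        x = np.array([10**4, 20**4, 30**4], dtype=float)
        intercepts = []
        for _ in range(500):
            d = 5.0 - 2.0 * x ** (-1 / 3) + rng.normal(0, 0.05, 3)
            intercepts.append(finite_size_extrapolate(list(zip(x, d))).d_infinity)
        mean = np.mean(intercepts)
        sem = np.std(intercepts, ddof=1) / np.sqrt(len(intercepts))
        assert abs(mean - 5.0) < 2 * sem


class TestLocalPhase:
    def test_pure_fluid_single_phase(self):
        frame = build_random_config(
            Composition(fractions={"HexA": 1.0}), 200, 3.0, seed=7
        )
        asn = classify_local_phase(frame, radius=1.2, phase_species=("HexA", "IMID"))
        assert set(asn.labels) == {"HexA-rich"}

    def test_slab_labels_match_ground_truth_away_from_interface(self, cubic_box):
        comp = Composition(fractions={"HexA": 0.5, "IMID": 0.5})
        frame = build_slab_config(comp, 600, cubic_box, slab_species="IMID", seed=8)
        asn = classify_local_phase(frame, radius=1.2)
        z = frame.coords[:, 2]
        lo, hi = frame.metadata["slab_bounds"]
        bulk_imid = (frame.species == "IMID") & (z > lo + 1.2) & (z < hi - 1.2)
        bulk_hexa = (frame.species == "HexA") & (z > hi + 1.2) & (z < cubic_box.lz - 1.2)
        assert np.all(asn.labels[bulk_imid] == "IMID-rich")
        assert np.all(asn.labels[bulk_hexa] == "HexA-rich")

    def test_matches_brute_force_neighborhood_vote(self):
        comp = Composition(fractions={"HexA": 0.45, "IMID": 0.45, "water": 0.1})
        frame = build_random_config(comp, 120, 3.0, seed=9)
        asn = classify_local_phase(frame, radius=1.0)
        species = frame.species.astype(str)
        for i in range(frame.n_particles):
            counts = {"HexA": 0, "IMID": 0}
            for j in range(frame.n_particles):
                if i == j or species[j] == "water":
                    continue
                d = frame.box.min_image(frame.coords[i] - frame.coords[j])
                if d @ d <= 1.0:
                    counts[species[j]] += 1
            total = counts["HexA"] + counts["IMID"]
            if total == 0 or counts["HexA"] == counts["IMID"]:
                want = "interfacial"
            else:
                top = max(counts, key=counts.get)
                want = f"{top}-rich" if counts[top] / total > 0.5 else "interfacial"
            assert asn.labels[i] == want, i

    def test_radius_beyond_half_box_rejected(self, random_mixture):
        with pytest.raises(DomainError):
            classify_local_phase(random_mixture, radius=100.0)


class TestPerPhase:
    @staticmethod
    def _labelled(traj):
        return np.where(traj.metadata["labels"] == 0, "slow-rich", "fast-rich")

    def test_impermeable_compartments_recovered(self, cubic_box):
        traj = gen_brownian_ensemble(2000, None, dt=1.0, n_steps=250, box=cubic_box,
                                     seed=10, compartments=(0.01, 0.05),
                                     exchange_rate=0.0)
        res = per_phase_diffusion(traj, labels=self._labelled(traj), origin_stride=10)
        assert res["slow-rich"][1].d == pytest.approx(0.01, rel=0.10)
        assert res["fast-rich"][1].d == pytest.approx(0.05, rel=0.10)

    def test_fast_exchange_converges_to_population_mean(self, cubic_box):
        traj = gen_brownian_ensemble(800, None, dt=1.0, n_steps=200, box=cubic_box,
                                     seed=11, compartments=(0.01, 0.05),
                                     exchange_rate=1.0)
        res = per_phase_diffusion(traj, labels=self._labelled(traj), origin_stride=10)
        d_slow, d_fast = res["slow-rich"][1], res["fast-rich"][1]
        pop = einstein_diffusion(compute_msd(traj, origin_stride=10))
        for r in (d_slow, d_fast):
            assert abs(r.d - pop.d) < 3 * np.hypot(r.d_se, pop.d_se) + 0.002

    def test_default_is_not_survivor_biased(self, cubic_box):
        """Survivor-restricted grouping misestimates under fast exchange."""
        traj = gen_brownian_ensemble(800, None, dt=1.0, n_steps=150, box=cubic_box,
                                     seed=12, compartments=(0.01, 0.05),
                                     exchange_rate=1.0)
        lab = self._labelled(traj)
        fair = per_phase_diffusion(traj, labels=lab, origin_stride=15)
        biased = per_phase_diffusion(traj, labels=lab, origin_stride=15,
                                     survivor_biased=True)
        # biased fast-phase D stays near 0.05; unbiased relaxes to ~0.03
        assert biased["fast-rich"][1].d > fair["fast-rich"][1].d * 1.3
        assert biased["slow-rich"][1].d < fair["slow-rich"][1].d * 0.7

    def test_weighted_union_equals_population_msd(self, cubic_box):
        """Pair-count-weighted per-phase MSDs recombine exactly."""
        traj = gen_brownian_ensemble(200, None, dt=1.0, n_steps=60, box=cubic_box,
                                     seed=13, compartments=(0.01, 0.05),
                                     exchange_rate=0.3)
        res = per_phase_diffusion(traj, labels=self._labelled(traj), origin_stride=5)
        pop = compute_msd(traj, origin_stride=5)
        combined = np.zeros_like(pop.msd)
        weights = np.zeros_like(pop.msd)
        for msd, _ in res.values():
            idx = np.searchsorted(pop.lags, msd.lags)
            combined[idx] += msd.msd * msd.n_pairs
            weights[idx] += msd.n_pairs
        np.testing.assert_array_equal(weights, pop.n_pairs)
        np.testing.assert_allclose(combined / weights, pop.msd, rtol=1e-12)
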