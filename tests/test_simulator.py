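import math

import numpy as np
import pytest

from spherobridge.simulator import (
    ConfigurationError,
    CoincidentParticlesError,
    CycleParams,
    DiffusionParams,
    ForceParams,
    SimulationConfig,
    SpheroidState,
    cell_cycle_time,
    compute_density,
    compute_mobility,
    diffuse_source,
    divide_particle,
    hcp_lattice,
    initial_state,
    pair_force,
    radial_profiles,
    relax_positions,
    relax_source_profile,
    residual_source_index,
    run_simulation,
    step,
)

DEFAULTS = ForceParams()


def cluster_state(positions: np.ndarray, r0: float = 10.0) -> SpheroidState:
    n = len(positions)
    return SpheroidState(positions=np.asarray(positions, dtype=float),
                         generations=np.zeros(n, dtype=int),
                         cycle_age_min=np.zeros(n), r0_um=r0)


class TestPairForce:
    def test_zero_at_equilibrium_and_cutoff(self):
        assert pair_force(1.106 * 10.0, DEFAULTS) == 0.0
        assert pair_force(1.5 * 10.0, DEFAULTS) == 0.0

    def test_repulsive_below_equilibrium(self):
        f = pair_force(10.0, DEFAULTS)
        assert f == pytest.approx(
            0.005 * (1 - 10 / 11.06) * (1 - 10 / 15.0), rel=1e-12)
        assert f > 0

    def test_sign_pattern_on_dense_grid(self):
        r = np.linspace(0.5, 30.0, 4000)
        f = pair_force(r, DEFAULTS)
        assert np.all(f[r < 11.06 - 1e-9] > 0)
        between = (r > 11.06 + 1e-9) & (r < 15.0 - 1e-9)
        assert np.all(f[between] < 0)
        assert np.all(f[r >= 15.0] == 0.0)

    def test_coincident_particles_rejected(self):
        with pytest.raises(CoincidentParticlesError):
            pair_force(0.0, DEFAULTS)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ConfigurationError):
            ForceParams(R=2.0, G=1.5)


class TestResidualSource:
    def test_examples(self):
        assert residual_source_index(0.0, 1000.0) == 1.0
        assert residual_source_index(1000.0, 1000.0) == 0.0
        assert residual_source_index(300.0, 1000.0) == pytest.approx(0.7)
        assert residual_source_index(2000.0, 1000.0) == 0.0  # clamped
        assert residual_source_index(1e12, math.inf) == 1.0


class TestDiffusion:
    def test_steady_state_matches_parabolic_closed_form(self):
        # alpha/D = 50 mm^-2 puts the penetration depth L = sqrt(2 Rs D/a)
        # = 200 um inside a 300 um, 200-shell grid
        a_over_d, rs, n_shells, h_um = 50.0, 1.0, 200, 1.5
        profile = relax_source_profile(rs, n_shells, h_um, a_over_d,
                                       tol=1e-13, max_iter=400_000)
        x_mm = np.arange(n_shells + 1) * h_um / 1000.0
        depth = math.sqrt(2.0 * rs / a_over_d)
        closed = np.clip(rs - (a_over_d / 2.0) * x_mm * (2 * depth - x_mm),
                         0.0, None)
        closed[x_mm >= depth] = 0.0
        assert np.abs(profile - closed).max() < 0.02 * rs

    def test_unstable_pseudo_step_rejected_with_max_reported(self):
        with pytest.raises(ConfigurationError, match="stable"):
            relax_source_profile(1.0, 50, 5.0, 20.0, pseudo_dt=1.0)

    def test_single_particle_receives_surface_value(self):
        state = cluster_state(np.zeros((1, 3)))
        n_z = diffuse_source(state, DiffusionParams(), r_t=0.8)
        assert n_z[0] == pytest.approx(0.8)

    def test_exhausted_budget_zeroes_supply(self):
        state = cluster_state(hcp_lattice(11.06, 40.0))
        n_z = diffuse_source(state, DiffusionParams(), r_t=0.0)
        assert np.all(n_z == 0.0)

    def test_supply_non_increasing_with_depth(self):
        state = cluster_state(hcp_lattice(11.06, 60.0))
        n_z = diffuse_source(state, DiffusionParams(), r_t=1.0)
        dists = state.center_distances
        depth = dists.max() - dists
        order = np.argsort(depth)
        assert np.all(np.diff(n_z[order]) <= 1e-9)


class TestDensityMobility:
    def test_isolated_particle_has_zero_density(self):
        state = cluster_state(np.zeros((1, 3)))
        assert compute_density(state, DEFAULTS)[0] == 0

    def test_hcp_interior_density_is_kissing_number(self):
        sites = hcp_lattice(DEFAULTS.equilibrium_um, 45.0)
        state = cluster_state(sites)
        density = compute_density(state, DEFAULTS)
        # the origin site is fully coordinated; second shell at
        # sqrt(2) * 11.06 = 15.64 um falls outside the 15 um cutoff
        assert density[0] == 12

    def test_mobility_clamps_and_scales(self):
        positions = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0],
                              [10.0, 0.0, 0.0]])
        state = cluster_state(positions - positions.mean(axis=0))
        p = compute_mobility(state)
        outermost = np.argmax(state.center_distances)
        assert p[outermost] == 1.0
        center_idx = np.argmin(state.center_distances)
        assert p[center_idx] >= 1e-3


class TestCellCycle:
    CP = CycleParams()  # 18 h minimum, Kc = Ke = 1

    def test_minimum_cycle_at_full_supply_zero_density(self):
        assert cell_cycle_time(1.0, 0.0, 1.0, self.CP) == pytest.approx(
            18.0 * 60.0)

    def test_half_supply_scales_cycle(self):
        # (1 + (1/0.5)^2) / (1 + 1) = 2.5 -> 45 h
        assert cell_cycle_time(0.5, 0.0, 1.0, self.CP) == pytest.approx(
            45.0 * 60.0)

    def test_starvation_means_no_division(self):
        assert cell_cycle_time(0.0, 0.0, 1.0, self.CP) == math.inf

    def test_crowding_extends_cycle(self):
        free = cell_cycle_time(1.0, 0.0, 1.0, self.CP)
        crowded = cell_cycle_time(1.0, 12.0, 0.5, self.CP)
        assert crowded == pytest.approx(free * (1 + 12.0 / 0.5))


class TestDivision:
    def test_daughters_separated_by_half_r0(self):
        rng = np.random.default_rng(0)
        d1, d2 = divide_particle(np.zeros(3), 5, 10.0, rng)
        assert np.linalg.norm(d1 - d2) == pytest.approx(5.0)

    def test_same_seed_same_direction(self):
        d = [divide_particle(np.zeros(3), 0, 10.0, np.random.default_rng(9))
             for _ in range(2)]
        assert np.allclose(d[0][0], d[1][0])

    def test_generation_increments_for_both_daughters(self):
        cfg = SimulationConfig(total_days=0.8, capacity=math.inf, seed=3)
        traj = run_simulation(cfg)
        final = traj.final_state
        assert final.n_particles == 2
        assert list(final.generations) == [1, 1]


class TestStep:
    def test_single_particle_divides_at_exactly_min_cycle(self):
        cfg = SimulationConfig(total_days=1.0, seed=1)
        state = initial_state(cfg)
        rng = np.random.default_rng(cfg.seed)
        minutes = 0
        while state.n_particles == 1:
            step(state, cfg, rng)
            minutes += 1
            assert minutes <= 1081
        assert minutes == 1080  # 18 h in 1 min steps

    def test_tiny_budget_freezes_population(self):
        cfg = SimulationConfig(total_days=1.5, capacity=1.0, seed=1)
        traj = run_simulation(cfg)
        assert np.all(traj.n_particles == 1)

    def test_overlapping_pair_separates(self):
        positions = np.array([[0.0, 0.0, 0.0], [8.0, 0.0, 0.0]])
        moved = relax_positions(positions, DEFAULTS, eta_um=1000.0,
                                max_step_um=2.0)
        assert np.linalg.norm(moved[0] - moved[1]) > 8.0


class TestRelaxation:
    def test_jittered_cluster_returns_to_equilibrium_spacing(self):
        rng = np.random.default_rng(4)
        sites = hcp_lattice(DEFAULTS.equilibrium_um, 35.0)
        positions = sites + rng.normal(0.0, 0.8, sites.shape)
        for _ in range(100):
            positions = relax_positions(positions, DEFAULTS, eta_um=1000.0,
                                        max_step_um=2.0)
        from scipy.spatial import cKDTree
        nn = cKDTree(positions).query(positions, k=2)[0][:, 1]
        assert np.median(nn) == pytest.approx(DEFAULTS.equilibrium_um,
                                              rel=0.05)

    def test_tree_pairs_match_brute_force(self):
        from spherobridge.simulator import _neighbor_pairs
        rng = np.random.default_rng(11)
        positions = rng.uniform(-30, 30, size=(80, 3))
        pairs = {tuple(sorted(p)) for p in
                 _neighbor_pairs(positions, DEFAULTS.cutoff_um)}
        brute = set()
        for i in range(len(positions)):
            for j in range(i + 1, len(positions)):
                if np.linalg.norm(positions[i] - positions[j]) \
                        < DEFAULTS.cutoff_um:
                    brute.add((i, j))
        assert pairs == brute


class TestRunSimulation:
    def test_zero_total_time_returns_initial_state_only(self):
        traj = run_simulation(SimulationConfig(total_days=0.0, seed=0))
        assert len(traj.snapshots) == 1
        assert traj.final_state.n_particles == 1

    def test_fixed_seed_is_bit_reproducible(self):
        cfg = SimulationConfig(total_days=1.2, n_initial=8, Ke=0.1,
                               capacity=1e5, seed=21,
                               initial_age_spread_h=18.0)
        t1, t2 = run_simulation(cfg), run_simulation(cfg)
        assert np.array_equal(t1.final_state.positions,
                              t2.final_state.positions)
        assert np.array_equal(t1.n_particles, t2.n_particles)

    def test_counts_monotone_and_generations_contiguous(self,
                                                        grown_trajectory):
        traj = grown_trajectory
        assert np.all(np.diff(traj.n_particles) >= 0)
        gens = np.unique(traj.final_state.generations)
        assert np.array_equal(gens, np.arange(gens.min(), gens.max() + 1))

    def test_residual_index_non_increasing(self, grown_trajectory):
        r = grown_trajectory.residual_index
        assert np.all(np.diff(r) <= 1e-12)

    def test_no_deep_overlaps_after_growth(self, grown_trajectory):
        from scipy.spatial import cKDTree
        pos = grown_trajectory.final_state.positions
        nn = cKDTree(pos).query(pos, k=2)[0][:, 1]
        assert nn.min() >= 0.5 * 10.0

    def test_validation_reports_all_errors_at_once(self):
        cfg = SimulationConfig(total_days=-1, k=-2, Kc=-1)
        with pytest.raises(ConfigurationError) as err:
            cfg.validate()
        message = str(err.value)
        assert "total_days" in message and "k must" in message \
            and "Kc" in message


class TestRadialProfiles:
    def test_single_particle_single_occupied_shell(self):
        state = cluster_state(np.zeros((1, 3)))
        profile = radial_profiles(state)
        occupied = profile[profile["n_particles"] > 0]
        assert len(occupied) == 1
        assert occupied["n_particles"].iloc[0] == 1

    def test_interior_density_near_kissing_number(self):
        state = cluster_state(hcp_lattice(DEFAULTS.equilibrium_um, 80.0))
        profile = radial_profiles(state)
        inner = profile.iloc[0]
        outer = profile.iloc[-1]
        assert inner["cell_density"] == pytest.approx(12.0, abs=1.0)
        assert outer["cell_density"] < inner["cell_density"]

    def test_source_profile_non_increasing_inward(self, grown_trajectory):
        state = grown_trajectory.final_state
        profile = radial_profiles(state)
        src = profile["source_index"].to_numpy()
        assert np.all(np.diff(src) >= -1e-9)  # increases outward
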