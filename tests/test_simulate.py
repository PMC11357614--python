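"""Engine correctness: neighbor search, forces, integrator, conservation laws."""

import math

import numpy as np
import pytest

from triblock.errors import GeometryError, InstabilityError, ParameterError
from triblock.forcefield import ChainTopology, ThermalMap
from triblock.simulate import (
    RunConfig,
    compute_forces,
    compute_forces_reference,
    init_system,
    minimum_image,
    neighbor_pairs,
    run,
    step_langevin,
)

from conftest import make_free_state, make_random_state


class TestMinimumImage:
    def test_zero_fixed(self):
        assert np.allclose(minimum_image([0.0, 0.0, 0.0], 10.0), 0.0)

    def test_wrap_and_boundary_convention(self):
        L = 10.0
        assert np.allclose(minimum_image([0.6 * L, 0, 0], L), [-0.4 * L, 0, 0])
        # half-open convention: -L/2 maps to itself, +L/2 maps to -L/2
        assert np.allclose(minimum_image([-0.5 * L, 0, 0], L), [-0.5 * L, 0, 0])
        assert np.allclose(minimum_image([+0.5 * L, 0, 0], L), [-0.5 * L, 0, 0])

    def test_components_in_range(self, rng):
        L = 7.3
        d = minimum_image(rng.uniform(-40, 40, (200, 3)), L)
        assert np.all(d >= -L / 2) and np.all(d < L / 2)


class TestInitSystem:
    def test_box_edge_closed_form(self):
        topo = ChainTopology(n_B_per_end=5, n_A=10)  # 20 beads
        st = init_system(topo, 100, 0.22, seed=0)
        assert st.box_edge == pytest.approx((2000 * (np.pi / 6) / 0.22) ** (1 / 3))

    def test_empty_system(self):
        topo = ChainTopology(n_B_per_end=1, n_A=1)
        st = init_system(topo, 0, 0.2, seed=0)
        assert st.n_beads == 0 and len(st.bonds) == 0

    def test_deterministic_per_seed(self, small_topology):
        a = init_system(small_topology, 12, 0.1, seed=42)
        b = init_system(small_topology, 12, 0.1, seed=42)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)
        c = init_system(small_topology, 12, 0.1, seed=43)
        assert not np.array_equal(a.positions, c.positions)

    def test_no_overlaps_and_wrapped(self, small_topology):
        st = init_system(small_topology, 20, 0.2, seed=3)
        assert np.all(st.positions >= 0) and np.all(st.positions < st.box_edge)
        from scipy.spatial import cKDTree

        tree = cKDTree(st.positions, boxsize=st.box_edge)
        assert len(tree.query_pairs(0.8)) == 0

    def test_volume_fraction_bounds(self, small_topology):
        with pytest.raises(ParameterError):
            init_system(small_topology, 10, 0.6, seed=0)


class TestNeighborPairs:
    def test_two_beads_inside_cutoff(self):
        st = make_free_state(2, 20.0, 1.0, 0)
        st.positions[:] = [[1.0, 1.0, 1.0], [1.0, 1.0, 2.98]]
        assert len(neighbor_pairs(st, 2.0)) == 1

    def test_periodic_image_at_full_box(self):
        st = make_free_state(2, 10.0, 1.0, 0)
        st.positions[:] = [[0.5, 5.0, 5.0], [0.5 + 10.0 - 1e-12, 5.0, 5.0]]
        st.positions %= st.box_edge
        assert len(neighbor_pairs(st, 1.0)) == 1  # distance 0 under wrapping

    def test_matches_brute_force(self, rng):
        st = make_random_state(50, 6.0, seed=9)
        r_list = 2.9
        pairs = {tuple(p) for p in neighbor_pairs(st, r_list)}
        brute = set()
        for i in range(50):
            for j in range(i + 1, 50):
                d = minimum_image(st.positions[i] - st.positions[j], st.box_edge)
                if np.linalg.norm(d) <= r_list:
                    brute.add((i, j))
        assert pairs == brute

    def test_rejects_ambiguous_cutoff(self):
        st = make_free_state(3, 5.0, 1.0, 0)
        with pytest.raises(GeometryError):
            neighbor_pairs(st, 2.6)


class TestComputeForces:
    def test_single_bead(self, params):
        st = make_free_state(1, 10.0, 1.0, 0)
        f, e = compute_forces(st, params)
        assert e == 0.0 and np.all(f == 0.0)

    def test_lj_minimum_zero_force(self, params):
        st = make_free_state(2, 20.0, 1.0, 0)
        st.bead_type[:] = 1  # both B
        st.positions[:] = [[5, 5, 5], [5, 5, 5 + 2 ** (1 / 6)]]
        f, _ = compute_forces(st, params)
        assert np.max(np.abs(f)) < 1e-10

    @pytest.mark.parametrize("bonded_chains,chain_len", [(0, 0), (3, 6)])
    def test_matches_all_pairs_oracle(self, params, bonded_chains, chain_len):
        st = make_random_state(30, 5.5, seed=21, bonded_chains=bonded_chains, chain_len=chain_len)
        f_fast, e_fast = compute_forces(st, params)
        f_ref, e_ref = compute_forces_reference(st, params)
        assert e_fast == pytest.approx(e_ref, rel=1e-10, abs=1e-10)
        assert np.max(np.abs(f_fast - f_ref)) < 1e-10

    def test_cell_list_matches_oracle_on_larger_state(self, params):
        st = make_random_state(200, 9.0, seed=4, bonded_chains=10, chain_len=8)
        f_fast, e_fast = compute_forces(st, params)
        f_ref, e_ref = compute_forces_reference(st, params)
        assert np.max(np.abs(f_fast - f_ref)) < 1e-10
        assert e_fast == pytest.approx(e_ref, rel=1e-10)

    def test_net_force_vanishes(self, params):
        st = make_random_state(120, 8.0, seed=5, bonded_chains=6, chain_len=10)
        f, _ = compute_forces(st, params)
        assert np.max(np.abs(f.sum(axis=0))) < 1e-9


class TestLangevinStep:
    def test_free_flight_when_unforced(self, params):
        st = make_free_state(8, 50.0, 1.0, 7)
        x0 = st.positions.copy()
        v0 = st.velocities.copy()
        dt = 0.01
        f = np.zeros_like(x0)
        step_langevin(st, f, dt, gamma=0.0, T=0.0, params=params)
        assert np.allclose(st.positions, (x0 + v0 * dt) % st.box_edge, atol=1e-12)
        assert np.allclose(st.velocities, v0, atol=1e-12)

    def test_equipartition(self, params):
        # free particles thermalize to mean KE per bead = (3/2) T
        T, gamma, dt, n = 1.3, 2.0, 0.01, 400
        st = make_free_state(n, 100.0, 0.2, 11)  # deliberately cold start
        f = np.zeros((n, 3))
        samples = []
        for step in range(2500):
            step_langevin(st, f, dt, gamma, T, params)
            if step >= 500 and step % 10 == 0:
                samples.append(0.5 * np.sum(st.velocities**2) / n)
        ke = np.mean(samples)
        # 3 standard errors; independent samples every 10 steps ~ gamma t = 0.2,
        # be conservative and inflate the error bar by the correlation factor
        se = np.std(samples, ddof=1) / math.sqrt(len(samples) / 6)
        assert abs(ke - 1.5 * T) < 3 * se + 0.02

    def test_velocity_autocorrelation_is_ou(self, params):
        # BAOAB for a free particle is an exact OU discretization:
        # <v(0) v(t)> / <v^2> = exp(-gamma t)
        T, gamma, dt, n = 1.0, 1.5, 0.01, 600
        st = make_free_state(n, 120.0, T, 13)
        f = np.zeros((n, 3))
        for _ in range(1000):  # burn-in
            step_langevin(st, f, dt, gamma, T, params)
        vs = [st.velocities.copy()]
        for _ in range(120):
            step_langevin(st, f, dt, gamma, T, params)
            vs.append(st.velocities.copy())
        v0 = vs[0]
        denom = np.mean(v0 * v0)
        for lag in (20, 60, 120):
            acf = np.mean(v0 * vs[lag]) / denom
            assert acf == pytest.approx(math.exp(-gamma * lag * dt), abs=0.06)

    def test_instability_reports_bead(self, params):
        st = make_free_state(4, 20.0, 1.0, 3)
        st.velocities[2] = np.array([np.inf, 0, 0])
        with pytest.raises(InstabilityError, match="bead 2"):
            step_langevin(st, np.zeros((4, 3)), 0.01, 0.0, 0.0, params)


class TestNVEConservation:
    def test_energy_and_momentum_conserved(self, params):
        # gamma = 0 reduces BAOAB to velocity Verlet: symplectic drift bound
        st = make_random_state(60, 7.0, seed=17, bonded_chains=5, chain_len=6)
        st.velocities *= 0.3
        dt = 0.001
        f, e0 = compute_forces(st, params)
        p0 = st.velocities.sum(axis=0).copy()
        energies = []
        for step in range(10_000):
            f, epot = step_langevin(st, f, dt, 0.0, 0.0, params)
            if step % 500 == 0:
                ekin = 0.5 * np.sum(st.velocities**2)
                energies.append(epot + ekin)
        drift = abs(energies[-1] - energies[0]) / abs(energies[0])
        assert drift < 1e-4
        assert np.max(np.abs(st.velocities.sum(axis=0) - p0)) < 1e-9


class TestRun:
    def _config(self, **kw):
        base = dict(
            topology=ChainTopology(n_B_per_end=2, n_A=4),
            n_chains=10,
            volume_fraction=0.1,
            temperature=0.6,
            n_warmup=50,
            n_equil=100,
            n_prod=100,
            stride=50,
            seed=5,
        )
        base.update(kw)
        return RunConfig(**base)

    def test_zero_production_yields_single_frame(self):
        traj = run(self._config(n_prod=0))
        assert len(traj.frames) == 1

    def test_reproducible_from_seed(self, tmp_path):
        t1 = run(self._config(), xyz_path=tmp_path / "a.xyz")
        t2 = run(self._config(), xyz_path=tmp_path / "b.xyz")
        assert (tmp_path / "a.xyz").read_text() == (tmp_path / "b.xyz").read_text()
        for f1, f2 in zip(t1.frames, t2.frames):
            assert np.array_equal(f1.positions, f2.positions)

    def test_frames_at_stride_with_increasing_times(self):
        traj = run(self._config(n_prod=150, stride=50))
        assert len(traj.frames) == 1 + 3
        times = [f.time for f in traj.frames]
        assert all(b > a for a, b in zip(times, times[1:]))

    def test_aggregation_at_low_temperature(self):
        # physical sanity: sticky B beads develop excess B-B coordination
        cfg = self._config(
            n_chains=30, temperature=0.5, n_warmup=500, n_equil=4000, n_prod=500,
            tmap=ThermalMap(),
        )
        traj = run(cfg)
        fr = traj.frames[-1]
        from scipy.spatial import cKDTree

        bpos = fr.positions[fr.bead_type == 1]
        tree = cKDTree(bpos % fr.box_edge, boxsize=fr.box_edge)
        n_bb = len(tree.query_pairs(1.3))
        coord = 2 * n_bb / len(bpos)
        # ideal-gas expectation at this density is far below one neighbor
        rho = len(bpos) / fr.box_edge**3
        ideal = rho * 4 / 3 * np.pi * 1.3**3
        assert coord > 2 * ideal
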