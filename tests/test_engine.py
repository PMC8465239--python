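"""Engine: pair/bond/angle forces, neighbor search, integrator, thermostat."""

import numpy as np
import pytest

import dpdlipid as d
from dpdlipid import _kernels
from dpdlipid.builder import SystemState, SystemTopology
from dpdlipid.engine import IntegrationBlowupError


def _two_bead_state(r, box=10.0, species=(0, 0), vel=None):
    pos = np.array([[1.0, 1.0, 1.0], [1.0 + r, 1.0, 1.0]])
    v = np.zeros((2, 3)) if vel is None else np.asarray(vel, float)
    return SystemState(pos, v, np.array(species), np.array([-1, -1]),
                       np.array([box] * 3), 0)


def _sim(state, topo=None, **kw):
    return d.Simulation(state, topo, **kw)


class TestWeightFunction:
    def test_piecewise_linear_values(self):
        assert d.weight(0.0) == 1.0
        assert d.weight(0.5) == 0.5
        assert d.weight(1.2) == 0.0
        assert d.weight(1.0) == 0.0

    def test_vectorized_and_negative_rejected(self):
        np.testing.assert_allclose(d.weight(np.array([0.25, 2.0])),
                                   [0.75, 0.0])
        with pytest.raises(ValueError):
            d.weight(-0.1)


class TestPairForces:
    def test_conservative_magnitude_at_half_cutoff(self):
        state = _two_bead_state(0.5)
        sim = _sim(state, params=d.DPDParams(gamma=0.0))
        f, _, _ = sim.compute_forces()
        # a=25, w=0.5 -> |F| = 12.5, equal and opposite along x
        np.testing.assert_allclose(f[0], [-12.5, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f[1], [12.5, 0, 0], atol=1e-12)

    def test_dissipative_vanishes_at_rest(self):
        # gamma on, sigma off (kBT=0): beads at rest feel only the
        # conservative repulsion
        state = _two_bead_state(0.5)
        p = d.DPDParams(gamma=4.5, kBT=0.0)
        f, _, _ = _sim(state, params=p).compute_forces()
        np.testing.assert_allclose(f[0], [-12.5, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f[1], [12.5, 0, 0], atol=1e-12)

    def test_dissipative_opposes_radial_velocity(self):
        vel = [[0.0, 0, 0], [1.0, 0, 0]]  # beads separating along x
        state = _two_bead_state(0.5, vel=vel)
        p = d.DPDParams(gamma=4.5, kBT=0.0)  # sigma = 0, pure drag
        f, _, _ = _sim(state, params=p).compute_forces()
        # F_D on j = -gamma w^2 (e.v_ij) e with v_ij = v_j - v_i = +x
        expect = -4.5 * 0.25 * 1.0
        conservative = 12.5
        assert f[1, 0] == pytest.approx(conservative + expect)

    def test_newtons_third_law_total_force_zero(self, relaxed_water):
        state, topo = relaxed_water
        f, _, _ = _sim(state.copy(), topo, seed=3).compute_forces()
        assert np.all(np.abs(f.sum(axis=0)) < 1e-9)

    def test_noise_is_symmetric_under_pair_order(self):
        base = np.uint64(_kernels.noise_base(12, 34))
        assert _kernels._pair_noise.py_func(base, 5, 9) == \
            _kernels._pair_noise.py_func(base, 9, 5)

    def test_noise_has_unit_variance(self):
        base = np.uint64(_kernels.noise_base(1, 2))
        vals = np.array([_kernels._pair_noise.py_func(base, 0, j)
                         for j in range(1, 20001)])
        assert vals.var() == pytest.approx(1.0, rel=0.03)
        assert abs(vals.mean()) < 0.02


class TestBondForces:
    def _bonded_pair(self, r):
        state = _two_bead_state(r)
        topo = SystemTopology.empty()
        topo.bond_ij = np.array([[0, 1]], dtype=np.int64)
        topo.bond_ks = np.array([120.0])
        topo.bond_rs = np.array([0.7])
        return state, topo

    @pytest.mark.parametrize("r,coef", [
        (0.7, 0.0),        # at the equilibrium length
        (0.35, 60.0),      # compressed to rs/2: ks*(1-0.5)
        (1.4, -120.0),     # stretched to 2rs: ks*(1-2)
    ])
    def test_force_coefficient(self, r, coef):
        state, topo = self._bonded_pair(r)
        sim = _sim(state, topo, params=d.DPDParams(gamma=0.0))
        f, _, _ = sim.compute_forces()
        f_bond = f[0, 0] - (-25.0 * max(0.0, 1.0 - r))  # subtract pair part
        # positive coef pushes bead 0 away from bead 1 (-x direction)
        assert f_bond == pytest.approx(-coef, abs=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        pos = rng.uniform(2, 4, size=(4, 3))
        topo = SystemTopology.empty()
        topo.bond_ij = np.array([[0, 1], [1, 2], [2, 3]], dtype=np.int64)
        topo.bond_ks = np.full(3, 120.0)
        topo.bond_rs = np.full(3, 0.7)
        box = np.full(3, 50.0)
        f = np.zeros_like(pos)
        vir = np.zeros(3)
        _kernels.bond_forces(pos, topo.bond_ij, topo.bond_ks, topo.bond_rs,
                             box, f, vir)

        def energy(p):
            ff = np.zeros_like(p)
            vv = np.zeros(3)
            return _kernels.bond_forces(p, topo.bond_ij, topo.bond_ks,
                                        topo.bond_rs, box, ff, vv)

        h = 1e-6
        for i in range(4):
            for a in range(3):
                dp = pos.copy()
                dp[i, a] += h
                dm = pos.copy()
                dm[i, a] -= h
                fd = -(energy(dp) - energy(dm)) / (2 * h)
                assert f[i, a] == pytest.approx(fd, abs=1e-6)


class TestAngleForces:
    def _triple(self, pos, k=3.0, t0=2 * np.pi / 3):
        topo = SystemTopology.empty()
        topo.angle_ijk = np.array([[0, 1, 2]], dtype=np.int64)
        topo.angle_k = np.array([k])
        topo.angle_t0 = np.array([t0])
        return np.asarray(pos, float), topo

    def _eval(self, pos, topo, box=50.0):
        f = np.zeros_like(pos)
        vir = np.zeros(3)
        e = _kernels.angle_forces(pos, topo.angle_ijk, topo.angle_k,
                                  topo.angle_t0, np.full(3, box), f, vir)
        return f, e

    def test_zero_force_at_equilibrium_angle(self):
        c, s = np.cos(np.pi / 3), np.sin(np.pi / 3)  # 120 deg at vertex
        pos, topo = self._triple([[1.0, 0, 0], [0, 0, 0], [-c, s, 0]])
        f, e = self._eval(pos, topo)
        assert np.all(np.abs(f) < 1e-12)
        assert e == pytest.approx(0.0, abs=1e-20)

    def test_straight_triple_energy_against_potential(self):
        pos, topo = self._triple([[1.0, 0, 0], [0, 0, 0], [-1.0, 0, 0]],
                                 k=3.0)
        _, e = self._eval(pos, topo)
        assert e == pytest.approx(3.0 * (np.pi / 3) ** 2)  # ~3.29

    def test_net_force_and_torque_vanish(self, rng):
        pos, topo = self._triple(rng.uniform(1, 3, size=(3, 3)))
        f, _ = self._eval(pos, topo)
        assert np.all(np.abs(f.sum(axis=0)) < 1e-12)
        torque = np.cross(pos, f).sum(axis=0)
        assert np.all(np.abs(torque) < 1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        for _ in range(5):
            pos, topo = self._triple(rng.uniform(1, 3, size=(3, 3)),
                                     k=6.0, t0=np.pi * 0.9)
            f, _ = self._eval(pos, topo)
            h = 1e-6
            for i in range(3):
                for a in range(3):
                    dp = pos.copy()
                    dp[i, a] += h
                    dm = pos.copy()
                    dm[i, a] -= h
                    fd = -(self._eval(dp, topo)[1]
                           - self._eval(dm, topo)[1]) / (2 * h)
                    assert f[i, a] == pytest.approx(fd, abs=1e-6)


class TestNeighborSearch:
    def test_cell_list_matches_brute_force_on_random_boxes(self, rng):
        for trial in range(100):
            box = np.array([rng.uniform(3.2, 9.0) for _ in range(3)])
            n = int(rng.integers(80, 400))
            pos = rng.uniform(size=(n, 3)) * box
            pi_c, pj_c = _kernels.find_pairs(pos, box, 1.0)
            npairs = _kernels._count_pairs_brute(pos, box, 1.0)
            pi_b = np.empty(npairs, dtype=np.int64)
            pj_b = np.empty(npairs, dtype=np.int64)
            _kernels._fill_pairs_brute(pos, box, 1.0, pi_b, pj_b)
            cell = {tuple(sorted(p)) for p in zip(pi_c, pj_c)}
            brute = {tuple(sorted(p)) for p in zip(pi_b, pj_b)}
            assert cell == brute, f"pair sets differ on trial {trial}"


class TestIntegrator:
    def test_free_flight_displacement(self):
        state = _two_bead_state(5.0)  # out of range: no forces
        state.velocities[0] = [1.0, 0.0, 0.0]
        x0 = state.positions[0, 0]
        sim = _sim(state, params=d.DPDParams(gamma=0.0))
        sim.step()
        assert state.positions[0, 0] - x0 == pytest.approx(0.01)

    def test_harmonic_bond_energy_bounded_over_long_run(self):
        # single bond, no thermostat: energy oscillates but does not drift
        state = _two_bead_state(0.9, box=50.0)
        topo = SystemTopology.empty()
        topo.bond_ij = np.array([[0, 1]], dtype=np.int64)
        topo.bond_ks = np.array([120.0])
        topo.bond_rs = np.array([0.7])
        sim = _sim(state, topo, params=d.DPDParams(gamma=0.0))
        e0 = sum(sim.total_energy())
        drifts = []
        for _ in range(10):
            sim.run(1000)
            drifts.append(sum(sim.total_energy()) - e0)
        # O(dt^2) bounded oscillation, no secular growth
        assert max(abs(x) for x in drifts) < 0.05
        assert abs(drifts[-1]) < 0.05

    def test_conservative_field_energy_drift(self, relaxed_water):
        state, topo = relaxed_water
        st = state.copy()
        sim = _sim(st, topo, params=d.DPDParams(gamma=0.0), seed=4)
        e0 = sum(sim.total_energy())
        sim.run(1000)
        e1 = sum(sim.total_energy())
        assert abs(e1 - e0) / st.n_beads < 1e-3

    def test_momentum_conserved_over_thermostatted_run(self, relaxed_water):
        state, topo = relaxed_water
        st = state.copy()
        st.zero_net_momentum()
        sim = _sim(st, topo, seed=9)
        sim.run(2000)
        assert np.all(np.abs(st.net_momentum()) < 1e-8)

    def test_same_seed_bitwise_reproducible(self, water_cfg):
        outs = []
        for _ in range(2):
            st, topo = d.random_initial_configuration(water_cfg, seed=13)
            sim = _sim(st, topo, seed=13)
            sim.run(100)
            outs.append((st.positions.copy(), st.velocities.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])

    def test_zero_steps_leaves_state_unchanged(self, water_cfg):
        st, topo = d.random_initial_configuration(water_cfg, seed=2)
        ref = st.copy()
        _sim(st, topo, seed=2).run(0)
        assert np.array_equal(st.positions, ref.positions)
        assert st.step_index == 0

    def test_blowup_detection_names_the_step(self):
        state = _two_bead_state(0.5)
        state.velocities[0] = [np.inf, 0, 0]
        sim = _sim(state, params=d.DPDParams(gamma=0.0))
        with pytest.raises(IntegrationBlowupError, match="step"):
            sim.run(150)


class TestEnergyAndPressure:
    def test_out_of_range_pair_has_zero_potential(self):
        state = _two_bead_state(1.5)
        epot, _ = _sim(state).total_energy()
        assert epot == 0.0

    def test_conservative_force_is_minus_energy_gradient(self, rng):
        # brute-force gradient oracle on a small random bonded system
        cfg = d.RunConfig(box_lengths=(6.0, 6.0, 6.0), n_lipids_1=2,
                          n_lipids_2=2, nt1=2, nt2=2, total_steps=0)
        state, topo = d.random_initial_configuration(cfg, seed=8)
        sim = _sim(state, topo)
        f, _, _ = sim.compute_forces(thermostat=False)
        h = 1e-6
        for i in rng.integers(0, state.n_beads, size=6):
            for a in range(3):
                pp = state.positions.copy()
                pp[i, a] += h
                pm = state.positions.copy()
                pm[i, a] -= h
                ep = sim.compute_forces(positions=pp, thermostat=False)[1]
                em = sim.compute_forces(positions=pm, thermostat=False)[1]
                assert f[i, a] == pytest.approx(-(ep - em) / (2 * h),
                                                abs=2e-5)

    def test_ideal_gas_equipartition(self, rng):
        n = 4000
        pos = rng.uniform(size=(n, 3)) * 10.0
        vel = rng.normal(size=(n, 3))
        vel -= vel.mean(axis=0)
        state = SystemState(pos, vel, np.zeros(n, dtype=np.int64),
                            np.full(n, -1), np.full(3, 10.0), 0)
        sim = _sim(state, params=d.DPDParams(rc=1e-6))  # no interactions
        epot, ekin = sim.total_energy()
        assert epot == 0.0
        assert ekin / n == pytest.approx(1.5, rel=0.05)

    def test_global_pressure_matches_ideal_plus_virial_scale(self,
                                                             relaxed_water):
        state, topo = relaxed_water
        p = _sim(state.copy(), topo).pressure_tensor_diag()
        # DPD equation of state: p ~ rho kBT + alpha a rho^2, alpha ~ 0.1
        assert np.all(p > 3.0)
        assert p.std() / p.mean() < 0.05
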