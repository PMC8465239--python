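"""Observables: density, order parameter, gyration, shape, pressure, tension."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dpdlipid as d
from dpdlipid import analysis as an
from dpdlipid.builder import SystemState


def _point_state(points, box=10.0, species=None):
    pts = np.atleast_2d(np.asarray(points, float))
    n = pts.shape[0]
    sp = (np.zeros(n, dtype=np.int64) if species is None
          else np.asarray(species, dtype=np.int64))
    return SystemState(pts, np.zeros_like(pts), sp, np.full(n, -1),
                       np.full(3, float(box)), 0)


class TestDensityProfile:
    def test_uniform_water_box_at_target_density(self, relaxed_water):
        state, _ = relaxed_water
        prof = d.density_profile(state, d.Species.WATER, n_bins=6)
        np.testing.assert_allclose(prof.values["WATER"], 3.0, atol=0.5)

    def test_single_bead_occupies_one_bin(self):
        state = _point_state([[5.0, 5.0, 2.5]], box=10.0)
        prof = d.density_profile(state, d.Species.WATER, n_bins=10)
        v = prof.values["WATER"]
        bin_volume = 10.0 * 10.0 * 1.0
        assert v[2] == pytest.approx(1.0 / bin_volume)
        assert np.count_nonzero(v) == 1

    def test_profile_integrates_to_bead_count(self, bilayer_run):
        state, _, _, cfg = bilayer_run
        prof = d.density_profile(state, None, n_bins=24)
        bin_vol = np.prod(state.box) / 24
        for name, vals in prof.values.items():
            count = int(np.sum(state.species == int(d.Species[name])))
            assert vals.sum() * bin_vol == pytest.approx(count, abs=0.5)

    def test_periodic_translation_rolls_the_profile(self, bilayer_run):
        state, _, _, _ = bilayer_run
        prof = d.density_profile(state, d.Species.TAIL1, n_bins=12)
        shifted = state.copy()
        shifted.positions[:, 2] += 2 * state.box[2] / 12  # two whole bins
        shifted.wrap()
        prof2 = d.density_profile(shifted, d.Species.TAIL1, n_bins=12)
        np.testing.assert_allclose(np.roll(prof.values["TAIL1"], 2),
                                   prof2.values["TAIL1"], atol=1e-9)

    def test_empty_selection_rejected(self, relaxed_water):
        state, _ = relaxed_water
        with pytest.raises(ValueError, match="empty species"):
            d.density_profile(state, [], n_bins=5)


class TestOrderParameter:
    def test_chains_along_z_give_one(self):
        p2, _ = an.p2_order(np.tile([0.0, 0.0, 1.0], (100, 1)))
        assert p2.mean() == pytest.approx(1.0)

    def test_chains_in_plane_give_minus_half(self, rng):
        v = np.column_stack([rng.normal(size=(200, 2)), np.zeros(200)])
        p2, _ = an.p2_order(v)
        np.testing.assert_allclose(p2, -0.5, atol=1e-12)

    def test_isotropic_orientations_average_to_zero(self):
        rng = np.random.default_rng(42)
        v = rng.normal(size=(100_000, 3))
        p2, _ = an.p2_order(v)
        assert abs(p2.mean()) < 0.01

    def test_bounds_and_reversal_invariance(self, rng):
        v = rng.normal(size=(500, 3))
        p2, _ = an.p2_order(v)
        assert np.all(p2 >= -0.5 - 1e-12) and np.all(p2 <= 1.0 + 1e-12)
        p2r, _ = an.p2_order(-v)
        np.testing.assert_allclose(p2, p2r, atol=1e-12)

    def test_zero_length_vectors_excluded_and_counted(self):
        vecs = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 2.0]])
        p2, n_excluded = an.p2_order(vecs)
        assert n_excluded == 1
        assert p2.shape == (1,)

    def test_profile_bins_by_head_centroid(self, bilayer_run):
        state, topo, _, cfg = bilayer_run
        prof = an.order_parameter_profile(state, topo, n_bins=12,
                                          lipid_type=1)
        counts = prof.counts["P2_type1"]
        # all 150 type-1 chains binned exactly once
        assert counts.sum() == 150
        # the two leaflets keep distinct head-centroid heights
        _, c1, _ = an.chain_head_vectors(state, topo, 1)
        _, c2, _ = an.chain_head_vectors(state, topo, 2)
        assert np.median(c1[:, 2] % state.box[2]) < \
            np.median(c2[:, 2] % state.box[2])


class TestGyrationTensor:
    def test_two_point_mass_distribution(self):
        g = an.gyration_tensor(np.array([[-1.5, 0, 0], [1.5, 0, 0]]))
        assert g.tensor[0, 0] == pytest.approx(1.5**2)  # (d/2)^2, d=3
        assert np.all(np.abs(g.tensor.ravel()[1:]) < 1e-14)

    def test_unit_axis_vertices_give_isotropic_third(self):
        verts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                          [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
        g = an.gyration_tensor(verts)
        np.testing.assert_allclose(g.tensor, np.eye(3) / 3.0, atol=1e-14)

    def test_eigenvalue_sum_equals_trace(self, rng):
        xyz = rng.normal(size=(13, 3))
        g = an.gyration_tensor(xyz)
        assert g.eigenvalues.sum() == pytest.approx(g.tensor.trace(),
                                                    abs=1e-10)
        assert g.eigenvalues[0] >= g.eigenvalues[1] >= g.eigenvalues[2]

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            an.gyration_tensor(np.array([[1.0, 2.0, 3.0]]))


class TestShapeFactor:
    def test_collinear_chain_is_one(self):
        xyz = np.column_stack([np.linspace(0, 8.4, 13),
                               np.zeros(13), np.zeros(13)])
        assert d.shape_factor(an.gyration_tensor(xyz)) == pytest.approx(1.0)

    def test_equal_eigenvalues_give_zero(self):
        assert d.shape_factor(np.array([2.0, 2.0, 2.0])) == pytest.approx(0.0)

    def test_flat_disc_limit(self):
        assert d.shape_factor(np.array([1.0, 1.0, 0.0])) == pytest.approx(0.25)

    def test_point_distribution_rejected(self):
        with pytest.raises(ValueError):
            d.shape_factor(np.zeros(3))

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=100)
    def test_invariant_under_rotation_and_scaling(self, seed):
        rng = np.random.default_rng(seed)
        xyz = rng.normal(size=(9, 3))
        delta = d.shape_factor(an.gyration_tensor(xyz))
        assert -1e-9 <= delta <= 1.0 + 1e-9
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y*y + z*z), 2 * (x*y - w*z), 2 * (x*z + w*y)],
            [2 * (x*y + w*z), 1 - 2 * (x*x + z*z), 2 * (y*z - w*x)],
            [2 * (x*z - w*y), 2 * (y*z + w*x), 1 - 2 * (x*x + y*y)],
        ])
        scale = rng.uniform(0.1, 10.0)
        transformed = scale * xyz @ rot.T + rng.normal(size=3)
        delta2 = d.shape_factor(an.gyration_tensor(transformed))
        assert delta2 == pytest.approx(delta, abs=1e-9)


class TestChainSeries:
    def test_unwrap_restores_bonds_across_boundary(self, bilayer_run):
        state, topo, _, _ = bilayer_run
        shifted = state.copy()
        shifted.positions[:, 2] += shifted.box[2] / 2  # split the membrane
        shifted.wrap()
        for chain in (0, topo.n_chains - 1):
            xyz = d.unwrap_chain(shifted, topo, chain)
            tmpl = topo.templates[int(topo.chain_type[chain])]
            for b in tmpl.bonds:
                assert np.linalg.norm(xyz[b.i] - xyz[b.j]) < 2.0

    def test_preassembled_chains_elongated_along_z(self, bilayer_run):
        _, topo, frames, _ = bilayer_run
        df = d.rg_components_series(frames[0], topo, 1)
        row = df.iloc[0]
        assert row.Rgzz > row.Rgxx
        assert row.Rgzz > row.Rgyy
        assert row.Rgxx == pytest.approx(row.Rgyy, abs=0.05)

    def test_membrane_aggregate_spread_in_plane(self, bilayer_run):
        state, topo, _, _ = bilayer_run
        df = d.membrane_gyration_components(state, topo, 1)
        row = df.iloc[0]
        assert row.Rgxx > row.Rgzz and row.Rgyy > row.Rgzz
        assert row.Rgxx == pytest.approx(row.Rgyy, rel=0.2)

    def test_series_deterministic_on_frozen_frame(self, bilayer_run):
        state, topo, _, _ = bilayer_run
        a = d.rg_components_series(state, topo, 2)
        b = d.rg_components_series(state, topo, 2)
        assert a.equals(b)

    def test_shape_factor_series_in_range(self, bilayer_run):
        _, topo, frames, _ = bilayer_run
        df = d.shape_factor_series(frames[-1], topo, 1)
        assert 0.0 <= df.delta.iloc[0] <= 1.0


class TestPressureAndTension:
    def test_ideal_gas_pressure_is_rho_kbt(self, rng):
        n = 6000
        box = np.full(3, 10.0)
        pos = rng.uniform(size=(n, 3)) * box
        vel = rng.normal(size=(n, 3))
        vel -= vel.mean(axis=0)
        state = SystemState(pos, vel, np.zeros(n, dtype=np.int64),
                            np.full(n, -1), box, 0)
        pp = d.pressure_profile(state, n_slabs=5,
                                params=d.DPDParams(rc=1e-6))
        rho_kbt = n / box.prod()  # ~6 here; exact per-slab up to sampling
        for comp in (pp.pxx, pp.pyy, pp.pzz):
            np.testing.assert_allclose(comp, rho_kbt, rtol=0.15)

    def test_slab_average_equals_global_virial(self, bilayer_run):
        state, topo, _, cfg = bilayer_run
        table = d.interaction_table()
        pp = d.pressure_profile(state, 16, table, topo, cfg.params)
        sim = d.Simulation(state.copy(), topo, table, cfg.params)
        glob = sim.pressure_tensor_diag()
        np.testing.assert_allclose(pp.global_components(), glob, rtol=1e-6)

    def test_bulk_water_tension_vanishes_within_error(self, water_window):
        frames, topo = water_window
        per_frame = np.array([
            d.tension_profile(d.pressure_profile(f, 6)).values["sigma_z"]
            for f in frames
        ])
        mean = per_frame.mean(axis=0)
        se = per_frame.std(axis=0, ddof=1) / np.sqrt(per_frame.shape[0])
        assert np.all(np.abs(mean) < 3 * se + 0.05)

    def test_isotropic_input_gives_exact_zero(self):
        pp = an.PressureProfile(np.linspace(0, 10, 6), np.full(5, 3.0),
                                np.full(5, 3.0), np.full(5, 3.0), 1,
                                np.full(3, 10.0))
        sigma = d.tension_profile(pp).values["sigma_z"]
        np.testing.assert_array_equal(sigma, 0.0)
        assert an.integrated_tension(pp) == 0.0

    def test_translation_leaves_global_components_unchanged(
            self, bilayer_run):
        state, topo, _, cfg = bilayer_run
        table = d.interaction_table()
        pp1 = d.pressure_profile(state, 8, table, topo, cfg.params)
        shifted = state.copy()
        shifted.positions += np.array([1.3, 2.1, 3.7])
        shifted.wrap()
        pp2 = d.pressure_profile(shifted, 8, table, topo, cfg.params)
        np.testing.assert_allclose(pp1.global_components(),
                                   pp2.global_components(), rtol=1e-9)

    def test_too_few_slabs_rejected(self, relaxed_water):
        state, _ = relaxed_water
        with pytest.raises(ValueError):
            d.pressure_profile(state, n_slabs=1)
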