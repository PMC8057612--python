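"""Discretization and time stepping."""

import numpy as np
import pytest

from plaquesim import (
    DomainGeometry,
    InitialConditions,
    NumericalError,
    ParameterError,
    ParameterSet,
    Region,
    SolverConfig,
    StateFields,
    euler_step,
    laplacian,
    nondimensionalize,
    redimensionalize,
    run_simulation,
    stable_timestep,
    taxis_divergence,
)
from plaquesim.state import SPECIES


def _strip_geometry(width: int = 9) -> DomainGeometry:
    labels = np.zeros((3, width), dtype=np.int8)
    labels[1, 0] = Region.LUMEN
    labels[1, 1:width - 1] = Region.INTIMA
    return DomainGeometry(labels=labels, h=1.0)


class TestLaplacian:
    def test_constant_field_is_harmonic(self, small_geometry):
        field = np.where(small_geometry.tissue_mask, 3.7, 0.0)
        assert np.all(laplacian(field, small_geometry) == 0.0)

    def test_linear_ramp_vanishes_at_interior(self):
        g = _strip_geometry()
        x = np.arange(g.n_cols)[None, :] * np.ones((3, 1))
        field = np.where(g.tissue_mask, x, 0.0)
        lap = laplacian(field, g, h=1.0)
        # interior strip cells have both horizontal neighbours in-domain
        assert np.allclose(lap[1, 2:-2], 0.0)

    def test_quadratic_second_derivative(self):
        g = _strip_geometry()
        h = 0.25
        x = np.arange(g.n_cols)[None, :] * h * np.ones((3, 1))
        field = np.where(g.tissue_mask, x * x, 0.0)
        lap = laplacian(field, g, h=h)
        assert np.allclose(lap[1, 2:-2], 2.0)


class TestTaxisDivergence:
    def test_conservation_on_closed_domain(self, small_geometry):
        rng = np.random.default_rng(11)
        g = small_geometry
        tissue = g.tissue_mask
        C = np.where(tissue, rng.uniform(0, 2, g.labels.shape), 0.0)
        A = np.where(tissue, rng.uniform(0, 1, g.labels.shape), 0.0)
        div = taxis_divergence(C, A, 1e-3, g)
        assert abs(div.sum()) < 1e-12 * np.abs(div).sum()

    def test_five_cell_hand_stencil(self):
        g = _strip_geometry(7)
        h, lam = 1.0, 2.0
        C = np.zeros((3, 7))
        A = np.zeros((3, 7))
        C[1, 1:6] = [1.0, 2.0, 3.0, 2.0, 1.0]
        A[1, 1:6] = [0.0, 1.0, 3.0, 1.0, 0.0]
        div = taxis_divergence(C, A, lam, g, h=h)
        # face fluxes J_(i,i+1) = lam * (C_i+C_{i+1})/2 * (A_{i+1}-A_i)/h
        J = [lam * (C[1, i] + C[1, i + 1]) / 2 * (A[1, i + 1] - A[1, i]) / h
             for i in range(1, 5)]
        expected = [-J[0], J[0] - J[1], J[1] - J[2], J[2] - J[3], J[3]]
        assert np.allclose(div[1, 1:6], expected)


class TestStableTimestep:
    def test_diffusion_bound_formula(self, small_geometry):
        p = ParameterSet(diffusion={sp: 1.0 for sp in SPECIES})
        cfg = SolverConfig(safety_factor=1.0)
        h = 1.0 / small_geometry.n_cols
        assert stable_timestep(p, cfg, small_geometry) == pytest.approx(h * h / 4.0)

    def test_halving_h_quarters_dt(self):
        p = ParameterSet()
        cfg = SolverConfig()

        def dt_at(n):
            labels = np.zeros((n, n), dtype=np.int8)
            labels[n // 2, n // 2] = Region.LUMEN
            labels[n // 2, n // 2 + 1] = Region.INTIMA
            g = DomainGeometry(labels=labels, h=1.0)
            return stable_timestep(p, cfg, g)

        assert dt_at(40) == pytest.approx(4.0 * dt_at(80))

    def test_no_diffusion_no_taxis_returns_configured_dt(self, small_geometry):
        p = ParameterSet(diffusion={sp: 0.0 for sp in SPECIES})
        cfg = SolverConfig(dt=0.125)
        assert stable_timestep(p, cfg, small_geometry) == 0.125

    def test_taxis_velocity_tightens_the_bound(self, small_geometry, params):
        g = small_geometry
        state = StateFields.zeros(g)
        tissue = g.tissue_mask
        state["Ma"][tissue] = 1.0
        # steep artificial MCP-1 gradient to drive a large taxis velocity
        col = np.arange(g.n_cols)[None, :] * np.ones((g.n_rows, 1))
        state["P"][tissue] = (col * 500.0)[tissue]
        cfg = SolverConfig()
        dt_plain = stable_timestep(params, cfg, g)
        dt_taxis = stable_timestep(params, cfg, g, state=state)
        assert dt_taxis < dt_plain


class TestEulerStep:
    def test_pure_decay_matches_closed_form(self, small_geometry, inert_params):
        g = small_geometry
        k, dt, n = 1.0, 0.01, 100
        p = inert_params.replace(d_P=k)
        state = StateFields.zeros(g)
        tissue = g.tissue_mask
        state["P"][tissue] = 1.0
        for _ in range(n):
            state, _ = euler_step(state, p, g, dt)
        exact_euler = (1.0 - k * dt) ** n
        assert state["P"][tissue] == pytest.approx(exact_euler, rel=1e-12)
        # first-order accuracy against the continuous solution
        assert abs(exact_euler - np.exp(-k * n * dt)) < k * k * n * dt * dt

    def test_diffusion_only_conserves_mass(self, small_geometry, inert_params):
        g = small_geometry
        p = inert_params.replace(diffusion={**inert_params.diffusion, "L": 1e-3})
        rng = np.random.default_rng(2)
        state = StateFields.zeros(g)
        tissue = g.tissue_mask
        state["L"][tissue] = rng.uniform(0.5, 1.5, int(tissue.sum()))
        total0 = state["L"].sum()
        dt = stable_timestep(p, SolverConfig(), g)
        for _ in range(200):
            state, diag = euler_step(state, p, g, dt)
        assert abs(state["L"].sum() - total0) / total0 < 1e-12

    def test_zero_dt_is_identity(self, small_geometry, params, mild_init):
        state = mild_init.build(small_geometry)
        new, diag = euler_step(state, params, small_geometry, 0.0)
        np.testing.assert_array_equal(new.data, state.data)
        assert diag["clip_count"] == 0

    def test_nonfinite_state_aborts_with_species_diagnostic(self, small_geometry, params):
        state = StateFields.zeros(small_geometry)
        r, c = next(iter(small_geometry.endothelium_cells))
        state["S"][r, c] = np.inf
        with pytest.raises(NumericalError, match="cell"):
            euler_step(state, params, small_geometry, 0.01)


class TestNondimensionalization:
    def test_smc_media_reference_scale(self, small_geometry, mild_init):
        # 6e-3 g/cm^3 in media divided by its reference gives exactly 1
        state = mild_init.build(small_geometry)
        assert np.all(state["S"][small_geometry.media_mask] == 1.0)
        scales = mild_init.reference_scales()
        assert scales["S"] == 6e-3

    def test_round_trip_identity(self, small_geometry, mild_init):
        state = mild_init.build(small_geometry)
        scales = {sp: (i + 1) * 1e-3 for i, sp in enumerate(SPECIES)}
        back = redimensionalize(nondimensionalize(state, scales), scales)
        np.testing.assert_allclose(back.data, state.data, rtol=1e-14)

    def test_zero_reference_scale_rejected(self, small_geometry, mild_init):
        state = mild_init.build(small_geometry)
        scales = {sp: 1.0 for sp in SPECIES}
        scales["L"] = 0.0
        with pytest.raises(ParameterError):
            nondimensionalize(state, scales)

    def test_scaled_and_unscaled_decay_are_equivalent(self, small_geometry, inert_params):
        """Simulating the scaled equation reproduces the unscaled trajectory."""
        g = small_geometry
        k, dt, n = 0.7, 0.02, 50
        p = inert_params.replace(d_P=k)
        tissue = g.tissue_mask
        ref = 4.2  # reference concentration for the scaled path

        phys = StateFields.zeros(g)
        phys["P"][tissue] = 2.1
        scaled = StateFields(phys.data.copy())
        scaled["P"] = scaled["P"] / ref
        for _ in range(n):
            phys, _ = euler_step(phys, p, g, dt)
            scaled, _ = euler_step(scaled, p, g, dt)
        np.testing.assert_allclose(scaled["P"] * ref, phys["P"], rtol=1e-12)


class TestRunSimulation:
    def test_zero_horizon_returns_initial_snapshot(self, small_geometry, params, mild_init):
        cfg = SolverConfig(t_end_months=0.0)
        traj = run_simulation(small_geometry, params, mild_init, cfg, n0_um2=1e5)
        assert len(traj.times_months) == 1
        assert traj.nc_area_series[0] == 0.0

    def test_repeat_runs_bitwise_identical(self, small_geometry, params, mild_init):
        cfg = SolverConfig(t_end_months=3.0)
        a = run_simulation(small_geometry, params, mild_init, cfg, n0_um2=1e5)
        b = run_simulation(small_geometry, params, mild_init, cfg, n0_um2=1e5)
        for sp in SPECIES:
            np.testing.assert_array_equal(a.species_means[sp], b.species_means[sp])
        np.testing.assert_array_equal(a.nc_area_series, b.nc_area_series)

    def test_off_tissue_cells_never_updated(self, small_geometry, params, mild_init):
        cfg = SolverConfig(t_end_months=2.0)
        traj = run_simulation(
            small_geometry, params, mild_init, cfg, n0_um2=1e5, keep_final_state=True
        )
        off = ~small_geometry.tissue_mask
        assert np.all(traj.final_state.data[:, off] == 0.0)

    def test_positivity_under_stability_bounded_dt(self, std_geometry, params, mild_init):
        cfg = SolverConfig(t_end_months=6.0)
        traj = run_simulation(std_geometry, params, mild_init, cfg, n0_um2=1e5)
        assert traj.diagnostics["min_pre_clip"] >= -1e-12

    def test_dirichlet_outer_bc_pins_rim_values(self, small_geometry, params, mild_init):
        cfg = SolverConfig(t_end_months=2.0, outer_bc="dirichlet")
        traj = run_simulation(
            small_geometry, params, mild_init, cfg, n0_um2=1e5, keep_final_state=True
        )
        init_state = mild_init.build(small_geometry)
        eem = small_geometry.eem_mask
        np.testing.assert_array_equal(
            traj.final_state.data[:, eem], init_state.data[:, eem]
        )
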