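"""Reaction terms, taxis couplings, and endothelial influx."""

import dataclasses

import numpy as np
import pytest

from plaquesim import (
    ParameterError,
    ParameterSet,
    StateFields,
    apply_boundary_influx,
    endothelial_influx_ldl,
    endothelial_influx_monocyte,
    reaction_rhs,
    taxis_velocity_fields,
)
from plaquesim.reactions import influx_nondimensional
from plaquesim.solver import taxis_divergence
from plaquesim.state import SPECIES


class TestEndothelialInflux:
    def test_zero_shear_limit(self, params):
        assert endothelial_influx_ldl(100.0, 0.0, params) == pytest.approx(
            params.L_cr * 100.0
        )
        assert endothelial_influx_monocyte(4e5, 0.0, params) == pytest.approx(
            params.Mo_cr * 4e5
        )

    def test_half_saturation_at_reference_shear(self, params):
        j = endothelial_influx_ldl(100.0, params.WSS0, params)
        assert j == pytest.approx(params.L_cr * 100.0 / 2.0)

    def test_patient_p3_inputs_match_hand_evaluation(self, params):
        # plasma LDL 70.4 mg/dL at WSS 85.8 dyn/cm^2
        expected = 2e-5 * 70.4 / (1.0 + 85.8 / 100.0)
        assert endothelial_influx_ldl(70.4, 85.8, params) == pytest.approx(expected)

    def test_monocyte_flux_linear_in_plasma_level(self, params):
        mild = endothelial_influx_monocyte(4e5, 120.0, params)
        severe = endothelial_influx_monocyte(16e5, 120.0, params)
        assert severe == pytest.approx(4.0 * mild)

    def test_quarter_flux_at_three_reference_shears(self, params):
        j = endothelial_influx_monocyte(4e5, 300.0, params)
        assert j == pytest.approx(params.Mo_cr * 4e5 / 4.0)

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ParameterError):
            endothelial_influx_ldl(-1.0, 50.0, params)
        with pytest.raises(ParameterError):
            endothelial_influx_monocyte(1e5, -2.0, params)


class TestReactionRhs:
    def test_zero_state_gives_zero_rates(self, small_geometry, params):
        state = StateFields.zeros(small_geometry)
        rates = reaction_rhs(state, params, small_geometry)
        assert np.all(rates.data == 0.0)

    def test_ldl_only_state_feeds_only_oxidation(self, small_geometry, params):
        state = StateFields.zeros(small_geometry)
        tissue = small_geometry.tissue_mask
        state["L"][tissue] = 2.0
        rates = reaction_rhs(state, params, small_geometry)
        np.testing.assert_allclose(rates["L"][tissue], -params.lam_L * 2.0)
        np.testing.assert_allclose(rates["Lox"][tissue], params.lam_LoxL * 2.0)
        for sp in SPECIES:
            if sp not in ("L", "Lox"):
                assert np.all(rates[sp] == 0.0), sp

    def test_single_cell_matches_hand_evaluated_sums(self, small_geometry):
        # unit constants, L=2, Lox=1, Ma=3 in one tissue cell
        p = ParameterSet().replace(
            lam_L=1.0, lam_Plextra=1.0, lam_LoxL=1.0, lam_LoxMa=1.0, lam_PE=1.0,
            K_P=1.0, lam_PS=1.0, d_P=1.0, lam_MaMo=1.0, d_Ma=1.0, d_Mo=1.0,
            lam_CvE=1.0, lam_CvS=1.0, lam_CvMa=1.0, d_Cv=1.0, d_S=1.0,
            lam_CMCECM=1.0, lam_SCECM_prod=1.0, lam_CME=1.0, lam_CMS=1.0,
            d_CM=1.0, lam_F=1.0, d_F=1.0, gamma_pl=1.0, k_perm=0.0, d_Pl=1.0,
        )
        g = small_geometry
        r, c = next(iter(sorted(g.endothelium_cells)))
        state = StateFields.zeros(g)
        state["L"][r, c] = 2.0
        state["Lox"][r, c] = 1.0
        state["Ma"][r, c] = 3.0
        rates = reaction_rhs(state, p, g)
        assert rates["L"][r, c] == pytest.approx(-2.0)          # -1*2 + 1*0
        assert rates["Lox"][r, c] == pytest.approx(2.0 - 3.0)   # +1*2 - 1*1*3
        assert rates["P"][r, c] == pytest.approx(0.0)           # E=0, S=0, P=0
        assert rates["Mo"][r, c] == pytest.approx(0.0)
        assert rates["Ma"][r, c] == pytest.approx(-3.0)         # -d_Ma*Ma
        assert rates["F"][r, c] == pytest.approx(3.0)           # +1*1*3
        assert rates["S"][r, c] == pytest.approx(0.0)
        assert rates["Cv"][r, c] == pytest.approx(3.0)          # +lam_CvMa*Ma
        assert rates["CM"][r, c] == pytest.approx(0.0)
        assert rates["Pl"][r, c] == pytest.approx(0.0)          # E=0

    def test_each_rate_constant_switches_exactly_one_row(self, small_geometry):
        """Zeroing one constant changes only that row's contribution."""
        g = small_geometry
        rng = np.random.default_rng(42)
        state = StateFields.zeros(g)
        tissue = g.tissue_mask
        for sp in SPECIES:
            state[sp][tissue] = rng.uniform(0.1, 2.0, size=int(tissue.sum()))
        p = ParameterSet()
        affected = {
            "lam_L": ["L"], "lam_Plextra": ["L", "Mo"], "lam_LoxL": ["Lox"],
            "lam_LoxMa": ["Lox"], "lam_PE": ["P"], "lam_PS": ["P"], "d_P": ["P"],
            "lam_MaMo": ["Mo", "Ma"], "d_Ma": ["Ma"], "d_Mo": ["Mo"],
            "lam_CvE": ["Cv"], "lam_CvS": ["Cv"], "lam_CvMa": ["Cv"],
            "d_Cv": ["Cv"], "d_S": ["S"], "lam_CMCECM": ["CECM"],
            "lam_SCECM_prod": ["CECM"], "lam_CME": ["CM"], "lam_CMS": ["CM"],
            "d_CM": ["CM"], "lam_F": ["F"], "d_F": ["F"], "gamma_pl": ["Pl"],
            "d_Pl": ["Pl"],
        }
        base = reaction_rhs(state, p, g)
        for name, species in affected.items():
            perturbed = reaction_rhs(state, p.replace(**{name: 0.0}), g)
            delta = perturbed.data - base.data
            for i, sp in enumerate(SPECIES):
                changed = bool(np.any(delta[i] != 0.0))
                assert changed == (sp in species), (name, sp)

    def test_foam_cell_production_nonnegative(self, small_geometry, params):
        rng = np.random.default_rng(3)
        g = small_geometry
        state = StateFields.zeros(g)
        tissue = g.tissue_mask
        state["Lox"][tissue] = rng.uniform(0, 5, int(tissue.sum()))
        state["Ma"][tissue] = rng.uniform(0, 5, int(tissue.sum()))
        rates = reaction_rhs(state, params, g)
        assert np.all(rates["F"] >= 0.0)

    def test_all_constants_zero_gives_zero_rhs(self, small_geometry, inert_params):
        rng = np.random.default_rng(5)
        g = small_geometry
        state = StateFields.zeros(g)
        tissue = g.tissue_mask
        for sp in SPECIES:
            state[sp][tissue] = rng.uniform(0.0, 3.0, int(tissue.sum()))
        rates = reaction_rhs(state, inert_params, g)
        assert np.all(rates.data == 0.0)


class TestTaxis:
    def test_uniform_attractant_gives_zero_flux(self, small_geometry, params):
        g = small_geometry
        state = StateFields.zeros(g)
        tissue = g.tissue_mask
        state["Ma"][tissue] = 1.0
        state["P"][tissue] = 0.7  # uniform
        for term in taxis_velocity_fields(state, params, g):
            div = taxis_divergence(state[term.species], term.attractant, term.coeff, g)
            if term.species == "Ma":
                assert np.all(div == 0.0)

    def test_macrophages_move_up_the_mcp1_gradient(self, params):
        from plaquesim import DomainGeometry, Region

        # 1D strip: lumen | five intima cells
        labels = np.zeros((3, 7), dtype=np.int8)
        labels[1, 0] = Region.LUMEN
        labels[1, 1:6] = Region.INTIMA
        g = DomainGeometry(labels=labels, h=1.0)
        C = np.zeros((3, 7))
        A = np.zeros((3, 7))
        C[1, 1:6] = [1.0, 1.0, 1.0, 0.0, 0.0]  # Ma concentrated left
        A[1, 1:6] = [0.0, 0.1, 0.2, 0.3, 0.4]  # MCP-1 increasing rightward
        div = taxis_divergence(C, A, params.lam_MaP, g, h=1.0)
        # net flux to the right: mass leaves the left cells, arrives right
        assert div[1, 1] < 0
        assert div[1, 4] > 0
        assert abs(div[1, 1:6].sum()) < 1e-15

    def test_two_cell_flux_matches_hand_computation(self):
        from plaquesim import DomainGeometry, Region

        labels = np.zeros((3, 4), dtype=np.int8)
        labels[1, 0] = Region.LUMEN
        labels[1, 1:3] = Region.INTIMA
        g = DomainGeometry(labels=labels, h=1.0)
        C = np.zeros((3, 4))
        A = np.zeros((3, 4))
        C[1, 1], C[1, 2] = 2.0, 0.0
        A[1, 1], A[1, 2] = 0.0, 1.0
        h, lam = 0.5, 1.0
        div = taxis_divergence(C, A, lam, g, h=h)
        # face flux = lam * mean(C) * dA/h = 1 * 1 * 2 = 2; div = +-flux/h
        assert div[1, 1] == pytest.approx(-2.0 / h)
        assert div[1, 2] == pytest.approx(+2.0 / h)

    def test_ec_sensitivity_saturates_in_vegf(self, small_geometry, params):
        state = StateFields.zeros(small_geometry)
        tissue = small_geometry.tissue_mask
        state["Cv"][tissue] = 3.0
        terms = {t.label: t for t in taxis_velocity_fields(state, params, small_geometry)}
        coeff = terms["EC chemotaxis to VEGF"].coeff
        assert isinstance(coeff, np.ndarray)
        assert coeff[tissue] == pytest.approx(params.lam_ECv / (params.K_E + 3.0))


class TestBoundaryInflux:
    def test_zero_plasma_levels_leave_rates_unchanged(self, small_geometry, params):
        g = small_geometry
        p = params.replace(C_LDL=0.0, C_Mo=0.0)
        state = StateFields.zeros(g)
        rates = StateFields.zeros(g)
        before = rates.data.copy()
        apply_boundary_influx(rates, state, g, p)
        np.testing.assert_array_equal(rates.data, before)

    def test_doubling_plasma_ldl_doubles_the_source(self, small_geometry, params):
        g = small_geometry
        state = StateFields.zeros(g)
        r1 = apply_boundary_influx(StateFields.zeros(g), state, g, params)
        r2 = apply_boundary_influx(
            StateFields.zeros(g), state, g, params.replace(C_LDL=2 * params.C_LDL)
        )
        endo = g.endothelium_mask
        np.testing.assert_allclose(r2["L"][endo], 2.0 * r1["L"][endo])
        np.testing.assert_allclose(r2["Mo"][endo], r1["Mo"][endo])

    def test_total_added_mass_bookkeeping(self, small_geometry, params):
        """Total mass rate = per-length flux x endothelium length (count x h)."""
        g = small_geometry
        h_nd = 1.0 / g.n_cols
        rates = apply_boundary_influx(
            StateFields.zeros(g), StateFields.zeros(g), g, params, h_nd=h_nd
        )
        j_l, j_mo = influx_nondimensional(params)
        n_endo = len(g.endothelium_cells)
        # source density j/h integrated over n_endo cells of area h^2
        assert rates["L"].sum() * h_nd * h_nd == pytest.approx(j_l * n_endo * h_nd)
        assert rates["Mo"].sum() * h_nd * h_nd == pytest.approx(j_mo * n_endo * h_nd)

    def test_sources_restricted_to_endothelium_cells(self, small_geometry, params):
        g = small_geometry
        rates = apply_boundary_influx(
            StateFields.zeros(g), StateFields.zeros(g), g, params
        )
        endo = g.endothelium_mask
        assert np.all(rates["L"][endo] > 0)
        assert np.all(rates["L"][~endo] == 0.0)


class TestParameterSetConfig:
    def test_yaml_round_trip_preserves_values_and_provenance(self, tmp_path, params):
        path = params.to_yaml(tmp_path / "params.yaml")
        loaded = ParameterSet.from_yaml(path)
        for f in dataclasses.fields(ParameterSet):
            assert getattr(loaded, f.name) == getattr(params, f.name), f.name
        import yaml

        raw = yaml.safe_load(path.read_text())
        assert raw["L_cr"]["provenance"] == "paper"
        assert raw["lam_F"]["provenance"] == "gap-filled"

    def test_unknown_key_rejected(self):
        with pytest.raises(ParameterError, match="unknown parameter"):
            ParameterSet.from_dict({"not_a_constant": {"value": 1.0}})

    def test_negative_diffusion_rejected(self):
        bad = {sp: 1e-4 for sp in SPECIES}
        bad["L"] = -1.0
        with pytest.raises(ParameterError):
            ParameterSet(diffusion=bad)
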