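"""Local reaction terms, taxis couplings, and endothelial boundary influx.

Each model field obeys a reaction-diffusion equation

    dC_i/dt = D_i lap(C_i) + reactions_i - div(sum_j lam_ij C_i grad(C_j))

on the tissue (intima + media) region.  This module assembles the local
reaction rates row by row, declares which species respond chemotactically or
haptotactically to which attractant, and adds the shear-modulated
transluminal influx of LDL and monocytes at the endothelium.

The endothelial solute flux follows the standard conductivity form

    J = k_cr * C_plasma / (1 + WSS / WSS0)

so low wall shear stress promotes lipoprotein and monocyte entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .errors import NumericalError, ParameterError
from .geometry import DomainGeometry
from .params import ParameterSet
from .state import SPECIES, StateFields

__all__ = [
    "endothelial_influx_ldl",
    "endothelial_influx_monocyte",
    "reaction_rhs",
    "TaxisTerm",
    "taxis_velocity_fields",
    "apply_boundary_influx",
]


# ---------------------------------------------------------------------------
# Endothelial influx (physical formula and its nondimensional counterpart)
# ---------------------------------------------------------------------------

def endothelial_influx_ldl(C_LDL: float, WSS: float, p: ParameterSet) -> float:
    """Transluminal LDL flux per unit endothelium length.

    ``J_LDL = L_cr * C_LDL / (1 + WSS/WSS0)`` with the LDL conductivity
    ``L_cr`` in m/s, plasma LDL in mg/dL and WSS in dyn/cm^2.
    """
    if WSS < 0 or C_LDL < 0:
        raise ParameterError("WSS and C_LDL must be nonnegative")
    return p.L_cr * C_LDL / (1.0 + WSS / p.WSS0)


def endothelial_influx_monocyte(C_Mo: float, WSS: float, p: ParameterSet) -> float:
    """Transluminal monocyte flux per unit endothelium length.

    ``J_Mo = Mo_cr * C_Mo / (1 + WSS/WSS0)`` with plasma monocytes in
    cells/cm^3.
    """
    if WSS < 0 or C_Mo < 0:
        raise ParameterError("WSS and C_Mo must be nonnegative")
    return p.Mo_cr * C_Mo / (1.0 + WSS / p.WSS0)


def influx_nondimensional(p: ParameterSet) -> tuple[float, float]:
    """Nondimensional per-unit-length influx of (LDL, monocytes).

    The physical fluxes are normalised by their zero-shear value at the
    reference plasma concentration and scaled by the influx strengths
    ``beta_L`` / ``beta_Mo`` (per month).  The LDL conductivity is further
    scaled by an endothelial-dysfunction factor ``1 + k_endo*(C_Mo/C_Mo_ref - 1)``:
    a systemically inflamed endothelium is more permeable to lipoproteins.
    """
    j_l = endothelial_influx_ldl(p.C_LDL, p.WSS, p) / (p.L_cr * p.C_LDL_ref)
    j_mo = endothelial_influx_monocyte(p.C_Mo, p.WSS, p) / (p.Mo_cr * p.C_Mo_ref)
    # Endothelial dysfunction: the effective LDL conductivity rises with the
    # systemic inflammatory burden encoded by the plasma monocyte level.
    dysfunction = 1.0 + p.k_endo * max(p.C_Mo / p.C_Mo_ref - 1.0, 0.0)
    return p.beta_L * dysfunction * j_l, p.beta_Mo * j_mo


# ---------------------------------------------------------------------------
# Local reactions
# ---------------------------------------------------------------------------

def reaction_rhs(state: StateFields, p: ParameterSet, g: DomainGeometry) -> StateFields:
    """Per-cell local reaction rates for all twelve fields (no transport).

    Rows, per species:

    * LDL        : -lam_L*L + lam_Plextra*Pl          (oxidation; leaky microvessels)
    * ox-LDL     : +lam_LoxL*L - lam_LoxMa*Lox*Ma     (oxidation; phagocytosis)
    * MCP-1      : +lam_PE*E*Lox/(K_P+Lox) + lam_PS*S - d_P*P
    * monocytes  : +lam_Plextra*Pl - lam_MaMo*Mo - d_Mo*Mo
    * macrophages: +lam_MaMo*Mo - d_Ma*Ma
    * foam cells : +lam_F*Lox*Ma - d_F*F
    * SMCs       : -d_S*S*Lox                          (ox-LDL-induced apoptosis)
    * ECM        : -lam_CMCECM*CECM*CM + lam_SCECM_prod*S
    * MMP        : +lam_CME*E + lam_CMS*S - d_CM*CM
    * ECs        : 0 (transport only)
    * VEGF       : -lam_CvE*E*Cv + lam_CvS*S + lam_CvMa*Ma - d_Cv*Cv
    * plasma     : +gamma_pl*Q_t - d_Pl*Pl, with Q_t = E*(1 + k_perm*Ma/(K_Ma+Ma)):
      extravasation from the continuum microvessel density, leakier where
      perivascular macrophages accumulate (inflamed neovessels are immature),
      balanced by first-order resorption/drainage
    """
    L, Lox, P = state["L"], state["Lox"], state["P"]
    Mo, Ma, F, S = state["Mo"], state["Ma"], state["F"], state["S"]
    CECM, CM, E, Cv, Pl = state["CECM"], state["CM"], state["E"], state["Cv"], state["Pl"]

    rates = StateFields.zeros(g)
    rates["L"] = -p.lam_L * L + p.lam_Plextra * Pl
    rates["Lox"] = p.lam_LoxL * L - p.lam_LoxMa * Lox * Ma
    rates["P"] = p.lam_PE * E * Lox / (p.K_P + Lox) + p.lam_PS * S - p.d_P * P
    rates["Mo"] = p.lam_Plextra * Pl - p.lam_MaMo * Mo - p.d_Mo * Mo
    rates["Ma"] = p.lam_MaMo * Mo - p.d_Ma * Ma
    rates["F"] = p.lam_F * Lox * Ma - p.d_F * F
    rates["S"] = -p.d_S * S * Lox
    rates["CECM"] = -p.lam_CMCECM * CECM * CM + p.lam_SCECM_prod * S
    rates["CM"] = p.lam_CME * E + p.lam_CMS * S - p.d_CM * CM
    rates["Cv"] = -p.lam_CvE * E * Cv + p.lam_CvS * S + p.lam_CvMa * Ma - p.d_Cv * Cv
    rates["Pl"] = p.gamma_pl * E * (1.0 + p.k_perm * Ma / (p.K_Ma + Ma)) - p.d_Pl * Pl

    off = ~g.tissue_mask
    rates.data[:, off] = 0.0
    if not np.isfinite(rates.data).all():
        sp, r, c = np.argwhere(~np.isfinite(rates.data))[0]
        raise NumericalError(
            f"non-finite reaction rate for {SPECIES[sp]} at cell ({r}, {c})"
        )
    return rates


# ---------------------------------------------------------------------------
# Taxis couplings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxisTerm:
    """One chemotaxis/haptotaxis coupling: ``flux = +coeff * C * grad(attractant)``.

    All couplings move the motile species up the attractant gradient; the
    corresponding term in the species equation is ``-div(flux)``.
    ``coeff`` may be a scalar sensitivity or a per-cell array (saturated
    sensitivities).
    """

    species: str
    attractant: np.ndarray
    coeff: float | np.ndarray
    label: str = ""


def taxis_velocity_fields(
    state: StateFields, p: ParameterSet, g: DomainGeometry
) -> List[TaxisTerm]:
    """The model's seven taxis couplings at the current state.

    * macrophages -> MCP-1 (chemotaxis)
    * monocytes   -> ox-LDL (chemotaxis)
    * ECs         -> VEGF (chemotaxis, saturated as lam_ECv/(K_E+Cv))
    * ECs         -> ECM (haptotaxis)
    * SMCs        -> MCP-1, macrophage-borne PDGF, ECM
    """
    return [
        TaxisTerm("Ma", state["P"], p.lam_MaP, "macrophage chemotaxis to MCP-1"),
        TaxisTerm("Mo", state["Lox"], p.lam_MoLox, "monocyte chemotaxis to ox-LDL"),
        TaxisTerm(
            "E",
            state["Cv"],
            p.lam_ECv / (p.K_E + state["Cv"]),
            "EC chemotaxis to VEGF",
        ),
        TaxisTerm("E", state["CECM"], p.lam_ECECM, "EC haptotaxis to ECM"),
        TaxisTerm("S", state["P"], p.lam_SP, "SMC chemotaxis to MCP-1"),
        TaxisTerm("S", state["Ma"], p.lam_SMa, "SMC chemotaxis to PDGF (macrophages)"),
        TaxisTerm("S", state["CECM"], p.lam_SCECM_taxis, "SMC haptotaxis to ECM"),
    ]


# ---------------------------------------------------------------------------
# Boundary influx
# ---------------------------------------------------------------------------

def apply_boundary_influx(
    rates: StateFields,
    state: StateFields,
    g: DomainGeometry,
    p: ParameterSet,
    h_nd: float | None = None,
) -> StateFields:
    """Add the endothelial LDL/monocyte sources to the rate fields.

    The per-unit-length flux is converted to a per-cell volumetric source by
    dividing by the (nondimensional) cell size ``h_nd``; sources act on
    endothelium cells only.  Modifies ``rates`` in place and returns it.
    """
    endo = g.endothelium_mask
    if not endo.any():
        raise ParameterError("geometry has no endothelium cells")
    if h_nd is None:
        h_nd = 1.0 / g.n_cols
    j_l, j_mo = influx_nondimensional(p)
    rates["L"][endo] += j_l / h_nd
    rates["Mo"][endo] += j_mo / h_nd
    return rates
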