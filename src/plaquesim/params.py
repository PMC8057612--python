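"""Model constants, their provenance, and initial-condition builders.

The simulator works in nondimensional variables: every concentration is
divided by a per-species reference scale, lengths by the frame width
(4 mm by default), and time is measured in months.  Constants printed in the
source literature (boundary-flux conductivities, the shear reference WSS0,
the plasma monocyte levels, all initial concentrations) are kept in their
physical units and carry provenance ``"paper"``.  Rate and diffusion
constants whose values were never published are gap-filled in nondimensional
units and carry provenance ``"gap-filled"`` or ``"prior-model-literature"``;
every one of them can be overridden from a config file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np
import yaml

from .errors import ParameterError
from .geometry import DomainGeometry
from .state import SPECIES, StateFields

__all__ = ["SPECIES", "ParameterSet", "InitialConditions"]

#: Plasma monocyte concentration (cells/cm^3) per inflammation level.
INFLAMMATION_LEVELS: Dict[str, float] = {
    "mild": 4e5,
    "moderate": 8e5,
    "severe": 16e5,
}

#: Scaling of the initial microvessel EC density at the EEM rim.
MICROVESSEL_LEVELS: Dict[str, float] = {"low": 0.5, "mid": 1.0, "high": 2.0}


def _default_diffusion() -> Dict[str, float]:
    # Nondimensional (frame width = 1, time in months).  Solutes diffuse
    # fastest, motile cells slowly; foam cells and matrix are immobile.
    return {
        "L": 3e-4,
        "Lox": 1e-4,
        "P": 1e-3,
        "Mo": 3e-4,
        "Ma": 3e-4,
        "F": 0.0,
        "S": 2e-4,
        "CECM": 0.0,
        "CM": 1e-3,
        "E": 2e-4,
        "Cv": 1e-3,
        "Pl": 1e-3,
    }


@dataclass
class ParameterSet:
    """Every rate, diffusion, and boundary constant of the model.

    Attributes whose names start with ``lam_`` are reaction-rate constants
    (one per reaction-term row), ``d_`` are first-order decay/apoptosis
    rates, ``K_`` are Michaelis saturation constants.  Units are per month
    on nondimensional concentrations unless noted otherwise.
    """

    # -- diffusion -------------------------------------------------------
    diffusion: Dict[str, float] = field(default_factory=_default_diffusion)

    # -- lipid pathway ---------------------------------------------------
    lam_L: float = 0.4          # LDL oxidation
    lam_Plextra: float = 0.4    # LDL and monocytes from leaky microvessels
    lam_LoxL: float = 0.4       # ox-LDL formed by oxidation of LDL
    lam_LoxMa: float = 0.05    # macrophage phagocytosis of ox-LDL (main ox-LDL sink)

    # -- MCP-1 -----------------------------------------------------------
    lam_PE: float = 0.5         # MCP-1 production by ECs (ox-LDL saturated)
    K_P: float = 1.0
    lam_PS: float = 0.1         # MCP-1 production by SMCs
    d_P: float = 0.3            # MCP-1 decay

    # -- monocytes / macrophages ----------------------------------------
    lam_MaP: float = 5e-5       # macrophage chemotaxis toward MCP-1
    lam_MaMo: float = 0.5       # differentiation of monocytes to macrophages
    d_Ma: float = 0.1           # macrophage apoptosis
    lam_MoLox: float = 5e-5     # monocyte chemotaxis toward ox-LDL
    d_Mo: float = 0.2           # monocyte decay

    # -- endothelial cells / VEGF ---------------------------------------
    lam_ECv: float = 1e-2       # EC chemotaxis toward VEGF (saturated)
    K_E: float = 1.0
    lam_ECECM: float = 2e-5     # EC haptotaxis toward ECM
    lam_CvE: float = 0.1        # VEGF uptake by ECs (mass action)
    lam_CvS: float = 0.05       # VEGF early production by SMCs
    lam_CvMa: float = 0.3       # VEGF late production by macrophages
    d_Cv: float = 0.3           # VEGF decay

    # -- SMCs ------------------------------------------------------------
    lam_SP: float = 1e-6        # SMC chemotaxis toward MCP-1
    lam_SMa: float = 1e-6       # SMC chemotaxis toward macrophage-borne PDGF
    lam_SCECM_taxis: float = 1e-6  # SMC haptotaxis toward ECM
    d_S: float = 0.018           # SMC apoptosis induced by ox-LDL

    # -- ECM / MMP -------------------------------------------------------
    lam_CMCECM: float = 0.3     # ECM degraded by MMPs
    lam_SCECM_prod: float = 0.05  # ECM produced by SMCs
    lam_CME: float = 0.05       # MMP produced by ECs
    lam_CMS: float = 0.05       # MMP produced by SMCs
    d_CM: float = 0.3           # MMP decay

    # -- foam cells (gap-filled equation) --------------------------------
    lam_F: float = 0.3          # foam cells from phagocytosed ox-LDL
    d_F: float = 0.05           # foam cell degradation

    # -- plasma extravasation (IPH proxy) --------------------------------
    gamma_pl: float = 0.4       # fluid flux gamma*Q_t, Q_t = E*(1 + k_perm*Ma/(K_Ma+Ma))
    k_perm: float = 2.5         # permeability enhancement by perivascular macrophages
    K_Ma: float = 1.0           # macrophage density at half-maximal leakiness
    d_Pl: float = 0.5           # extravascular plasma clearance (resorption/drainage)
    k_endo: float = 1.5         # endothelial permeability scaling with systemic inflammation
    psi: float = 0.0            # plasma convection coefficient (disabled)
    U_i: float = 0.0            # interstitial velocity magnitude (disabled)

    # -- endothelial boundary influx (physical constants) ----------------
    L_cr: float = 2e-5          # LDL endothelial conductivity, m/s
    Mo_cr: float = 4e-5         # monocyte endothelial conductivity, m/s
    WSS0: float = 100.0         # shear reference, dyn/cm^2
    beta_L: float = 0.1        # nondim transluminal LDL influx strength, 1/month
    beta_Mo: float = 0.05        # nondim transluminal monocyte influx strength, 1/month
    C_LDL_ref: float = 100.0    # plasma LDL normalisation, mg/dL
    C_Mo_ref: float = 4e5       # plasma monocyte normalisation, cells/cm^3

    # -- patient inputs --------------------------------------------------
    WSS: float = 100.0          # wall shear stress at T1, dyn/cm^2
    C_LDL: float = 100.0        # plasma LDL, mg/dL
    C_Mo: float = 4e5           # plasma monocytes, cells/cm^3

    #: Provenance of every constant: paper / prior-model-literature / gap-filled.
    PROVENANCE = {
        "diffusion": "prior-model-literature",
        "lam_L": "gap-filled", "lam_Plextra": "gap-filled",
        "lam_LoxL": "gap-filled", "lam_LoxMa": "gap-filled",
        "lam_PE": "gap-filled", "K_P": "gap-filled", "lam_PS": "gap-filled",
        "d_P": "gap-filled",
        "lam_MaP": "prior-model-literature", "lam_MaMo": "gap-filled",
        "d_Ma": "gap-filled", "lam_MoLox": "prior-model-literature",
        "d_Mo": "gap-filled",
        "lam_ECv": "prior-model-literature", "K_E": "gap-filled",
        "lam_ECECM": "prior-model-literature", "lam_CvE": "gap-filled",
        "lam_CvS": "gap-filled", "lam_CvMa": "gap-filled", "d_Cv": "gap-filled",
        "lam_SP": "prior-model-literature", "lam_SMa": "prior-model-literature",
        "lam_SCECM_taxis": "prior-model-literature", "d_S": "gap-filled",
        "lam_CMCECM": "gap-filled", "lam_SCECM_prod": "gap-filled",
        "lam_CME": "gap-filled", "lam_CMS": "gap-filled", "d_CM": "gap-filled",
        "lam_F": "gap-filled", "d_F": "gap-filled",
        "gamma_pl": "gap-filled", "k_perm": "gap-filled", "K_Ma": "gap-filled",
        "d_Pl": "gap-filled", "k_endo": "gap-filled", "psi": "gap-filled", "U_i": "gap-filled",
        "L_cr": "paper", "Mo_cr": "paper", "WSS0": "paper",
        "beta_L": "gap-filled", "beta_Mo": "gap-filled",
        "C_LDL_ref": "gap-filled", "C_Mo_ref": "paper",
        "WSS": "paper", "C_LDL": "paper", "C_Mo": "paper",
    }

    def __post_init__(self) -> None:
        missing = set(SPECIES) - set(self.diffusion)
        if missing:
            raise ParameterError(f"diffusion coefficients missing for {sorted(missing)}")
        for sp, dval in self.diffusion.items():
            if dval < 0:
                raise ParameterError(f"negative diffusion coefficient for {sp}")
        for name in ("lam_L", "d_P", "d_Ma", "d_Mo", "d_Cv", "d_S", "d_CM", "d_F"):
            if getattr(self, name) < 0:
                raise ParameterError(f"negative rate constant {name}")
        if self.WSS < 0 or self.C_LDL < 0 or self.C_Mo < 0:
            raise ParameterError("patient inputs WSS, C_LDL, C_Mo must be nonnegative")

    @property
    def D_max(self) -> float:
        return max(self.diffusion.values())

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    # -- config round-trip ----------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            out[f.name] = {
                "value": dict(val) if isinstance(val, dict) else float(val),
                "provenance": self.PROVENANCE.get(f.name, "gap-filled"),
            }
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, entry in data.items():
            if key not in known:
                raise ParameterError(f"unknown parameter {key!r}")
            kwargs[key] = entry["value"] if isinstance(entry, dict) and "value" in entry else entry
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class InitialConditions:
    """Physical initial magnitudes and the per-species reference scales.

    The listed magnitudes follow the model's published initial state: SMC
    density 6e-3 g/cm^3 in media and 3e-3 in intima; LDL 1.0e-3 mg/mm^2 and
    ox-LDL 1e-7 mg/mm^2 spread evenly in the intima; MMP 3e-8, MCP-1 3e-10
    and ECM 4e-2 g/cm^3; VEGF mean 4e-10 g/cm^3 with a gradient rising from
    the media toward the intima.  Species that start at zero or trace level
    (monocytes, macrophages, foam cells, plasma, ECs) are scaled by a
    plausible maximum instead of their initial value.
    """

    S_media: float = 6e-3       # g/cm^3
    S_intima: float = 3e-3      # g/cm^3
    L0: float = 1.0e-3          # mg/mm^2, intima only
    Lox0: float = 1e-7          # mg/mm^2, intima only
    CM0: float = 3e-8           # g/cm^3
    P0: float = 3e-10           # g/cm^3
    CECM0: float = 4e-2         # g/cm^3
    Cv_mean: float = 4e-10      # g/cm^3, with media->intima gradient
    E_rim: float = 1e5          # cells/cm^3 nominal microvessel EC density
    rim_band_um: float = 100.0  # depth of the adventitial microvessel band
    inflammation_level: str = "mild"
    microvessel_level: str = "mid"

    def __post_init__(self) -> None:
        if self.inflammation_level not in INFLAMMATION_LEVELS:
            raise ParameterError(
                f"inflammation level must be one of {sorted(INFLAMMATION_LEVELS)}"
            )
        if self.microvessel_level not in MICROVESSEL_LEVELS:
            raise ParameterError(
                f"microvessel level must be one of {sorted(MICROVESSEL_LEVELS)}"
            )

    @property
    def C_Mo(self) -> float:
        """Plasma monocyte concentration implied by the inflammation level."""
        return INFLAMMATION_LEVELS[self.inflammation_level]

    def reference_scales(self) -> Dict[str, float]:
        """Per-species reference concentration used for nondimensionalization."""
        return {
            "L": self.L0,
            "Lox": self.L0,        # trace initial; scaled by the LDL scale
            "P": self.P0,
            "Mo": self.C_Mo,       # plasma level of the mild regime serves via C_Mo_ref
            "Ma": self.C_Mo,
            "F": self.S_media,     # foam cells on the SMC mass scale
            "S": self.S_media,
            "CECM": self.CECM0,
            "CM": self.CM0,
            "E": self.E_rim,
            "Cv": self.Cv_mean,
            "Pl": self.L0,         # plasma proxy on the lipid scale
        }

    def build(self, g: DomainGeometry) -> StateFields:
        """Nondimensional initial fields on a geometry.

        All fields are zero outside the tissue (intima + media) region.
        """
        intima = g.intima_mask
        media = g.media_mask
        tissue = g.tissue_mask
        zeros = lambda: np.zeros(g.labels.shape, dtype=float)  # noqa: E731

        fields: Dict[str, np.ndarray] = {sp: zeros() for sp in SPECIES}
        fields["S"][media] = 1.0                      # 6e-3 / 6e-3
        fields["S"][intima] = self.S_intima / self.S_media
        fields["L"][intima] = 1.0                     # 1e-3 / 1e-3
        fields["Lox"][intima] = self.Lox0 / self.L0
        fields["P"][tissue] = 1.0
        fields["CM"][tissue] = 1.0
        fields["CECM"][tissue] = 1.0

        # VEGF: mean 1, rising linearly with depth from the EEM toward the
        # endothelium (the hypoxic thickened intima is the VEGF source).
        from scipy import ndimage as _ndi

        depth = _ndi.distance_transform_edt(~g.exterior_mask)
        depth = np.where(tissue, depth, 0.0)
        dmax = depth.max()
        if dmax > 0:
            profile = depth / dmax          # 0 at EEM rim, 1 deepest
            mean_p = profile[tissue].mean()
            fields["Cv"][tissue] = 0.5 + profile[tissue] * (0.5 / max(mean_p, 1e-12))
            # rescale so the tissue mean is exactly 1
            fields["Cv"][tissue] *= 1.0 / fields["Cv"][tissue].mean()
        else:
            fields["Cv"][tissue] = 1.0

        # Microvessel ECs seeded in a band of media at the EEM rim (the
        # vasa vasorum penetrate the outer media), scaled by the level factor.
        dist_ext = _ndi.distance_transform_edt(~g.exterior_mask) * g.h
        rim = media & (dist_ext <= self.rim_band_um)
        if not rim.any():
            rim = g.eem_mask
        fields["E"][rim] = MICROVESSEL_LEVELS[self.microvessel_level]
        return StateFields.from_dict(fields)
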