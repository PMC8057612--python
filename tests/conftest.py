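"""Shared fixtures: synthetic geometries and parameter sets."""

from __future__ import annotations

import numpy as np
import pytest

from plaquesim import (
    DomainGeometry,
    InitialConditions,
    ParameterSet,
    generate_synthetic_geometry,
)


def eccentric_thickness(theta: np.ndarray) -> np.ndarray:
    """Standard eccentric intima profile: 400 + 200*cos(theta) um."""
    return 400.0 + 200.0 * np.cos(theta)


@pytest.fixture(scope="session")
def std_geometry() -> DomainGeometry:
    """The standard synthetic case: eccentric plaque on a 100x100 grid."""
    return generate_synthetic_geometry(
        n=100,
        lumen_radius_um=500.0,
        intima_thickness_fn=eccentric_thickness,
        media_thickness_um=300.0,
        seed=0,
        h_um=40.0,
    )


@pytest.fixture(scope="session")
def small_geometry() -> DomainGeometry:
    """A coarse 40x40 version of the standard case for fast dynamics tests."""
    return generate_synthetic_geometry(
        n=40,
        lumen_radius_um=500.0,
        intima_thickness_fn=eccentric_thickness,
        media_thickness_um=300.0,
        seed=0,
        h_um=100.0,
    )


@pytest.fixture(scope="session")
def concentric_geometry() -> DomainGeometry:
    """A concentric annulus (constant wall thickness)."""
    return generate_synthetic_geometry(
        n=80,
        lumen_radius_um=500.0,
        intima_thickness_fn=400.0,
        media_thickness_um=300.0,
        seed=0,
        h_um=50.0,
    )


@pytest.fixture()
def params() -> ParameterSet:
    return ParameterSet(WSS=100.0, C_LDL=140.0)


@pytest.fixture()
def inert_params() -> ParameterSet:
    """All reaction, taxis, influx and diffusion constants zeroed."""
    p = ParameterSet()
    zeros = {
        name: 0.0
        for name in (
            "lam_L", "lam_Plextra", "lam_LoxL", "lam_LoxMa", "lam_PE", "lam_PS",
            "d_P", "lam_MaP", "lam_MaMo", "d_Ma", "lam_MoLox", "d_Mo", "lam_ECv",
            "lam_ECECM", "lam_CvE", "lam_CvS", "lam_CvMa", "d_Cv", "lam_SP",
            "lam_SMa", "lam_SCECM_taxis", "d_S", "lam_CMCECM", "lam_SCECM_prod",
            "lam_CME", "lam_CMS", "d_CM", "lam_F", "d_F", "gamma_pl", "d_Pl",
            "beta_L", "beta_Mo",
        )
    }
    zeros["diffusion"] = {sp: 0.0 for sp in p.diffusion}
    return p.replace(**zeros)


@pytest.fixture()
def mild_init() -> InitialConditions:
    return InitialConditions(inflammation_level="mild", microvessel_level="mid")
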