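"""Explicit finite-difference integration of the coupled field equations.

The twelve fields live on the tissue cells of a labeled grid.  Diffusion and
taxis are discretized in conservative flux form on cell faces, so that total
mass is conserved to rounding error on the closed domain: every face between
a tissue cell and a lumen/exterior cell carries zero flux (mirror closure),
implementing the no-transport condition at the external elastic membrane and
restricting endothelial exchange to the explicit source terms.

Time stepping is forward Euler under the usual 2D stability bound
``dt <= safety * h^2 / (4 * D_max)``, tightened further when taxis velocities
approach the advective CFL limit.  Negative values produced by the explicit
scheme are clipped to zero and counted; clip totals are reported on the
trajectory as a solver health metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .errors import NumericalError, ParameterError
from .geometry import DomainGeometry
from .params import InitialConditions, ParameterSet
from .reactions import (
    apply_boundary_influx,
    reaction_rhs,
    taxis_velocity_fields,
)
from .state import SPECIES, StateFields
from .analysis import Trajectory, nc_area

__all__ = [
    "SolverConfig",
    "laplacian",
    "taxis_divergence",
    "stable_timestep",
    "euler_step",
    "nondimensionalize",
    "redimensionalize",
    "run_simulation",
]


@dataclass
class SolverConfig:
    """Time-stepping and scaling configuration.

    ``dt`` is the nondimensional step in months; leave ``None`` to derive it
    from the stability bound.  ``t_end_months`` is the simulated horizon
    (three years by default).  ``outer_bc`` selects the closure at the EEM:
    ``"no_flux"`` (default) or ``"dirichlet"`` (fields pinned to their
    initial values on the EEM rim).
    """

    dt: Optional[float] = None
    safety_factor: float = 0.9
    t_end_months: float = 36.0
    snapshot_interval_months: float = 1.0
    t_ref_months: float = 1.0
    reference_scales: Optional[Dict[str, float]] = None
    outer_bc: str = "no_flux"

    def __post_init__(self) -> None:
        if not (0.0 < self.safety_factor <= 1.0):
            raise ParameterError("safety_factor must lie in (0, 1]")
        if self.t_end_months < 0:
            raise ParameterError("t_end_months must be nonnegative")
        if self.outer_bc not in ("no_flux", "dirichlet"):
            raise ParameterError(f"unknown outer boundary condition {self.outer_bc!r}")


# ---------------------------------------------------------------------------
# Masked grid kernels
# ---------------------------------------------------------------------------

class _GridOps:
    """Precomputed face masks for flux-form stencils on one geometry."""

    def __init__(self, g: DomainGeometry):
        tissue = g.tissue_mask
        self.tissue = tissue
        self.open_x = tissue[:, :-1] & tissue[:, 1:]
        self.open_y = tissue[:-1, :] & tissue[1:, :]
        self.endo = g.endothelium_mask
        self.eem = g.eem_mask
        self.h_nd = 1.0 / g.n_cols

    def diffusion(self, C: np.ndarray, D: float, h: float, out: np.ndarray) -> None:
        """Accumulate D*lap(C) into ``out`` (flux form, mirror closure)."""
        if D == 0.0:
            return
        fx = (C[:, 1:] - C[:, :-1]) * self.open_x * (D / (h * h))
        out[:, :-1] += fx
        out[:, 1:] -= fx
        fy = (C[1:, :] - C[:-1, :]) * self.open_y * (D / (h * h))
        out[:-1, :] += fy
        out[1:, :] -= fy

    def taxis(
        self,
        C: np.ndarray,
        A: np.ndarray,
        coeff: float | np.ndarray,
        h: float,
        out: np.ndarray,
    ) -> float:
        """Accumulate -div(coeff * C * grad A) into ``out``; return max face speed.

        Face flux uses the arithmetic-mean concentration and, for per-cell
        sensitivities, the arithmetic-mean coefficient.
        """
        gx = (A[:, 1:] - A[:, :-1]) * self.open_x / h
        gy = (A[1:, :] - A[:-1, :]) * self.open_y / h
        if isinstance(coeff, np.ndarray):
            cx = 0.5 * (coeff[:, 1:] + coeff[:, :-1])
            cy = 0.5 * (coeff[1:, :] + coeff[:-1, :])
        else:
            cx = cy = coeff
        vx = cx * gx
        vy = cy * gy
        jx = 0.5 * (C[:, 1:] + C[:, :-1]) * vx
        jy = 0.5 * (C[1:, :] + C[:-1, :]) * vy
        out[:, :-1] -= jx / h
        out[:, 1:] += jx / h
        out[:-1, :] -= jy / h
        out[1:, :] += jy / h
        vmax = 0.0
        if vx.size:
            vmax = max(float(np.abs(vx).max()), float(np.abs(vy).max()))
        return vmax


_OPS_CACHE: dict = {}


def _ops(g: DomainGeometry) -> _GridOps:
    ops = _OPS_CACHE.get(id(g))
    if ops is None or ops[0]() is None:
        import weakref

        ops = (weakref.ref(g), _GridOps(g))
        _OPS_CACHE[id(g)] = ops
        if len(_OPS_CACHE) > 64:  # drop dead entries
            for k in [k for k, v in _OPS_CACHE.items() if v[0]() is None]:
                del _OPS_CACHE[k]
    return ops[1]


# ---------------------------------------------------------------------------
# Public stencil operations
# ---------------------------------------------------------------------------

def laplacian(field: np.ndarray, g: DomainGeometry, h: float | None = None) -> np.ndarray:
    """Masked 5-point Laplacian with zero-flux closure, units 1/length^2.

    ``h`` defaults to the nondimensional cell size ``1/n_cols``.
    """
    ops = _ops(g)
    h = ops.h_nd if h is None else float(h)
    out = np.zeros_like(np.asarray(field, dtype=float))
    ops.diffusion(np.asarray(field, dtype=float), 1.0, h, out)
    return out


def taxis_divergence(
    C: np.ndarray,
    attractant: np.ndarray,
    coeff: float | np.ndarray,
    g: DomainGeometry,
    h: float | None = None,
) -> np.ndarray:
    """Rate contribution ``-div(coeff * C * grad attractant)`` in flux form.

    Zero normal flux at every domain boundary, so the returned field sums to
    zero over the tissue (taxis redistributes, never creates, mass).
    """
    ops = _ops(g)
    h = ops.h_nd if h is None else float(h)
    out = np.zeros_like(np.asarray(C, dtype=float))
    ops.taxis(np.asarray(C, dtype=float), np.asarray(attractant, dtype=float), coeff, h, out)
    return out


def stable_timestep(
    p: ParameterSet,
    cfg: SolverConfig,
    g: DomainGeometry,
    state: Optional[StateFields] = None,
) -> float:
    """Largest stable explicit step: ``safety * h^2 / (4 D_max)``.

    If a state is supplied, the bound is further reduced so that the current
    maximum taxis face velocity satisfies the advective CFL condition
    ``dt <= safety * h / (2 v_max)``.
    """
    ops = _ops(g)
    h = ops.h_nd
    dt_bounds: List[float] = []
    if p.D_max > 0.0:
        dt_bounds.append(cfg.safety_factor * h * h / (4.0 * p.D_max))
    if state is not None:
        scratch = np.zeros(g.labels.shape)
        v_max = 0.0
        for term in taxis_velocity_fields(state, p, g):
            v_max = max(v_max, ops.taxis(state[term.species], term.attractant, term.coeff, h, scratch))
        if v_max > 0.0:
            dt_bounds.append(cfg.safety_factor * h / (2.0 * v_max))
    if not dt_bounds:
        if cfg.dt is None:
            raise ParameterError("no diffusion, no taxis, and no explicit dt given")
        return cfg.dt
    dt = min(dt_bounds)
    if cfg.dt is not None:
        dt = min(dt, cfg.dt)
    return dt


# ---------------------------------------------------------------------------
# Euler stepping
# ---------------------------------------------------------------------------

def _rhs(
    state: StateFields,
    p: ParameterSet,
    g: DomainGeometry,
    ops: _GridOps,
) -> tuple[StateFields, float]:
    """Full right-hand side (diffusion + taxis + reactions + influx)."""
    rates = reaction_rhs(state, p, g)
    h = ops.h_nd
    for sp in SPECIES:
        ops.diffusion(state[sp], p.diffusion[sp], h, rates[sp])
    v_max = 0.0
    for term in taxis_velocity_fields(state, p, g):
        v_max = max(v_max, ops.taxis(state[term.species], term.attractant, term.coeff, h, rates[term.species]))
    apply_boundary_influx(rates, state, g, p, h_nd=h)
    return rates, v_max


def euler_step(
    state: StateFields,
    p: ParameterSet,
    g: DomainGeometry,
    dt: float,
    cfg: Optional[SolverConfig] = None,
    init_state: Optional[StateFields] = None,
) -> tuple[StateFields, dict]:
    """One forward-Euler step; returns the new state and a diagnostics dict.

    All species advance simultaneously.  Negative values are clipped to zero
    and counted; ``diag["clip_count"]`` and ``diag["clip_mass"]`` report the
    number of clipped cells and the total clipped (negative) mass.
    """
    cfg = cfg or SolverConfig()
    ops = _ops(g)
    if dt == 0.0:
        return state.copy(), {"clip_count": 0, "clip_mass": 0.0, "v_max": 0.0, "min_pre_clip": 0.0}
    rates, v_max = _rhs(state, p, g, ops)
    new = StateFields(state.data + dt * rates.data)
    if cfg.outer_bc == "dirichlet" and init_state is not None:
        new.data[:, ops.eem] = init_state.data[:, ops.eem]
    if not np.isfinite(new.data).all():
        sp, r, c = np.argwhere(~np.isfinite(new.data))[0]
        raise NumericalError(
            f"non-finite state for {SPECIES[sp]} at cell ({r}, {c}) after step dt={dt}"
        )
    neg = new.data < 0.0
    clip_count = int(neg.sum())
    clip_mass = float(new.data[neg].sum()) if clip_count else 0.0
    min_pre_clip = float(new.data.min())
    if clip_count:
        new.data[neg] = 0.0
    diag = {
        "clip_count": clip_count,
        "clip_mass": clip_mass,
        "v_max": v_max,
        "min_pre_clip": min_pre_clip,
    }
    return new, diag


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def nondimensionalize(state: StateFields, scales: Dict[str, float]) -> StateFields:
    """Divide each species by its reference scale (round-trip exact)."""
    out = state.copy()
    for sp in SPECIES:
        ref = scales[sp]
        if ref <= 0:
            raise ParameterError(f"reference scale for {sp} must be positive")
        out[sp] = out[sp] / ref
    return out


def redimensionalize(state: StateFields, scales: Dict[str, float]) -> StateFields:
    """Inverse of :func:`nondimensionalize`."""
    out = state.copy()
    for sp in SPECIES:
        ref = scales[sp]
        if ref <= 0:
            raise ParameterError(f"reference scale for {sp} must be positive")
        out[sp] = out[sp] * ref
    return out


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------

def run_simulation(
    g: DomainGeometry,
    p: ParameterSet,
    init: InitialConditions,
    cfg: Optional[SolverConfig] = None,
    n0_um2: Optional[float] = None,
    keep_final_state: bool = False,
) -> Trajectory:
    """Advance the plaque microenvironment from T1 to ``cfg.t_end_months``.

    The patient's plasma monocyte level is taken from the initial-condition
    inflammation level.  Snapshots (per-species spatial means, apoptotic NC
    area, plaque burden) are emitted every ``snapshot_interval_months``.
    Deterministic: identical inputs give bitwise-identical trajectories.
    """
    cfg = cfg or SolverConfig()
    p = p.replace(C_Mo=init.C_Mo)
    state = init.build(g)
    state.validate(g)
    init_state = state.copy()
    s0 = init_state["S"]

    from .geometry import plaque_burden

    pb = plaque_burden(g).PB
    ops = _ops(g)

    dt0 = stable_timestep(p, cfg, g, state=state)
    interval = cfg.snapshot_interval_months
    if interval <= 0:
        raise ParameterError("snapshot interval must be positive")

    times = [0.0]
    means = [state.spatial_means(g)]
    nc = [nc_area(state, s0, g)]
    clip_count_total = 0
    clip_mass_total = 0.0
    min_pre_clip = 0.0

    t = 0.0
    dt_cur = dt0
    h = ops.h_nd
    sf = cfg.safety_factor
    n_snaps = int(round(cfg.t_end_months / interval)) if cfg.t_end_months > 0 else 0
    for k in range(1, n_snaps + 1):
        t_target = k * interval
        while t < t_target - 1e-12:
            dt = min(dt_cur, t_target - t)
            new_state, diag = euler_step(state, p, g, dt, cfg, init_state)
            v_max = diag["v_max"]
            hard = h / (2.0 * v_max) if v_max > 0 else math.inf
            if dt > hard:
                # taxis velocities outgrew the advective CFL bound: retry
                # this step with a tighter dt (state unchanged).
                dt_cur = sf * hard
                if dt_cur < dt0 * 1e-4:
                    raise NumericalError(
                        f"advective CFL collapse at t={t:.3f} months "
                        f"(v_max={v_max:.3g}, dt={dt_cur:.3g})"
                    )
                continue
            state = new_state
            t += dt
            clip_count_total += diag["clip_count"]
            clip_mass_total += diag["clip_mass"]
            min_pre_clip = min(min_pre_clip, diag["min_pre_clip"])
            dt_cur = min(dt0, sf * hard)
        t = t_target
        times.append(t)
        means.append(state.spatial_means(g))
        nc.append(nc_area(state, s0, g))

    series = {sp: np.array([m[sp] for m in means]) for sp in SPECIES}
    return Trajectory(
        times_months=np.asarray(times),
        species_means=series,
        nc_area_series=np.asarray(nc),
        N0=n0_um2,
        pb_series=np.full(len(times), pb),
        diagnostics={
            "dt_months": dt0,
            "clip_count": clip_count_total,
            "clip_mass": clip_mass_total,
            "min_pre_clip": min_pre_clip,
        },
        final_state=state if keep_final_state else None,
    )
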