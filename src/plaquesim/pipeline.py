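"""Two-phase patient workflow: calibrate at follow-up, then predict.

Baseline imaging cannot measure the initial inflammation burden or the
intraplaque microvessel density, so both are identified indirectly: one
simulation is run per candidate (inflammation level x microvessel level)
up to the patient's follow-up interval T2, and the pair whose simulated
necrotic-core growth best matches the observed growth is selected.  The
chosen pair then seeds a fresh simulation from baseline to the three-year
horizon T3.  Wall shear stress is held at its baseline value throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .analysis import (
    FACTORS,
    ScoreTable,
    Trajectory,
    nc_growth_rate,
)
from .errors import ParameterError, PlaquesimError
from .geometry import (
    DomainGeometry,
    generate_synthetic_geometry,
    load_label_mask,
    morphology,
)
from .params import (
    INFLAMMATION_LEVELS,
    MICROVESSEL_LEVELS,
    InitialConditions,
    ParameterSet,
)
from .solver import SolverConfig, run_simulation

__all__ = [
    "PatientRecord",
    "CalibrationResult",
    "calibrate_t2",
    "predict_t3",
    "patient_factor_values",
    "run_patient_cli",
]

logger = logging.getLogger("plaquesim")

INFLAMMATION_ORDER = ("mild", "moderate", "severe")
MICROVESSEL_ORDER = ("low", "mid", "high")

#: Fallback baseline NC area as a fraction of the intima area, used when a
#: patient record does not carry a measured T1 NC area.
DEFAULT_NC_FRACTION = 0.05


@dataclass
class PatientRecord:
    """Demographic and hemodynamic inputs for one patient (baseline, T1)."""

    id: str
    ldl: float              # plasma LDL, mg/dL
    hdl: float              # plasma HDL, mg/dL
    wss: float              # wall shear stress, dyn/cm^2
    interval_months: float  # follow-up interval T1 -> T2
    monocyte_level: Optional[str] = None  # inflammation label, if known
    geometry_path: Optional[str] = None
    nc_area_t1_um2: Optional[float] = None
    demographics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ldl <= 0 or self.hdl <= 0 or self.wss <= 0:
            raise ParameterError("LDL, HDL and WSS must be positive")
        if self.interval_months <= 0:
            raise ParameterError("follow-up interval must be positive")


@dataclass
class CalibrationResult:
    """Outcome of the T2 level-selection step."""

    inflammation_level: str
    microvessel_level: str
    simulated_growth: Dict[Tuple[str, str], float]
    observed_growth: float
    residuals: Dict[Tuple[str, str], float]

    def __post_init__(self) -> None:
        best = min(self.residuals.values())
        chosen = self.residuals[(self.inflammation_level, self.microvessel_level)]
        if chosen > best + 1e-15:
            raise ParameterError("chosen pair does not minimize the residual")


def _mildness(pair: Tuple[str, str]) -> Tuple[int, int, int]:
    i = INFLAMMATION_ORDER.index(pair[0])
    m = MICROVESSEL_ORDER.index(pair[1])
    return (i + m, i, m)


def baseline_nc_area(patient: PatientRecord, g: DomainGeometry) -> float:
    """Baseline NC area N0 (um^2): measured if recorded, else a default
    fraction of the intima area."""
    if patient.nc_area_t1_um2 is not None:
        if patient.nc_area_t1_um2 <= 0:
            raise ParameterError("recorded baseline NC area must be positive")
        return patient.nc_area_t1_um2
    return DEFAULT_NC_FRACTION * float(g.intima_mask.sum()) * g.h * g.h


def _patient_params(p: ParameterSet, patient: PatientRecord) -> ParameterSet:
    return p.replace(WSS=patient.wss, C_LDL=patient.ldl)


def calibrate_t2(
    patient: PatientRecord,
    observed_growth: float,
    g: DomainGeometry,
    p: Optional[ParameterSet] = None,
    cfg: Optional[SolverConfig] = None,
    levels: Optional[Sequence[Tuple[str, str]]] = None,
) -> CalibrationResult:
    """Select the (inflammation, microvessel) pair matching observed NC growth.

    One simulation per candidate is run to the patient's follow-up interval;
    the candidate minimizing the absolute NC-growth residual wins, with ties
    broken toward the milder pair.
    """
    if observed_growth < 0:
        raise ParameterError("observed NC growth must be nonnegative")
    p = _patient_params(p or ParameterSet(), patient)
    cfg = cfg or SolverConfig()
    if levels is None:
        levels = [(i, m) for i in INFLAMMATION_ORDER for m in MICROVESSEL_ORDER]
    if not levels:
        raise ParameterError("candidate level grid is empty")

    cal_cfg = dataclasses.replace(
        cfg,
        t_end_months=patient.interval_months,
        snapshot_interval_months=patient.interval_months,
    )
    n0 = baseline_nc_area(patient, g)

    simulated: Dict[Tuple[str, str], float] = {}
    failures: List[str] = []
    for infl, micro in levels:
        init = InitialConditions(inflammation_level=infl, microvessel_level=micro)
        try:
            traj = run_simulation(g, p, init, cal_cfg, n0_um2=n0)
        except PlaquesimError as exc:
            failures.append(f"({infl}, {micro}): {exc}")
            continue
        simulated[(infl, micro)] = nc_growth_rate(traj, patient.interval_months)
    if not simulated:
        raise ParameterError(
            "calibration failed: no candidate simulated successfully: " + "; ".join(failures)
        )

    residuals = {pair: abs(growth - observed_growth) for pair, growth in simulated.items()}
    best = min(residuals.values())
    ties = [pair for pair, res in residuals.items() if res == best]
    chosen = min(ties, key=_mildness)
    logger.info(
        "calibration %s: chose %s (residual %.4g, observed %.4g)",
        patient.id, chosen, best, observed_growth,
    )
    return CalibrationResult(
        inflammation_level=chosen[0],
        microvessel_level=chosen[1],
        simulated_growth=simulated,
        observed_growth=observed_growth,
        residuals=residuals,
    )


def predict_t3(
    patient: PatientRecord,
    calib: CalibrationResult,
    g: DomainGeometry,
    p: Optional[ParameterSet] = None,
    cfg: Optional[SolverConfig] = None,
) -> Trajectory:
    """Re-run from baseline with the calibrated levels to the 36-month horizon."""
    p = _patient_params(p or ParameterSet(), patient)
    cfg = cfg or SolverConfig()
    init = InitialConditions(
        inflammation_level=calib.inflammation_level,
        microvessel_level=calib.microvessel_level,
    )
    return run_simulation(
        g, p, init, cfg,
        n0_um2=baseline_nc_area(patient, g),
        keep_final_state=True,
    )


def patient_factor_values(
    patient: PatientRecord, g: DomainGeometry, traj: Trajectory
) -> Dict[str, float]:
    """Raw values of the eight scored risk factors for one patient.

    Morphology (PB, EI) and the blood/hemodynamic panel are baseline values;
    macrophage, SMC and ox-LDL severities are the spatial means at the end
    of the predicted trajectory (T3).
    """
    m = morphology(g)
    return {
        "PB": m.PB,
        "EI": m.EI,
        "LDL": patient.ldl,
        "HDL": patient.hdl,
        "WSS": patient.wss,
        "Mphi": float(traj.species_means["Ma"][-1]),
        "SMC": float(traj.species_means["S"][-1]),
        "oxLDL": float(traj.species_means["Lox"][-1]),
    }


# ---------------------------------------------------------------------------
# Config-driven end-to-end run
# ---------------------------------------------------------------------------

def _geometry_from_config(gcfg: dict, resolution: Optional[int] = None) -> DomainGeometry:
    if "mask" in gcfg:
        return load_label_mask(gcfg["mask"], gcfg.get("pixel_size_um", 20.0))
    if "synthetic" in gcfg:
        s = dict(gcfg["synthetic"])
        if resolution is not None:
            s["n"] = resolution
        n = int(s.get("n", 100))
        a = float(s.get("intima_a_um", 400.0))
        b = float(s.get("intima_b_um", 0.0))
        fn = (lambda th: a + b * np.cos(th)) if b else a
        return generate_synthetic_geometry(
            n=n,
            lumen_radius_um=float(s.get("lumen_radius_um", 500.0)),
            intima_thickness_fn=fn,
            media_thickness_um=float(s.get("media_thickness_um", 300.0)),
            seed=int(s.get("seed", 0)),
            h_um=float(s.get("h_um", 4000.0 / n)),
            boundary_noise_um=float(s.get("boundary_noise_um", 0.0)),
        )
    raise ParameterError("geometry config needs either 'mask' or 'synthetic'")


def _solver_config(cfg: dict) -> SolverConfig:
    scfg = cfg.get("solver", {})
    return SolverConfig(
        dt=scfg.get("dt"),
        safety_factor=float(scfg.get("safety_factor", 0.9)),
        t_end_months=float(scfg.get("t_end_months", 36.0)),
        snapshot_interval_months=float(scfg.get("snapshot_interval_months", 1.0)),
        outer_bc=scfg.get("outer_bc", "no_flux"),
    )


def _params_from_config(cfg: dict) -> ParameterSet:
    pcfg = cfg.get("parameters")
    if pcfg is None:
        return ParameterSet()
    if isinstance(pcfg, str):
        return ParameterSet.from_yaml(pcfg)
    base = ParameterSet()
    return base.replace(**{k: v for k, v in pcfg.items()})


def run_patient_cli(config_path: str | Path, output_dir: Optional[str | Path] = None) -> Path:
    """Execute calibrate -> predict -> analyze from a YAML config.

    Supports a single ``patient`` entry or a ``patients`` list (a cohort; a
    graded score table needs at least two patients).  Writes per-patient
    trajectory CSVs, calibration summaries, the score table, and a log with
    package version, seeds and parameters.  Returns the output directory.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise FileNotFoundError(f"config file not found: {config_path}")
    cfg = yaml.safe_load(config_path.read_text())
    if not isinstance(cfg, dict):
        raise ParameterError(f"config {config_path} is not a mapping")

    out = Path(output_dir or cfg.get("output_dir", "plaquesim_out"))
    out.mkdir(parents=True, exist_ok=True)

    resolution = cfg.get("resolution")
    solver_cfg = _solver_config(cfg)
    base_params = _params_from_config(cfg)

    entries = cfg.get("patients") or ([cfg["patient"]] if "patient" in cfg else None)
    if not entries:
        raise ParameterError("config must define 'patient' or 'patients'")

    rows = []
    factor_rows = {}
    for entry in entries:
        patient = PatientRecord(
            id=str(entry["id"]),
            ldl=float(entry["ldl"]),
            hdl=float(entry["hdl"]),
            wss=float(entry["wss"]),
            interval_months=float(entry["interval_months"]),
            nc_area_t1_um2=entry.get("nc_area_t1_um2"),
        )
        g = _geometry_from_config(entry.get("geometry", cfg.get("geometry", {})),
                                  resolution=resolution)
        observed = float(entry.get("observed_nc_growth", cfg.get("observed_nc_growth")))
        calib = calibrate_t2(patient, observed, g, base_params, solver_cfg)
        traj = predict_t3(patient, calib, g, base_params, solver_cfg)
        traj.to_frame().to_csv(out / f"trajectory_{patient.id}.csv", index=False)
        factor_rows[patient.id] = patient_factor_values(patient, g, traj)
        rows.append(
            {
                "patient": patient.id,
                "inflammation_level": calib.inflammation_level,
                "microvessel_level": calib.microvessel_level,
                "observed_nc_growth_t2": observed,
                "nc_growth_t3": nc_growth_rate(traj, solver_cfg.t_end_months),
                "dt_months": traj.diagnostics["dt_months"],
                "clip_count": traj.diagnostics["clip_count"],
            }
        )

    summary = pd.DataFrame(rows).set_index("patient")
    summary.to_csv(out / "calibration_summary.csv")
    values = pd.DataFrame(factor_rows).T[list(FACTORS)]
    values.to_csv(out / "factor_values.csv")
    if len(values) >= 2:
        table = ScoreTable.from_values(values)
        table.to_frame().to_csv(out / "score_table.csv")

    from . import __version__

    log = {
        "plaquesim_version": __version__,
        "config": str(config_path),
        "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
        "seed": cfg.get("seed", 0),
        "resolution": resolution,
        "solver": dataclasses.asdict(solver_cfg),
        "n_patients": len(entries),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out
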