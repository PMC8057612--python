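"""Fully synthetic four-patient cohorts for end-to-end testing.

No imaging data ships with the package, so this module fabricates what the
pipeline needs: eccentric annular cross-section geometries standing in for
segmented VH-IVUS slices, patient records whose lipid panel, shear stress
and follow-up interval bracket the clinically observed ranges, hidden true
(inflammation, microvessel) levels, and an "observed" follow-up NC growth
obtained by simulating with those truths.  Everything is deterministic under
a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .analysis import (
    FACTORS,
    ScoreTable,
    Trajectory,
    group_ttest,
    nc_growth_rate,
    spearman_nc_correlation,
)
from .errors import ParameterError
from .geometry import DomainGeometry, generate_synthetic_geometry, save_label_mask
from .params import InitialConditions, ParameterSet
from .pipeline import (
    PatientRecord,
    baseline_nc_area,
    calibrate_t2,
    patient_factor_values,
    predict_t3,
)
from .solver import SolverConfig, run_simulation

__all__ = [
    "CohortSpec",
    "CohortPatient",
    "CohortAnalysis",
    "generate_cohort",
    "generate_observed_followup",
    "run_cohort_analysis",
    "write_cohort",
]

#: Fig-4-style compared variables -> species keys.
COMPARED_VARIABLES = {
    "LDL": "L",
    "ox-LDL": "Lox",
    "Monocyte": "Mo",
    "Macrophage": "Ma",
    "MCP-1": "P",
    "SMC": "S",
    "ECM": "CECM",
    "Foam cell": "F",
}

#: Default hidden truths: two stable-like, two unstable-like patients,
#: mirroring a 2/2 grouping of low vs high inflammation regimes.
DEFAULT_TRUTHS: Tuple[Tuple[str, str], ...] = (
    ("mild", "low"),
    ("mild", "mid"),
    ("severe", "mid"),
    ("severe", "high"),
)


@dataclass
class CohortSpec:
    """Declarative description of a synthetic cohort.

    Record values are drawn uniformly from group-specific sub-ranges of the
    declared brackets: stable-like patients get lower LDL, higher HDL and
    higher WSS than unstable-like ones.  The LDL bracket [70, 160] mg/dL
    spans the clinically reported 70.4-157.8 range.
    """

    n_patients: int = 4
    seed: int = 0
    grid_n: int = 100
    frame_um: float = 4000.0
    lumen_radius_range_um: Tuple[float, float] = (400.0, 600.0)
    intima_base_range_um: Tuple[float, float] = (350.0, 500.0)
    intima_ecc_range_um: Tuple[float, float] = (100.0, 250.0)
    media_thickness_um: float = 280.0
    ldl_bracket: Tuple[float, float] = (70.0, 160.0)
    hdl_bracket: Tuple[float, float] = (19.0, 38.0)
    wss_bracket: Tuple[float, float] = (77.0, 141.0)
    interval_choices_months: Tuple[int, ...] = (11, 12, 13)
    nc_fraction_range: Tuple[float, float] = (0.05, 0.15)
    truths: Tuple[Tuple[str, str], ...] = DEFAULT_TRUTHS

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("cohort needs at least one patient")
        if len(self.truths) < self.n_patients:
            raise ParameterError("need one truth pair per patient")
        for lo, hi in (
            self.lumen_radius_range_um,
            self.intima_base_range_um,
            self.intima_ecc_range_um,
            self.ldl_bracket,
            self.hdl_bracket,
            self.wss_bracket,
        ):
            if not (0 < lo <= hi):
                raise ParameterError("ranges must be positive and ordered")


@dataclass
class CohortPatient:
    """One synthetic patient: record, geometry, hidden truth, design group."""

    record: PatientRecord
    geometry: DomainGeometry
    truth: Tuple[str, str]
    group: str  # "stable-like" or "unstable-like"


def _split(bracket: Tuple[float, float], lower_half: bool) -> Tuple[float, float]:
    lo, hi = bracket
    mid = 0.5 * (lo + hi)
    return (lo, mid) if lower_half else (mid, hi)


def generate_cohort(spec: Optional[CohortSpec] = None) -> List[CohortPatient]:
    """Generate patients, geometries and hidden truths from a spec.

    Patients with a ``mild`` true inflammation level form the stable-like
    group; all others are unstable-like.  Same seed, same cohort.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    h_um = spec.frame_um / spec.grid_n
    patients: List[CohortPatient] = []
    for i in range(spec.n_patients):
        truth = spec.truths[i]
        stable_like = truth[0] == "mild"
        group = "stable-like" if stable_like else "unstable-like"

        lumen_r = rng.uniform(*spec.lumen_radius_range_um)
        base = rng.uniform(*spec.intima_base_range_um)
        ecc = rng.uniform(*spec.intima_ecc_range_um)
        phase = rng.uniform(0.0, 2 * np.pi)
        geom_seed = int(rng.integers(0, 2**31 - 1))
        g = generate_synthetic_geometry(
            n=spec.grid_n,
            lumen_radius_um=lumen_r,
            intima_thickness_fn=lambda th, a=base, b=ecc, p0=phase: a + b * np.cos(th - p0),
            media_thickness_um=spec.media_thickness_um,
            seed=geom_seed,
            h_um=h_um,
        )

        ldl = rng.uniform(*_split(spec.ldl_bracket, lower_half=stable_like))
        hdl = rng.uniform(*_split(spec.hdl_bracket, lower_half=not stable_like))
        wss = rng.uniform(*_split(spec.wss_bracket, lower_half=not stable_like))
        interval = float(rng.choice(spec.interval_choices_months))
        nc_frac = rng.uniform(*spec.nc_fraction_range)
        intima_area = float(g.intima_mask.sum()) * h_um * h_um

        record = PatientRecord(
            id=f"SP{i + 1}",
            ldl=float(ldl),
            hdl=float(hdl),
            wss=float(wss),
            interval_months=interval,
            monocyte_level=truth[0],
            nc_area_t1_um2=nc_frac * intima_area,
        )
        patients.append(CohortPatient(record=record, geometry=g, truth=truth, group=group))
    return patients


def generate_observed_followup(
    patient: PatientRecord,
    truth: Tuple[str, str],
    g: DomainGeometry,
    p: Optional[ParameterSet] = None,
    cfg: Optional[SolverConfig] = None,
    noise: float = 0.0,
    seed: int = 0,
) -> float:
    """Simulated "observed" NC growth at T2 under the hidden truth levels.

    Plays the role of the follow-up image measurement: the truth levels are
    simulated to the patient's interval and the resulting growth rate is
    perturbed multiplicatively by a seed-controlled Gaussian of relative
    standard deviation ``noise``.
    """
    if noise < 0:
        raise ParameterError("noise must be nonnegative")
    p = (p or ParameterSet()).replace(WSS=patient.wss, C_LDL=patient.ldl)
    cfg = cfg or SolverConfig()
    cal_cfg = dataclasses.replace(
        cfg,
        t_end_months=patient.interval_months,
        snapshot_interval_months=patient.interval_months,
    )
    init = InitialConditions(inflammation_level=truth[0], microvessel_level=truth[1])
    traj = run_simulation(g, p, init, cal_cfg, n0_um2=baseline_nc_area(patient, g))
    growth = nc_growth_rate(traj, patient.interval_months)
    if noise > 0.0:
        rng = np.random.default_rng(seed)
        growth *= 1.0 + noise * rng.standard_normal()
    return max(growth, 0.0)


@dataclass
class CohortAnalysis:
    """End-to-end results for a synthetic cohort."""

    summary: pd.DataFrame          # per patient: truth, recovered, growth, score
    score_table: ScoreTable
    ttests: pd.DataFrame           # per variable: Welch statistic, p, significance
    correlations: pd.DataFrame     # per group x variable: Spearman r, p
    trajectories: Dict[str, Trajectory]
    patients: List[CohortPatient]


def run_cohort_analysis(
    spec: Optional[CohortSpec] = None,
    p: Optional[ParameterSet] = None,
    cfg: Optional[SolverConfig] = None,
    noise: float = 0.0,
) -> CohortAnalysis:
    """Cohort -> observe -> calibrate -> predict -> score -> group statistics.

    Stable-like vs unstable-like groups follow the cohort's design labels;
    the Welch t-tests pool each variable's monthly spatial means across the
    members of a group, and the Spearman correlations pair each variable's
    series with the NC area series within a group.  Deterministic under the
    spec's master seed.
    """
    spec = spec or CohortSpec()
    p = p or ParameterSet()
    cfg = cfg or SolverConfig()
    patients = generate_cohort(spec)

    trajectories: Dict[str, Trajectory] = {}
    factor_rows: Dict[str, Dict[str, float]] = {}
    rows = []
    for i, cp in enumerate(patients):
        observed = generate_observed_followup(
            cp.record, cp.truth, cp.geometry, p, cfg,
            noise=noise, seed=spec.seed + 1000 + i,
        )
        calib = calibrate_t2(cp.record, observed, cp.geometry, p, cfg)
        traj = predict_t3(cp.record, calib, cp.geometry, p, cfg)
        trajectories[cp.record.id] = traj
        factor_rows[cp.record.id] = patient_factor_values(cp.record, cp.geometry, traj)
        rows.append(
            {
                "patient": cp.record.id,
                "group": cp.group,
                "true_inflammation": cp.truth[0],
                "true_microvessel": cp.truth[1],
                "recovered_inflammation": calib.inflammation_level,
                "recovered_microvessel": calib.microvessel_level,
                "observed_nc_growth_t2": observed,
                "nc_growth_t3": nc_growth_rate(traj, cfg.t_end_months),
            }
        )

    values = pd.DataFrame(factor_rows).T[list(FACTORS)]
    table = ScoreTable.from_values(values)
    summary = pd.DataFrame(rows).set_index("patient")
    summary["total_score"] = table.totals
    summary["fate"] = table.labels

    groups: Dict[str, List[str]] = {"stable-like": [], "unstable-like": []}
    for cp in patients:
        groups[cp.group].append(cp.record.id)

    ttest_rows, corr_rows = [], []
    for name, sp in COMPARED_VARIABLES.items():
        pooled = {
            grp: np.concatenate([trajectories[pid].species_means[sp] for pid in ids])
            for grp, ids in groups.items()
            if ids
        }
        if len(pooled) == 2:
            res = group_ttest(pooled["stable-like"], pooled["unstable-like"])
            ttest_rows.append(
                {
                    "variable": name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "significant_0.01": res.significant,
                    "degenerate": res.degenerate,
                }
            )
        for grp, ids in groups.items():
            if not ids:
                continue
            x = np.concatenate([trajectories[pid].species_means[sp] for pid in ids])
            y = np.concatenate([trajectories[pid].nc_total_series for pid in ids])
            corr = spearman_nc_correlation(x, y)
            corr_rows.append(
                {
                    "group": grp,
                    "variable": name,
                    "r": corr.r,
                    "p_value": corr.p_value,
                    "undefined": corr.undefined,
                }
            )

    return CohortAnalysis(
        summary=summary,
        score_table=table,
        ttests=pd.DataFrame(ttest_rows),
        correlations=pd.DataFrame(corr_rows),
        trajectories=trajectories,
        patients=patients,
    )


def write_cohort(patients: Sequence[CohortPatient], out_dir: str | Path) -> Path:
    """Write masks (PNG), records (CSV) and truths (CSV, test-only) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, truth_rows = [], []
    for cp in patients:
        mask_path = out / f"mask_{cp.record.id}.png"
        save_label_mask(cp.geometry, mask_path)
        rows.append(
            {
                "id": cp.record.id,
                "ldl_mg_dl": cp.record.ldl,
                "hdl_mg_dl": cp.record.hdl,
                "wss_dyn_cm2": cp.record.wss,
                "interval_months": cp.record.interval_months,
                "nc_area_t1_um2": cp.record.nc_area_t1_um2,
                "mask": mask_path.name,
                "pixel_size_um": cp.geometry.h,
            }
        )
        truth_rows.append(
            {
                "id": cp.record.id,
                "inflammation_level": cp.truth[0],
                "microvessel_level": cp.truth[1],
                "group": cp.group,
            }
        )
    pd.DataFrame(rows).to_csv(out / "records.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "truths.csv", index=False)
    return out
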