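"""Necrotic-core metrics, the multi-factor risk score, and cohort statistics.

The necrotic core (NC) is operationalized as the intima area where SMC
density fell below half of its initial value; plaque development is tracked
by the growth rate N(t)/N0, where N0 is the NC area measured at baseline.
Eight risk factors (plaque burden, eccentricity index, plasma LDL and HDL,
wall shear stress, and the simulated macrophage, SMC and ox-LDL levels at
the three-year horizon) are each graded 1 = mild, 2 = moderate, 3 = severe
by comparing the patients against each other; the total over the eight
grades classifies a plaque as stable or vulnerable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, PlaquesimError
from .geometry import DomainGeometry, Region
from .state import SPECIES, StateFields

__all__ = [
    "Trajectory",
    "ScoreTable",
    "FACTORS",
    "nc_area",
    "nc_growth_rate",
    "score_factor",
    "total_score",
    "classify_plaque",
    "group_ttest",
    "spearman_nc_correlation",
    "TTestResult",
    "CorrelationResult",
]

#: The eight scored risk factors, in reporting order.
FACTORS = ("PB", "EI", "LDL", "HDL", "WSS", "Mphi", "SMC", "oxLDL")

#: Grading direction per factor: does a larger value mean more severe?
FACTOR_DIRECTIONS: Dict[str, str] = {
    "PB": "higher_worse",
    "EI": "higher_worse",
    "LDL": "higher_worse",
    "HDL": "lower_worse",
    "WSS": "lower_worse",
    "Mphi": "higher_worse",
    "SMC": "lower_worse",
    "oxLDL": "higher_worse",
}

#: Total-score threshold separating stable from vulnerable plaques.
VULNERABLE_THRESHOLD = 18


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time series of field summaries plus NC area and plaque burden.

    ``nc_area_series`` holds the apoptotic (newly necrotic) area in um^2;
    the total NC area at time t is ``N0 + nc_area_series`` when the baseline
    NC area ``N0`` is known.
    """

    times_months: np.ndarray
    species_means: Dict[str, np.ndarray]
    nc_area_series: np.ndarray
    N0: Optional[float] = None
    pb_series: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)
    final_state: Optional[StateFields] = None

    def __post_init__(self) -> None:
        n = len(self.times_months)
        if len(self.nc_area_series) != n:
            raise ParameterError("NC series length does not match time axis")
        for sp, series in self.species_means.items():
            if len(series) != n:
                raise ParameterError(f"series length mismatch for {sp}")
        if np.any(self.nc_area_series < 0):
            raise ParameterError("NC area must be nonnegative")

    @property
    def nc_total_series(self) -> np.ndarray:
        if self.N0 is None:
            raise ParameterError("baseline NC area N0 is not set")
        return self.N0 + self.nc_area_series

    def to_frame(self) -> pd.DataFrame:
        """One row per snapshot: time, species means, NC area, PB."""
        data = {"time_months": self.times_months}
        data.update({sp: self.species_means[sp] for sp in SPECIES})
        data["nc_apoptotic_area_um2"] = self.nc_area_series
        if self.N0 is not None:
            data["nc_area_um2"] = self.nc_total_series
            data["nc_growth_rate"] = self.nc_total_series / self.N0
        if self.pb_series is not None:
            data["plaque_burden"] = self.pb_series
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# NC metrics
# ---------------------------------------------------------------------------

def nc_area(state: StateFields, initial_smc: np.ndarray, g: DomainGeometry) -> float:
    """Apoptotic NC area: intima cells whose SMC density dropped by >50%.

    A cell at exactly half its initial value is *not* counted (the decrease
    must exceed 50%).  Contiguity is not required.  Returns um^2.
    """
    s = state["S"] if isinstance(state, StateFields) else np.asarray(state)
    initial_smc = np.asarray(initial_smc)
    if s.shape != g.labels.shape or initial_smc.shape != g.labels.shape:
        raise ParameterError("SMC fields do not match the geometry")
    intima = g.intima_mask
    necrotic = intima & (initial_smc > 0) & (s < 0.5 * initial_smc)
    return float(necrotic.sum()) * g.h * g.h


def nc_growth_rate(traj: Trajectory, t: float | np.ndarray) -> float | np.ndarray:
    """NC growth rate N(t)/N0 at time t (months), interpolated on snapshots."""
    if traj.N0 is None or traj.N0 <= 0:
        raise ParameterError("NC growth rate undefined: baseline NC area N0 must be positive")
    total = traj.nc_total_series
    val = np.interp(t, traj.times_months, total) / traj.N0
    return float(val) if np.isscalar(t) else val


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_factor(values: Sequence[float], direction: str) -> np.ndarray:
    """Grade patients 1-3 on one factor by min-max thirds.

    The observed range is split into three equal-width bins; the worst third
    (per ``direction``) receives grade 3, the best third grade 1, the middle
    grade 2.  A value exactly on a bin boundary takes the milder grade.  If
    all values coincide every patient is graded 2.
    """
    if direction not in ("higher_worse", "lower_worse"):
        raise ParameterError(f"unknown grading direction {direction!r}")
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ParameterError("grading needs at least two patients")
    if not np.isfinite(vals).all():
        raise ParameterError("grading needs finite values")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        return np.full(vals.shape, 2, dtype=int)
    c1 = lo + (hi - lo) / 3.0
    c2 = lo + 2.0 * (hi - lo) / 3.0
    grades = np.full(vals.shape, 2, dtype=int)
    if direction == "higher_worse":
        grades[vals <= c1] = 1
        grades[vals > c2] = 3
    else:
        grades[vals >= c2] = 1
        grades[vals < c1] = 3
    return grades


def total_score(grades: Iterable[int]) -> int:
    """Sum of the eight per-factor grades (range 8-24)."""
    glist = list(grades)
    if len(glist) != len(FACTORS):
        raise ParameterError(f"expected {len(FACTORS)} grades, got {len(glist)}")
    for grade in glist:
        if int(grade) != grade or not (1 <= int(grade) <= 3):
            raise ParameterError(f"grades must be integers in 1..3, got {grade!r}")
    return int(sum(int(x) for x in glist))


def classify_plaque(total: int, composition_flags: Sequence[str] = ()) -> str:
    """Fate label from the total score: vulnerable at or above the threshold.

    Stable plaques are annotated with any supplied composition flags
    (e.g. ``["macrocalcification"]``).
    """
    if not (len(FACTORS) <= total <= 3 * len(FACTORS)):
        raise ParameterError(f"total score {total} outside the admissible range")
    if total >= VULNERABLE_THRESHOLD:
        return "vulnerable"
    if composition_flags:
        return "stable (" + ", ".join(composition_flags) + ")"
    return "stable"


@dataclass
class ScoreTable:
    """Per-patient 1-3 grades for the eight factors, totals, and fate labels."""

    patients: Tuple[str, ...]
    grades: pd.DataFrame  # index: patients, columns: FACTORS
    totals: Tuple[int, ...]
    labels: Tuple[str, ...]

    @classmethod
    def from_values(
        cls,
        values: pd.DataFrame,
        composition_flags: Optional[Dict[str, Sequence[str]]] = None,
    ) -> "ScoreTable":
        """Grade a cohort from raw per-patient factor values.

        ``values`` has one row per patient and one column per factor name in
        :data:`FACTORS`.
        """
        missing = set(FACTORS) - set(values.columns)
        if missing:
            raise ParameterError(f"missing factor columns {sorted(missing)}")
        grades = pd.DataFrame(index=values.index, columns=list(FACTORS), dtype=int)
        for f in FACTORS:
            grades[f] = score_factor(values[f].to_numpy(), FACTOR_DIRECTIONS[f])
        totals = tuple(total_score(row) for row in grades.to_numpy())
        flags = composition_flags or {}
        labels = tuple(
            classify_plaque(tot, flags.get(str(pid), ()))
            for pid, tot in zip(values.index, totals)
        )
        return cls(
            patients=tuple(str(i) for i in values.index),
            grades=grades,
            totals=totals,
            labels=labels,
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.grades.copy()
        out["total"] = self.totals
        out["fate"] = self.labels
        return out


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    degenerate: bool = False
    significant: bool = False  # at the 0.01 level


def group_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Welch two-sample t-test between pooled factor observations.

    Observations are per-patient spatial-mean values sampled along the
    trajectories and pooled within each group.  Significance is reported at
    the 0.01 level.  If both groups have zero variance the test is flagged
    degenerate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least two observations")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, degenerate=True)
        return TTestResult(np.inf, 0.0, degenerate=True, significant=True)
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(stat), float(p), significant=bool(p < 0.01))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    undefined: bool = False


def spearman_nc_correlation(
    factor_series: Sequence[float], nc_series: Sequence[float]
) -> CorrelationResult:
    """Spearman rank correlation of a factor series against NC area.

    Average ranks are used for ties.  Constant input on either side makes
    the coefficient undefined, reported via the ``undefined`` flag.
    """
    x = np.asarray(factor_series, dtype=float)
    y = np.asarray(nc_series, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("paired series must have equal length")
    if x.size < 3:
        raise ParameterError("Spearman correlation needs at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(float("nan"), float("nan"), undefined=True)
    r, p = stats.spearmanr(x, y)
    return CorrelationResult(float(r), float(p))
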