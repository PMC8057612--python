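"""Labeled 2D vessel cross-section domains and their morphology metrics.

The simulation arena is a uniform Cartesian grid whose cells carry one of
four region labels: exterior (outside the external elastic membrane, EEM),
lumen, thickening intima, and media.  The plaque wall (intima + media) is the
PDE domain; the lumen and exterior only define boundaries.  Two morphology
indices used in plaque risk assessment are computed here:

* plaque burden  PB = plaque area / (plaque area + lumen area)
* eccentricity index  EI = 1 - WT_min / WT_max

where WT_min / WT_max are the minimum and maximum wall thickness measured on
equiangular rays cast from the lumen centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Callable, FrozenSet, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import GeometryError, MaskFormatError, ParameterError

__all__ = [
    "Region",
    "DomainGeometry",
    "MorphologyMetrics",
    "load_label_mask",
    "save_label_mask",
    "generate_synthetic_geometry",
    "plaque_burden",
    "eccentricity_index",
    "morphology",
]

#: Default cell edge length: a 4 mm frame divided into 200 cells.
DEFAULT_H_UM = 20.0
DEFAULT_GRID = 200

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class Region(IntEnum):
    """Region codes of a labeled cross-section mask."""

    EXTERIOR = 0
    LUMEN = 1
    INTIMA = 2
    MEDIA = 3


def _adjacent_to(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Cells of ``mask_a`` with at least one 4-neighbor in ``mask_b``."""
    grown = ndimage.binary_dilation(mask_b, structure=_FOUR_CONNECTED)
    return mask_a & grown


@dataclass(frozen=True, eq=False)
class DomainGeometry:
    """A validated labeled grid with derived boundary cell sets.

    Parameters
    ----------
    labels
        Integer array of shape ``(n_rows, n_cols)`` with :class:`Region` codes.
    h
        Cell edge length in micrometres.
    """

    labels: np.ndarray
    h: float = DEFAULT_H_UM

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.ndim != 2:
            raise GeometryError("label mask must be a 2D array")
        if self.h <= 0:
            raise ParameterError(f"cell size h must be positive, got {self.h}")
        valid = {int(r) for r in Region}
        present = set(np.unique(labels).tolist())
        if not present <= valid:
            raise MaskFormatError(
                f"unknown label codes {sorted(present - valid)}; expected subset of {sorted(valid)}"
            )
        lumen = labels == Region.LUMEN
        if not lumen.any():
            raise GeometryError("geometry has no lumen cells")
        _, n_comp = ndimage.label(lumen, structure=_FOUR_CONNECTED)
        if n_comp != 1:
            raise GeometryError(f"lumen must be a single 4-connected component, found {n_comp}")
        object.__setattr__(self, "labels", labels)

    # -- basic shape ------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.labels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.labels.shape[1]

    # -- region masks -----------------------------------------------------
    @property
    def lumen_mask(self) -> np.ndarray:
        return self.labels == Region.LUMEN

    @property
    def intima_mask(self) -> np.ndarray:
        return self.labels == Region.INTIMA

    @property
    def media_mask(self) -> np.ndarray:
        return self.labels == Region.MEDIA

    @property
    def exterior_mask(self) -> np.ndarray:
        return self.labels == Region.EXTERIOR

    @property
    def tissue_mask(self) -> np.ndarray:
        """Intima plus media: the PDE domain."""
        return self.intima_mask | self.media_mask

    # -- boundary cell sets ----------------------------------------------
    @property
    def endothelium_mask(self) -> np.ndarray:
        """Intima cells 4-adjacent to the lumen (the endothelial layer)."""
        return _adjacent_to(self.intima_mask, self.lumen_mask)

    @property
    def eem_mask(self) -> np.ndarray:
        """Media cells 4-adjacent to the exterior (the EEM rim)."""
        return _adjacent_to(self.media_mask, self.exterior_mask)

    @property
    def endothelium_cells(self) -> FrozenSet[Tuple[int, int]]:
        return frozenset(zip(*np.nonzero(self.endothelium_mask)))

    @property
    def eem_cells(self) -> FrozenSet[Tuple[int, int]]:
        return frozenset(zip(*np.nonzero(self.eem_mask)))

    @property
    def lumen_centroid(self) -> Tuple[float, float]:
        """(row, col) centroid of the lumen region, in cell coordinates."""
        rows, cols = np.nonzero(self.lumen_mask)
        return float(rows.mean()), float(cols.mean())


@dataclass(frozen=True)
class MorphologyMetrics:
    """Cross-sectional morphology indices of a plaque."""

    plaque_area: float  # um^2
    lumen_area: float  # um^2
    PB: float  # plaque burden, dimensionless in [0, 1)
    wt_min: float = math.nan  # um
    wt_max: float = math.nan  # um
    EI: float = math.nan  # eccentricity index in [0, 1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.PB < 1.0):
            raise GeometryError(f"plaque burden out of range: {self.PB}")
        if not math.isnan(self.EI) and not (0.0 <= self.EI <= 1.0 + 1e-12):
            raise GeometryError(f"eccentricity index out of range: {self.EI}")
        if not math.isnan(self.wt_min) and self.wt_min > self.wt_max:
            raise GeometryError("wt_min exceeds wt_max")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TEXT_SUFFIXES = {".txt", ".dat", ".grid", ".asc"}


def load_label_mask(path: str | Path, pixel_size_um: float = DEFAULT_H_UM) -> DomainGeometry:
    """Load a labeled cross-section mask from an image or text grid.

    Accepts an 8-bit single-channel PNG/TIFF whose pixel values are the raw
    region codes {0,1,2,3}, or a whitespace-delimited integer grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label mask not found: {path}")
    if path.suffix.lower() in _TEXT_SUFFIXES:
        try:
            arr = np.loadtxt(path, dtype=np.int64)
        except ValueError as exc:
            raise MaskFormatError(f"cannot parse text grid {path}: {exc}") from exc
        arr = np.atleast_2d(arr)
    else:
        with Image.open(path) as img:
            if img.mode not in ("L", "P", "I", "I;16"):
                img = img.convert("L")
            arr = np.asarray(img, dtype=np.int64)
        if arr.ndim != 2:
            raise MaskFormatError(f"{path} is not a single-channel image")
    return DomainGeometry(labels=arr.astype(np.int8), h=float(pixel_size_um))


def save_label_mask(g: DomainGeometry, path: str | Path) -> Path:
    """Write a geometry's labels as an 8-bit grayscale image or text grid."""
    path = Path(path)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        np.savetxt(path, g.labels, fmt="%d")
    else:
        Image.fromarray(g.labels.astype(np.uint8), mode="L").save(path)
    return path


# ---------------------------------------------------------------------------
# Synthetic geometry
# ---------------------------------------------------------------------------

def generate_synthetic_geometry(
    n: int = DEFAULT_GRID,
    lumen_radius_um: float = 500.0,
    intima_thickness_fn: Callable[[np.ndarray], np.ndarray] | float = 400.0,
    media_thickness_um: float = 300.0,
    seed: int = 0,
    h_um: float = DEFAULT_H_UM,
    boundary_noise_um: float = 0.0,
) -> DomainGeometry:
    """Generate an annular cross-section emulating a segmented IVUS slice.

    The lumen is a centred disc; the intima outer boundary sits at
    ``lumen_radius + intima_thickness_fn(angle)`` and the EEM a constant
    ``media_thickness_um`` further out.  Eccentric plaques are produced by an
    angle-dependent intima thickness.  Deterministic for a fixed seed.
    """
    if n < 8:
        raise ParameterError("grid too small")
    if callable(intima_thickness_fn):
        thickness = intima_thickness_fn
    else:
        const = float(intima_thickness_fn)
        thickness = lambda theta: np.full_like(theta, const)  # noqa: E731

    rows = np.arange(n)[:, None] - (n - 1) / 2.0
    cols = np.arange(n)[None, :] - (n - 1) / 2.0
    r_um = np.hypot(rows, cols) * h_um
    theta = np.arctan2(-rows, cols)  # math convention, y up

    ti = np.asarray(thickness(theta), dtype=float)
    if np.any(ti <= 0) or lumen_radius_um <= 0 or media_thickness_um <= 0:
        raise ParameterError("radii and thicknesses must be positive")
    if boundary_noise_um > 0.0:
        rng = np.random.default_rng(seed)
        n_harm = 8
        amp = rng.normal(0.0, boundary_noise_um, size=n_harm)
        phase = rng.uniform(0.0, 2 * np.pi, size=n_harm)
        for k in range(n_harm):
            ti = ti + amp[k] * np.cos((k + 2) * theta + phase[k])
        ti = np.clip(ti, h_um, None)

    r_intima = lumen_radius_um + ti
    r_eem = r_intima + media_thickness_um
    if float(r_eem.max()) >= (n / 2.0 - 1.0) * h_um:
        raise ParameterError(
            f"geometry exceeds grid: outer radius {r_eem.max():.0f} um on a "
            f"{n}x{n} grid of {h_um} um cells"
        )

    labels = np.zeros((n, n), dtype=np.int8)
    labels[r_um <= r_eem] = Region.MEDIA
    labels[r_um <= r_intima] = Region.INTIMA
    labels[r_um <= lumen_radius_um] = Region.LUMEN
    return DomainGeometry(labels=labels, h=h_um)


# ---------------------------------------------------------------------------
# Morphology metrics
# ---------------------------------------------------------------------------

def plaque_burden(g: DomainGeometry, include_media: bool = True) -> MorphologyMetrics:
    """Plaque burden from cell-count areas.

    Plaque area is the area between the lumen and the outer boundary
    (intima + media); set ``include_media=False`` for the intima-only variant.
    """
    h2 = g.h * g.h
    plaque_cells = int(g.intima_mask.sum())
    if include_media:
        plaque_cells += int(g.media_mask.sum())
    plaque_area = plaque_cells * h2
    lumen_area = int(g.lumen_mask.sum()) * h2
    denom = plaque_area + lumen_area
    pb = plaque_area / denom if denom > 0 else 0.0
    return MorphologyMetrics(plaque_area=plaque_area, lumen_area=lumen_area, PB=pb)


def _wall_thickness_profile(g: DomainGeometry, n_rays: int) -> np.ndarray:
    """Wall thickness (um) along equiangular rays from the lumen centroid.

    Each ray is sampled at quarter-cell steps; the wall spans from the first
    non-lumen sample to the last non-exterior sample.
    """
    r0, c0 = g.lumen_centroid
    nr, nc = g.labels.shape
    step = 0.25  # cells
    max_t = int(math.hypot(nr, nc) / step) + 2
    t = np.arange(1, max_t) * step
    thickness = np.empty(n_rays, dtype=float)
    for k in range(n_rays):
        ang = 2.0 * math.pi * k / n_rays
        dr, dc = -math.sin(ang), math.cos(ang)
        rr = np.rint(r0 + t * dr).astype(int)
        cc = np.rint(c0 + t * dc).astype(int)
        inside = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
        if not inside.all():
            last = int(np.argmin(inside))
            rr, cc, tt = rr[:last], cc[:last], t[:last]
        else:
            tt = t
        lab = g.labels[rr, cc]
        non_lumen = np.nonzero(lab != Region.LUMEN)[0]
        exterior = np.nonzero(lab == Region.EXTERIOR)[0]
        if non_lumen.size == 0 or exterior.size == 0:
            raise GeometryError(f"ray {k} ({math.degrees(ang):.1f} deg) never exits the wall")
        # midpoint between the last sample inside and first outside halves
        # the sampling bias of the crossing estimate
        i_en, i_ex = non_lumen[0], exterior[0]
        t_enter = tt[i_en] if i_en == 0 else 0.5 * (tt[i_en] + tt[i_en - 1])
        t_exit = tt[i_ex] if i_ex == 0 else 0.5 * (tt[i_ex] + tt[i_ex - 1])
        if t_exit <= t_enter:
            raise GeometryError(f"ray {k}: wall does not enclose the lumen")
        thickness[k] = (t_exit - t_enter) * g.h
    return thickness


def eccentricity_index(g: DomainGeometry, n_rays: int = 360) -> MorphologyMetrics:
    """Eccentricity index EI = 1 - WT_min/WT_max by equiangular ray casting."""
    if n_rays < 4:
        raise ParameterError("need at least 4 rays")
    wt = _wall_thickness_profile(g, n_rays)
    wt_min, wt_max = float(wt.min()), float(wt.max())
    ei = 1.0 - wt_min / wt_max if wt_max > 0 else 0.0
    base = plaque_burden(g)
    return MorphologyMetrics(
        plaque_area=base.plaque_area,
        lumen_area=base.lumen_area,
        PB=base.PB,
        wt_min=wt_min,
        wt_max=wt_max,
        EI=ei,
    )


def morphology(g: DomainGeometry, n_rays: int = 360, include_media: bool = True) -> MorphologyMetrics:
    """All morphology metrics (PB, wall thickness range, EI) in one pass."""
    wt = _wall_thickness_profile(g, n_rays)
    base = plaque_burden(g, include_media=include_media)
    wt_min, wt_max = float(wt.min()), float(wt.max())
    return MorphologyMetrics(
        plaque_area=base.plaque_area,
        lumen_area=base.lumen_area,
        PB=base.PB,
        wt_min=wt_min,
        wt_max=wt_max,
        EI=1.0 - wt_min / wt_max if wt_max > 0 else 0.0,
    )
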