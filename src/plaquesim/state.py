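"""The twelve-field simulation state container."""

from __future__ import annotations

from typing import Dict, Iterator

import numpy as np

from .errors import NumericalError, ParameterError
from .geometry import DomainGeometry

#: The twelve model fields, in canonical order.
#: L: LDL, Lox: ox-LDL, P: MCP-1, Mo: monocytes, Ma: macrophages, F: foam
#: cells, S: SMCs, CECM: ECM, CM: MMP, E: endothelial cells (continuum
#: microvessel density), Cv: VEGF, Pl: extravascular plasma (IPH proxy).
SPECIES = ("L", "Lox", "P", "Mo", "Ma", "F", "S", "CECM", "CM", "E", "Cv", "Pl")

_INDEX = {sp: i for i, sp in enumerate(SPECIES)}


class StateFields:
    """Per-cell nondimensional concentrations of the twelve model fields.

    Stored as one ``(12, n_rows, n_cols)`` array; values on lumen and
    exterior cells are identically zero and are never updated.
    """

    __slots__ = ("data",)

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=float)
        if data.ndim != 3 or data.shape[0] != len(SPECIES):
            raise ParameterError(
                f"state array must have shape (12, n_rows, n_cols), got {data.shape}"
            )
        self.data = data

    # -- constructors ----------------------------------------------------
    @classmethod
    def zeros(cls, g: DomainGeometry) -> "StateFields":
        return cls(np.zeros((len(SPECIES),) + g.labels.shape))

    @classmethod
    def from_dict(cls, fields: Dict[str, np.ndarray]) -> "StateFields":
        missing = set(SPECIES) - set(fields)
        if missing:
            raise ParameterError(f"missing species {sorted(missing)}")
        return cls(np.stack([np.asarray(fields[sp], dtype=float) for sp in SPECIES]))

    # -- access ----------------------------------------------------------
    def __getitem__(self, species: str) -> np.ndarray:
        return self.data[_INDEX[species]]

    def __setitem__(self, species: str, value: np.ndarray) -> None:
        self.data[_INDEX[species]] = value

    def __iter__(self) -> Iterator[str]:
        return iter(SPECIES)

    def copy(self) -> "StateFields":
        return StateFields(self.data.copy())

    def to_dict(self) -> Dict[str, np.ndarray]:
        return {sp: self.data[_INDEX[sp]] for sp in SPECIES}

    # -- validation ------------------------------------------------------
    def validate(self, g: DomainGeometry) -> None:
        """Check finiteness, nonnegativity, and zero off-tissue values."""
        if self.data.shape[1:] != g.labels.shape:
            raise ParameterError("state shape does not match geometry")
        if not np.isfinite(self.data).all():
            sp, r, c = np.argwhere(~np.isfinite(self.data))[0]
            raise NumericalError(
                f"non-finite value in species {SPECIES[sp]} at cell ({r}, {c})"
            )
        if (self.data < 0).any():
            sp, r, c = np.argwhere(self.data < 0)[0]
            raise NumericalError(
                f"negative value in species {SPECIES[sp]} at cell ({r}, {c})"
            )
        off = ~g.tissue_mask
        if np.any(self.data[:, off] != 0.0):
            raise NumericalError("nonzero concentration outside the tissue domain")

    def spatial_means(self, g: DomainGeometry) -> Dict[str, float]:
        """Mean of each field over the tissue region."""
        tissue = g.tissue_mask
        n = max(int(tissue.sum()), 1)
        return {sp: float(self.data[_INDEX[sp]][tissue].sum() / n) for sp in SPECIES}
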