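"""Dose grids and the log-centred dose codification.

Dose-finding models in this package never see raw milligram amounts.
Each raw dose ``y_i`` is mapped to a *codified* dose

    x_i = log(y_i) - mean_j log(y_j),

i.e. log-dose centred at the mean log-dose, so the covariate scale is
dimensionless, centred at zero, and invariant to rescaling all doses by
a common factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = ["DoseGrid", "codify_doses"]


@dataclass(frozen=True)
class DoseGrid:
    """An ordered grid of trial doses with their codified values.

    Parameters
    ----------
    raw_doses : tuple of float
        Strictly increasing positive dose amounts (mg/day equivalents).
    codified : tuple of float
        Log-centred dose values; sum to zero by construction.
    """

    raw_doses: tuple[float, ...]
    codified: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.raw_doses) != len(self.codified):
            raise ValueError("raw_doses and codified must have equal length")
        if len(self.raw_doses) < 2:
            raise ValueError("a dose grid needs at least 2 doses")
        if any(d <= 0 for d in self.raw_doses):
            raise ValueError("all raw doses must be positive")
        if any(b <= a for a, b in zip(self.raw_doses, self.raw_doses[1:])):
            raise ValueError("raw doses must be strictly increasing")
        if abs(sum(self.codified)) > 1e-9 * max(1.0, max(abs(c) for c in self.codified)):
            raise ValueError("codified doses must sum to zero")

    @property
    def n_doses(self) -> int:
        return len(self.raw_doses)

    def codified_dose(self, dose_level: int) -> float:
        """Codified value for a 1-based dose level."""
        if not 1 <= dose_level <= self.n_doses:
            raise ValueError(f"dose_level {dose_level} outside grid 1..{self.n_doses}")
        return self.codified[dose_level - 1]


def codify_doses(raw_doses: Sequence[float]) -> DoseGrid:
    """Build a :class:`DoseGrid` from raw dose amounts.

    Examples
    --------
    >>> grid = codify_doses([10, 20, 30, 50])
    >>> [round(x, 2) for x in grid.codified]
    [-0.85, -0.16, 0.25, 0.76]
    """
    raw = tuple(float(y) for y in raw_doses)
    if any(y <= 0 for y in raw):
        raise ValueError("doses must be positive")
    logs = [math.log(y) for y in raw]
    mean_log = sum(logs) / len(logs)
    codified = [lg - mean_log for lg in logs]
    # re-centre exactly so the zero-sum invariant holds to float precision
    resid = sum(codified) / len(codified)
    codified = tuple(c - resid for c in codified)
    return DoseGrid(raw_doses=raw, codified=codified)
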