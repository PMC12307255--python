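"""Concentration grids for 96-well activity plates.

A plate samples enzyme activity on a 12x8 grid of substrate ([Phe]) and
cofactor ([BH4]) concentrations.  The canonical in-memory orientation puts
[Phe] on axis 0 (length 12) and [BH4] on axis 1 (length 8); plate files use
the physical layout (rows A-H = BH4, columns 1-12 = Phe) and are transposed
at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default concentration levels (uM).  The assay spans 0-2500 uM [Phe] across
#: plate columns and 0-250 uM [BH4] across rows, with denser sampling near
#: physiological concentrations; the exact levels are configurable.
DEFAULT_PHE_LEVELS = (0.0, 25.0, 50.0, 100.0, 150.0, 250.0, 400.0, 600.0, 900.0, 1300.0, 1800.0, 2500.0)
DEFAULT_BH4_LEVELS = (0.0, 5.0, 10.0, 25.0, 50.0, 75.0, 125.0, 250.0)


@dataclass(frozen=True)
class ConcentrationGrid:
    """The [Phe] x [BH4] sample points of a plate, in uM, ascending."""

    phe_levels: tuple[float, ...] = DEFAULT_PHE_LEVELS
    bh4_levels: tuple[float, ...] = DEFAULT_BH4_LEVELS

    def __post_init__(self) -> None:
        phe = np.asarray(self.phe_levels, dtype=float)
        bh4 = np.asarray(self.bh4_levels, dtype=float)
        object.__setattr__(self, "phe_levels", tuple(phe))
        object.__setattr__(self, "bh4_levels", tuple(bh4))
        for name, levels in (("phe_levels", phe), ("bh4_levels", bh4)):
            if np.any(levels < 0):
                raise ValueError(f"{name} must be nonnegative")
            if np.any(np.diff(levels) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.phe_levels), len(self.bh4_levels))

    @property
    def phe(self) -> np.ndarray:
        return np.asarray(self.phe_levels)

    @property
    def bh4(self) -> np.ndarray:
        return np.asarray(self.bh4_levels)

    def nonzero_mask(self) -> np.ndarray:
        """Boolean mask of wells with both concentrations > 0 (log-definable)."""
        return (self.phe[:, None] > 0) & (self.bh4[None, :] > 0)


def default_grid() -> ConcentrationGrid:
    return ConcentrationGrid()
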