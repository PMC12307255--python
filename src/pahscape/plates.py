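"""Plate I/O and per-run processing of activity replicates.

Each genotype is assayed in biological triplicate on 96-well plates, together
with a wild-type (positive) and a no-DNA (negative) control in every run.
Processing follows the assay's evaluation order: background subtraction with
the no-DNA plate, normalization to the run's wild type, and the element-wise
median across replicates.

Plate-table file format (CSV or XLSX, one sheet): an optional concentrations
header of two lines (``phe_uM,<12 values>`` / ``bh4_uM,<8 values>``) followed
by one block per (genotype, replicate).  A block is a metadata line
``genotype_id,run_id,replicate_index`` followed by its values, then a header
line ``well,1,...,12`` and eight rows ``A``-``H``.  Plate rows A-H carry the
[BH4] series (ascending) and columns 1-12 the [Phe] series (ascending); the
reader transposes to the canonical orientation (axis 0 = [Phe], axis 1 =
[BH4]).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .grids import ConcentrationGrid

PLATE_ROWS = "ABCDEFGH"


class PlateFormatError(ValueError):
    """Raised when a plate table block cannot be parsed."""


@dataclass(frozen=True)
class PlateReplicate:
    """One replicate 12x8 activity matrix (pmol Tyr/mg/min) on a grid."""

    genotype_id: str
    run_id: str
    replicate_index: int
    values: np.ndarray
    grid: ConcentrationGrid

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"plate for {self.genotype_id!r} has shape {values.shape}, grid expects {self.grid.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"plate for {self.genotype_id!r} contains non-finite values")


@dataclass(frozen=True)
class ActivityLandscape:
    """A genotype's aggregated 12x8 activity matrix, raw or %WT units."""

    genotype_id: str
    values: np.ndarray
    units: str  # "raw" or "percent_wt"
    grid: ConcentrationGrid
    n_replicates: int = 1

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != self.grid.shape:
            raise ValueError("landscape shape does not match grid")
        if self.units not in ("raw", "percent_wt"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.units == "percent_wt" and np.any(values < 0):
            raise ValueError("percent_wt landscapes must be nonnegative")


# ---------------------------------------------------------------------------
# Plate-table reading and writing


def _parse_cells(rows: list[list[str]], path: str, grid: ConcentrationGrid | None) -> list[PlateReplicate]:
    n_phe, n_bh4 = 12, 8
    phe = bh4 = None
    i = 0
    # optional concentrations header
    while i < len(rows) and rows[i] and str(rows[i][0]).strip().lower() in ("phe_um", "bh4_um"):
        key = str(rows[i][0]).strip().lower()
        vals = tuple(float(v) for v in rows[i][1:] if str(v).strip() != "")
        if key == "phe_um":
            phe = vals
        else:
            bh4 = vals
        i += 1
    if phe is not None and bh4 is not None:
        grid = ConcentrationGrid(phe_levels=phe, bh4_levels=bh4)
    elif grid is None:
        grid = ConcentrationGrid()

    replicates: list[PlateReplicate] = []
    while i < len(rows):
        if not rows[i] or all(str(c).strip() == "" for c in rows[i]):
            i += 1
            continue
        header = [str(c).strip() for c in rows[i]]
        if header[0] != "genotype_id":
            raise PlateFormatError(f"{path}: expected a 'genotype_id' block header at row {i + 1}, got {header[0]!r}")
        if i + 1 >= len(rows):
            raise PlateFormatError(f"{path}: truncated block at row {i + 1}")
        meta = rows[i + 1]
        genotype_id, run_id = str(meta[0]).strip(), str(meta[1]).strip()
        replicate_index = int(meta[2])
        block_name = f"{genotype_id}/{run_id}/rep{replicate_index}"
        j = i + 2
        if j >= len(rows) or str(rows[j][0]).strip().lower() != "well":
            raise PlateFormatError(f"{path}: block {block_name} missing 'well' column header")
        if len([c for c in rows[j][1:] if str(c).strip() != ""]) != n_phe:
            raise PlateFormatError(f"{path}: block {block_name} has {len(rows[j]) - 1} columns, expected {n_phe}")
        plate = np.empty((n_bh4, n_phe))
        for r, letter in enumerate(PLATE_ROWS):
            line = rows[j + 1 + r] if j + 1 + r < len(rows) else []
            if not line or str(line[0]).strip().upper() != letter:
                raise PlateFormatError(f"{path}: block {block_name} missing plate row {letter}")
            cells = [c for c in line[1 : 1 + n_phe]]
            if len(cells) != n_phe or any(str(c).strip() == "" for c in cells):
                raise PlateFormatError(f"{path}: block {block_name} row {letter} has wrong width")
            plate[r] = [float(c) for c in cells]
        # plate[bh4, phe] -> canonical values[phe, bh4]
        replicates.append(
            PlateReplicate(
                genotype_id=genotype_id,
                run_id=run_id,
                replicate_index=replicate_index,
                values=plate.T.copy(),
                grid=grid,
            )
        )
        i = j + 1 + n_bh4
    return replicates


def read_plate_table(path: str | Path, grid: ConcentrationGrid | None = None) -> list[PlateReplicate]:
    """Read a CSV or XLSX plate table into canonical-orientation replicates.

    The grid is taken from the file's concentrations header when present,
    otherwise from the ``grid`` argument, otherwise the package default.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        from openpyxl import load_workbook

        ws = load_workbook(path, read_only=True, data_only=True).active
        rows = [["" if c is None else c for c in row] for row in ws.iter_rows(values_only=True)]
    else:
        with open(path, newline="") as fh:
            rows = [row for row in csv.reader(fh)]
    return _parse_cells(rows, str(path), grid)


def write_plate_table(path: str | Path, replicates: Sequence[PlateReplicate]) -> None:
    """Write replicates in the plate-table CSV layout (round-trips with the reader)."""
    if not replicates:
        raise ValueError("no replicates to write")
    grid = replicates[0].grid
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["phe_uM", *[f"{v:g}" for v in grid.phe_levels]])
        w.writerow(["bh4_uM", *[f"{v:g}" for v in grid.bh4_levels]])
        for rep in replicates:
            w.writerow([])
            w.writerow(["genotype_id", "run_id", "replicate_index"])
            w.writerow([rep.genotype_id, rep.run_id, rep.replicate_index])
            w.writerow(["well", *range(1, 13)])
            plate = rep.values.T  # canonical -> plate orientation
            for r, letter in enumerate(PLATE_ROWS):
                w.writerow([letter, *[repr(float(v)) for v in plate[r]]])


# ---------------------------------------------------------------------------
# Per-run processing


def _check_compatible(a: PlateReplicate, b: PlateReplicate) -> None:
    if a.grid != b.grid:
        raise ValueError(f"grid mismatch between {a.genotype_id!r} and {b.genotype_id!r}")
    if a.run_id != b.run_id:
        raise ValueError(f"run mismatch: {a.run_id!r} vs {b.run_id!r}")


def background_subtract(sample: PlateReplicate, no_dna: PlateReplicate) -> PlateReplicate:
    """Subtract the no-DNA control element-wise; clip negatives to zero.

    Activity is physically nonnegative, and the downstream log-space fit
    assumes nonnegative z.
    """
    _check_compatible(sample, no_dna)
    values = np.clip(sample.values - no_dna.values, 0.0, None)
    return replace(sample, values=values)


def normalize_to_wt(
    sample: PlateReplicate, wt: PlateReplicate, no_dna: PlateReplicate
) -> PlateReplicate:
    """Express a background-subtracted plate as percent of the run's WT maximum.

    Returns 100 * (sample - no_dna)_clipped / M with M the maximum well of the
    background-subtracted WT plate of the same run.
    """
    _check_compatible(sample, wt)
    _check_compatible(sample, no_dna)
    sub = background_subtract(sample, no_dna)
    wt_sub = background_subtract(wt, no_dna)
    m = float(wt_sub.values.max())
    if m <= 0:
        raise ValueError(f"wild-type control shows no activity in run {sample.run_id!r}")
    return replace(sub, values=100.0 * sub.values / m)


def median_landscape(replicates: Sequence[PlateReplicate], units: str = "percent_wt") -> ActivityLandscape:
    """Element-wise median across replicates of one genotype."""
    if not replicates:
        raise ValueError("at least one replicate required")
    ids = {r.genotype_id for r in replicates}
    if len(ids) != 1:
        raise ValueError(f"mixed genotypes in median_landscape: {sorted(ids)}")
    grids = {r.grid for r in replicates}
    if len(grids) != 1:
        raise ValueError("mixed grids in median_landscape")
    stack = np.stack([r.values for r in replicates])
    return ActivityLandscape(
        genotype_id=replicates[0].genotype_id,
        values=np.median(stack, axis=0),
        units=units,
        grid=replicates[0].grid,
        n_replicates=len(replicates),
    )


def landscape_to_long(landscape: ActivityLandscape):
    """Tidy long-format table (genotype_id, phe_uM, bh4_uM, activity)."""
    import pandas as pd

    phe, bh4 = np.meshgrid(landscape.grid.phe, landscape.grid.bh4, indexing="ij")
    col = "activity_percent_wt" if landscape.units == "percent_wt" else "activity_raw"
    return pd.DataFrame(
        {
            "genotype_id": landscape.genotype_id,
            "phe_uM": phe.ravel(),
            "bh4_uM": bh4.ravel(),
            col: landscape.values.ravel(),
        }
    )
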