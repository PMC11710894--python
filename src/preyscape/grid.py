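"""Lattice containers shared by the simulator, preprocessing and mapping code.

The analysis grid is a planar lattice of square cells (default side 800 m,
area 0.64 km^2). Indexing is 0-based with half-open cell extents
[x, x + side); the cell center sits at x + side/2. Coordinates are assumed
to come from a projected (planar) system, in meters.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: Vegetation classes carried on every grid/covariate table, as percent cover.
VEG_CLASSES = ("tundra", "tussock", "tall_shrub", "low_shrub", "sparse")

#: Grid columns that are coordinates/bookkeeping rather than covariates.
_INDEX_COLS = ("row", "col", "x", "y")


@dataclasses.dataclass
class CovariateGrid:
    """A lattice of cells with habitat covariates and an optional validity mask.

    Parameters
    ----------
    table:
        One row per cell with columns ``row``, ``col``, ``x``, ``y`` (cell
        center coordinates in meters), the vegetation percent covers of
        :data:`VEG_CLASSES`, and ``elevation`` (m). Prediction grids add
        ``valid`` (bool) and ``mask_reason`` (";"-joined reason codes).
    cell_side_m:
        Cell side length in meters.
    """

    table: pd.DataFrame
    cell_side_m: float = 800.0

    def __post_init__(self) -> None:
        if self.cell_side_m <= 0:
            raise ValueError("cell_side_m must be positive")
        missing = [c for c in ("row", "col") if c not in self.table.columns]
        if missing:
            raise ValueError(f"grid table missing columns: {missing}")
        if "x" not in self.table.columns:
            half = self.cell_side_m / 2.0
            self.table = self.table.assign(
                x=self.table["col"] * self.cell_side_m + half,
                y=self.table["row"] * self.cell_side_m + half,
            )

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_side_m / 1000.0) ** 2

    @property
    def n_cells(self) -> int:
        return len(self.table)

    @property
    def shape(self) -> tuple[int, int]:
        return (int(self.table["row"].max()) + 1, int(self.table["col"].max()) + 1)

    def covariate_columns(self) -> list[str]:
        skip = set(_INDEX_COLS) | {"valid", "mask_reason", "cell_id"}
        return [c for c in self.table.columns if c not in skip]

    def valid_table(self) -> pd.DataFrame:
        if "valid" in self.table.columns:
            return self.table[self.table["valid"]]
        return self.table

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "cell_id", np.arange(len(out)))
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, cell_side_m: float = 800.0) -> "CovariateGrid":
        table = pd.read_csv(path)
        table = table.drop(columns=[c for c in ("cell_id",) if c in table.columns])
        return cls(table=table.reset_index(drop=True), cell_side_m=cell_side_m)


@dataclasses.dataclass
class Territory:
    """A predator territory: a center plus the masked cell set used for prey
    aggregation.

    ``member_index`` holds positional indices into the source grid/surface
    table for the *valid* member cells; ``corrected_area_km2`` is the summed
    area of those cells (never more than the disk area pi r^2).
    """

    territory_id: str
    center_x: float
    center_y: float
    radius_m: float
    member_index: np.ndarray
    corrected_area_km2: float
    n_cells_unmasked: int = 0

    @property
    def n_cells(self) -> int:
        return int(len(self.member_index))
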