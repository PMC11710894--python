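"""Project fitted abundance models onto a covariate lattice, mask invalid
cells, derive study-area totals with uncertainty, and aggregate prey
density inside predator territories.

Masking rules: cells with mean elevation above 500 m, or with any
abundance covariate outside the range observed in the training data, are
excluded from prediction. Territory areas are corrected for the excluded
cells before densities are computed.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import CovariateGrid, Territory
from .preprocess import Scaler
from .removal import FittedRemovalModel

__all__ = [
    "DensitySurface",
    "build_prediction_grid",
    "map_density",
    "density_unit_convert",
    "total_abundance",
    "territory_from_center",
    "territory_density",
    "territory_density_table",
    "study_area_union",
]

MAX_ELEVATION_M = 500.0


def build_prediction_grid(raw_grid: CovariateGrid, scaler: Scaler,
                          fitted_ranges: dict, covariates: list[str],
                          max_elevation: float = MAX_ELEVATION_M) -> CovariateGrid:
    """Standardize raw covariate layers with *training* statistics and set
    the validity mask.

    A cell is masked when its mean elevation exceeds ``max_elevation``
    (reason ``elevation``) or when any model covariate lies outside the
    training range (reason ``range:<name>``); multiple reasons are
    recorded ";"-joined.
    """
    t = raw_grid.table
    missing = [c for c in covariates if c not in t.columns]
    if missing:
        raise ValueError(f"grid is missing covariate layers: {missing}")
    reasons = [[] for _ in range(len(t))]
    if "elevation" in t.columns:
        over = np.asarray(t["elevation"], float) > max_elevation
        for i in np.flatnonzero(over):
            reasons[i].append("elevation")
    for c in covariates:
        if c not in fitted_ranges:
            continue
        lo, hi = fitted_ranges[c]
        vals = np.asarray(t[c], float)
        out = (vals < lo) | (vals > hi)
        for i in np.flatnonzero(out):
            reasons[i].append(f"range:{c}")

    std = scaler.transform(t)
    std["valid"] = [len(r) == 0 for r in reasons]
    std["mask_reason"] = [";".join(r) for r in reasons]
    return CovariateGrid(table=std, cell_side_m=raw_grid.cell_side_m)


@dataclasses.dataclass
class DensitySurface:
    """Per-cell expected counts (animals per cell) with 95% bounds.

    ``table`` has one row per *valid* cell: row, col, x, y, mean, lower,
    upper. The design matrix and coefficient distribution of the source
    model are retained so totals can be re-simulated coherently.
    """

    table: pd.DataFrame
    species: str
    cell_area_km2: float
    model: FittedRemovalModel | None = None
    _X: np.ndarray | None = None
    _log_offset: float = 0.0

    @property
    def n_cells(self) -> int:
        return len(self.table)

    def densities_per_km2(self) -> np.ndarray:
        return self.table["mean"].to_numpy() / self.cell_area_km2

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def map_density(fit: FittedRemovalModel, grid: CovariateGrid,
                species: str = "", method: str = "mvn",
                n_draws: int = 10000, seed: int = 0,
                level: float = 0.95) -> DensitySurface:
    """Predict expected counts per cell from a fitted abundance model.

    The grid must already be standardized with the training scaler
    (see :func:`build_prediction_grid`). Per-cell expectation is
    exp(beta' x + log A_cell); the interval comes from multivariate-normal
    coefficient draws (default) or the delta method. Masked cells yield no
    value.
    """
    valid = grid.valid_table()
    if len(valid) == 0:
        raise ValueError("no valid cells to predict on")
    cols = fit.names_abundance[1:]
    X = np.column_stack([np.ones(len(valid))] +
                        [np.asarray(valid[c], float) for c in cols])
    log_a = math.log(grid.cell_area_km2)
    eta = X @ fit.beta + log_a
    mean = np.exp(eta)

    bcov = fit.beta_cov()
    if bcov is None:
        lo = hi = mean
    elif method == "mvn":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(fit.beta, bcov, size=n_draws,
                                        method="svd")
        surfaces = np.exp(draws @ X.T + log_a)
        lo = np.quantile(surfaces, 0.5 - level / 2.0, axis=0)
        hi = np.quantile(surfaces, 0.5 + level / 2.0, axis=0)
    elif method == "delta":
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, bcov, X), 0.0))
        lo, hi = np.exp(eta - z * se), np.exp(eta + z * se)
    else:
        raise ValueError("method must be 'mvn' or 'delta'")

    table = pd.DataFrame({
        "row": valid["row"].to_numpy(), "col": valid["col"].to_numpy(),
        "x": valid["x"].to_numpy(), "y": valid["y"].to_numpy(),
        "mean": mean, "lower": lo, "upper": hi,
    })
    return DensitySurface(table=table, species=species,
                          cell_area_km2=grid.cell_area_km2, model=fit,
                          _X=X, _log_offset=log_a)


def density_unit_convert(value_per_cell, cell_area_km2: float = 0.64):
    """Convert animals per cell to animals per km^2 (full precision;
    rounding belongs to the presentation layer)."""
    if cell_area_km2 <= 0:
        raise ValueError("cell area must be positive")
    return np.asarray(value_per_cell, float) / cell_area_km2 \
        if np.ndim(value_per_cell) else float(value_per_cell) / cell_area_km2


def total_abundance(surface: DensitySurface, n_draws: int = 20000,
                    seed: int = 0, level: float = 0.95) -> dict:
    """Study-area abundance: sum of valid-cell expected counts, with a CI
    from summing per-draw surfaces over coefficient draws."""
    if surface.n_cells == 0:
        raise ValueError("empty density surface")
    est = float(surface.table["mean"].sum())
    fit = surface.model
    if fit is None or fit.beta_cov() is None or surface._X is None:
        return {"estimate": est, "lower": est, "upper": est, "n_draws": 0}
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.beta, fit.beta_cov(), size=n_draws,
                                    method="svd")
    totals = np.exp(draws @ surface._X.T + surface._log_offset).sum(axis=1)
    return {
        "estimate": est,
        "lower": float(np.quantile(totals, 0.5 - level / 2.0)),
        "upper": float(np.quantile(totals, 0.5 + level / 2.0)),
        "n_draws": n_draws,
    }


# ---------------------------------------------------------------------------
# territories


def territory_from_center(grid: CovariateGrid, territory_id: str,
                          center: tuple[float, float],
                          radius_m: float) -> Territory:
    """Collect the valid grid cells whose centers fall within ``radius_m``
    of the territory center; corrected area sums only those cells."""
    if radius_m <= 0:
        raise ValueError("territory radius must be positive")
    t = grid.table
    d2 = (t["x"].to_numpy() - center[0]) ** 2 + (t["y"].to_numpy() - center[1]) ** 2
    inside = d2 <= radius_m ** 2
    valid = t["valid"].to_numpy() if "valid" in t.columns else np.ones(len(t), bool)
    member = np.flatnonzero(inside & valid)
    return Territory(
        territory_id=territory_id, center_x=center[0], center_y=center[1],
        radius_m=radius_m, member_index=member,
        corrected_area_km2=len(member) * grid.cell_area_km2,
        n_cells_unmasked=int(inside.sum()))


class EmptyTerritoryError(ValueError):
    """All of a territory's cells are masked; its density is undefined."""


def territory_density(surface: DensitySurface, territory: Territory,
                      grid: CovariateGrid) -> dict:
    """Prey density inside one territory: summed expected counts of its
    valid member cells divided by the corrected area (animals per km^2)."""
    if territory.n_cells == 0:
        raise EmptyTerritoryError(
            f"territory {territory.territory_id} has no valid cells")
    gt = grid.table.iloc[territory.member_index]
    key = pd.MultiIndex.from_arrays([gt["row"], gt["col"]])
    surf = surface.table.set_index(["row", "col"])
    counts = surf.loc[key, "mean"].to_numpy()
    total = float(np.sum(counts))
    return {
        "territory_id": territory.territory_id,
        "density_per_km2": total / territory.corrected_area_km2,
        "corrected_area_km2": territory.corrected_area_km2,
        "n_cells": territory.n_cells,
    }


def territory_density_table(surfaces: dict, territories: list[Territory],
                            grid: CovariateGrid) -> pd.DataFrame:
    """Per-territory densities for several species' surfaces; territories
    with zero valid cells get NaN densities and an ``excluded`` flag."""
    rows = []
    for terr in territories:
        rec = {"territory_id": terr.territory_id,
               "corrected_area_km2": terr.corrected_area_km2,
               "n_cells": terr.n_cells, "excluded": terr.n_cells == 0}
        for species, surface in surfaces.items():
            if terr.n_cells == 0:
                rec[species] = np.nan
            else:
                rec[species] = territory_density(surface, terr, grid)[
                    "density_per_km2"]
        rows.append(rec)
    return pd.DataFrame(rows)


def study_area_union(territory_centers, territory_radius_m: float = 15000.0,
                     point_centers=None, point_radius_m: float = 4500.0,
                     cell_side_m: float = 800.0):
    """Cell-quantized union of disks around territory and point-count
    centers (the expanded study area).

    Returns ``(mask_table, area_km2)`` where ``mask_table`` lists the lattice
    cells (row, col, x, y) whose centers fall inside the union.
    """
    territory_centers = np.atleast_2d(np.asarray(territory_centers, float)) \
        if territory_centers is not None and len(territory_centers) else np.empty((0, 2))
    point_centers = np.atleast_2d(np.asarray(point_centers, float)) \
        if point_centers is not None and len(point_centers) else np.empty((0, 2))
    if len(territory_centers) == 0 and len(point_centers) == 0:
        raise ValueError("no centers supplied")

    pads = ([territory_radius_m] * len(territory_centers)
            + [point_radius_m] * len(point_centers))
    allc = np.vstack([c for c in (territory_centers, point_centers) if len(c)])
    x_lo = np.min(allc[:, 0] - pads) - cell_side_m
    x_hi = np.max(allc[:, 0] + pads) + cell_side_m
    y_lo = np.min(allc[:, 1] - pads) - cell_side_m
    y_hi = np.max(allc[:, 1] + pads) + cell_side_m
    col0, col1 = int(np.floor(x_lo / cell_side_m)), int(np.ceil(x_hi / cell_side_m))
    row0, row1 = int(np.floor(y_lo / cell_side_m)), int(np.ceil(y_hi / cell_side_m))
    cols = np.arange(col0, col1 + 1)
    rows = np.arange(row0, row1 + 1)
    cx = cols * cell_side_m + cell_side_m / 2.0
    cy = rows * cell_side_m + cell_side_m / 2.0
    gx, gy = np.meshgrid(cx, cy)
    inside = np.zeros(gx.shape, dtype=bool)
    for centers, radius in ((territory_centers, territory_radius_m),
                            (point_centers, point_radius_m)):
        for c in centers:
            inside |= (gx - c[0]) ** 2 + (gy - c[1]) ** 2 <= radius ** 2
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    keep = inside
    mask = pd.DataFrame({"row": rr[keep], "col": cc[keep],
                         "x": gx[keep], "y": gy[keep]})
    area_km2 = len(mask) * (cell_side_m / 1000.0) ** 2
    return mask, area_km2
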