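"""Covariate preparation: 2-SD standardization, collinearity screening,
elevation filtering and window aggregation.

Continuous predictors are standardized by subtracting the mean and dividing
by *two* sample standard deviations (Gelman's convention), which puts them
on a scale comparable with binary predictors and helps optimizer
conditioning. A fitted :class:`Scaler` is stored with every model so that
prediction-time data are always standardized with the *training* statistics,
never refit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import CovariateGrid

__all__ = [
    "Scaler",
    "DegenerateCovariateError",
    "standardize",
    "screen_collinearity",
    "filter_sites_by_elevation",
    "window_percent_cover",
]


class DegenerateCovariateError(ValueError):
    """Raised when a covariate has zero variance and cannot be standardized."""


@dataclasses.dataclass
class Scaler:
    """Per-covariate location/scale for 2-SD standardization.

    ``transform`` maps x -> (x - mean) / (divisor * sd); ``inverse`` undoes
    it. Non-numeric (factor) columns are passed through untouched.
    """

    means: dict[str, float]
    sds: dict[str, float]
    divisor: float = 2.0

    @classmethod
    def fit(cls, data: pd.DataFrame, columns: list[str] | None = None,
            divisor: float = 2.0) -> "Scaler":
        if columns is None:
            columns = [c for c in data.columns
                       if pd.api.types.is_numeric_dtype(data[c])]
        means, sds = {}, {}
        for col in columns:
            values = np.asarray(data[col], dtype=float)
            if len(values) < 2:
                raise ValueError(f"need >= 2 values to fit a scaler for {col!r}")
            sd = float(np.std(values, ddof=1))
            if sd == 0.0:
                raise DegenerateCovariateError(
                    f"covariate {col!r} is constant; cannot standardize")
            means[col] = float(np.mean(values))
            sds[col] = sd
        return cls(means=means, sds=sds, divisor=divisor)

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        out = data.copy()
        for col, mu in self.means.items():
            if col in out.columns:
                out[col] = (np.asarray(out[col], dtype=float) - mu) / (
                    self.divisor * self.sds[col])
        return out

    def inverse(self, data: pd.DataFrame) -> pd.DataFrame:
        out = data.copy()
        for col, mu in self.means.items():
            if col in out.columns:
                out[col] = np.asarray(out[col], dtype=float) * (
                    self.divisor * self.sds[col]) + mu
        return out

    def transform_array(self, values: np.ndarray, column: str) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.means[column]) / (
            self.divisor * self.sds[column])

    def inverse_array(self, values: np.ndarray, column: str) -> np.ndarray:
        return np.asarray(values, dtype=float) * (
            self.divisor * self.sds[column]) + self.means[column]

    def to_dict(self) -> dict:
        return {"means": dict(self.means), "sds": dict(self.sds),
                "divisor": self.divisor}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(means=dict(d["means"]), sds=dict(d["sds"]),
                   divisor=float(d.get("divisor", 2.0)))


def standardize(values, scaler: Scaler | None = None,
                columns: list[str] | None = None):
    """Standardize ``values`` by two standard deviations.

    Accepts a DataFrame (column-wise) or a 1-D array/Series. When ``scaler``
    is omitted a new one is fitted on the inputs; otherwise the supplied
    (training) statistics are used and never refit.

    Returns ``(standardized, scaler)``.
    """
    if isinstance(values, pd.DataFrame):
        if scaler is None:
            scaler = Scaler.fit(values, columns=columns)
        return scaler.transform(values), scaler
    arr = np.asarray(values, dtype=float)
    frame = pd.DataFrame({"_x": arr})
    if scaler is None:
        scaler = Scaler.fit(frame, columns=["_x"])
    out = scaler.transform(frame)["_x"].to_numpy()
    return out, scaler


def screen_collinearity(covariates: pd.DataFrame,
                        threshold: float = 0.70) -> list[dict]:
    """Flag covariate pairs with |Pearson r| >= ``threshold``.

    Returns a list of dicts with keys ``pair``, ``r`` and ``reason``; an
    empty list means the covariate set passes the screen. Constant columns
    make the correlation undefined and are flagged with a reason instead of
    an r value.
    """
    if len(covariates) < 3:
        raise ValueError("need >= 3 rows to screen collinearity")
    cols = [c for c in covariates.columns
            if pd.api.types.is_numeric_dtype(covariates[c])]
    flagged: list[dict] = []
    constant = {c for c in cols
                if float(np.std(np.asarray(covariates[c], float), ddof=1)) == 0.0}
    for a_i in range(len(cols)):
        for b_i in range(a_i + 1, len(cols)):
            a, b = cols[a_i], cols[b_i]
            if a in constant or b in constant:
                flagged.append({"pair": (a, b), "r": np.nan,
                                "reason": "constant column: correlation undefined"})
                continue
            r = float(np.corrcoef(np.asarray(covariates[a], float),
                                  np.asarray(covariates[b], float))[0, 1])
            if abs(r) >= threshold:
                flagged.append({"pair": (a, b), "r": r, "reason": "high correlation"})
    return flagged


def filter_sites_by_elevation(sites: pd.DataFrame, max_elevation: float = 500.0,
                              column: str = "elevation"):
    """Drop sites whose mean elevation exceeds ``max_elevation`` (m a.s.l.).

    The boundary is inclusive: a site at exactly the threshold is retained
    (only sites *greater than* the threshold are removed). Returns
    ``(retained, report)`` where ``report`` counts removed/retained sites.
    """
    if column not in sites.columns:
        raise ValueError(f"sites table has no {column!r} column")
    elev = np.asarray(sites[column], dtype=float)
    if np.isnan(elev).any():
        bad = sites.index[np.isnan(elev)].tolist()
        raise ValueError(f"missing elevation for site(s) {bad}")
    keep = elev <= max_elevation
    retained = sites[keep].reset_index(drop=True)
    report = {
        "n_input": int(len(sites)),
        "n_retained": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "max_elevation": float(max_elevation),
    }
    return retained, report


def window_percent_cover(grid: CovariateGrid, center: tuple[float, float],
                         window_side_m: float = 800.0) -> dict[str, float]:
    """Mean covariates within a square window centered on a point.

    Cells belong to the window when their centers fall inside the half-open
    square ``[cx - s/2, cx + s/2) x [cy - s/2, cy + s/2)``. Because all
    cells have equal area, the mean of per-cell percent covers equals the
    percent cover of the window, and mean elevation is the windowed mean.
    """
    cx, cy = center
    half = window_side_m / 2.0
    t = grid.table
    inside = ((t["x"] >= cx - half) & (t["x"] < cx + half)
              & (t["y"] >= cy - half) & (t["y"] < cy + half))
    cells = t[inside]
    if len(cells) == 0:
        raise ValueError(f"window at {center} contains no cells")
    out = {}
    for col in grid.covariate_columns():
        out[col] = float(np.mean(np.asarray(cells[col], dtype=float)))
    out["n_cells"] = int(len(cells))
    return out


def save_scaler(scaler: Scaler, path: str | Path) -> None:
    import json
    Path(path).write_text(json.dumps(scaler.to_dict(), indent=1))


def load_scaler(path: str | Path) -> Scaler:
    import json
    return Scaler.from_dict(json.loads(Path(path).read_text()))
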