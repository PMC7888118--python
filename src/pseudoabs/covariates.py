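"""Gridded environmental covariates and extraction at point locations.

An :class:`EnvironmentStack` holds named covariate layers on one shared
lon/lat grid. Layers are static (one slice) or monthly (12 slices indexed by
calendar month 1-12, emulating monthly remote-sensing composites). Missing
cells are NaN. Extraction is containing-cell lookup (no interpolation):
points on missing cells or outside the grid yield NaN rather than raising,
and rows with any missing covariate are dropped when the model table is
assembled — the tabular analogue of prediction maps leaving blank pixels
where predictors are missing.

Grid registration: ``origin_lon``/``origin_lat`` is the north-west *corner*
of the grid; rows run southward, columns eastward; cell centers sit at
half-cell offsets; indexing is row-major, 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

N_MONTHS = 12


@dataclass(frozen=True)
class GridGeometry:
    """Regular lon/lat grid anchored at its north-west corner."""

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_cols < 2 or self.n_rows < 2:
            raise ValueError("n_cols and n_rows must be >= 2")

    @property
    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max) of the grid extent."""
        return (
            self.origin_lon,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat - self.n_rows * self.cell_size,
            self.origin_lat,
        )

    def index_of(self, lon, lat):
        """(row, col) of the containing cell; -1 where outside the grid."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - lat) / self.cell_size).astype(int)
        # points exactly on the south/east outer edge belong to the last cell
        col = np.where((lon == self.origin_lon + self.n_cols * self.cell_size), self.n_cols - 1, col)
        row = np.where((lat == self.origin_lat - self.n_rows * self.cell_size), self.n_rows - 1, row)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return np.where(inside, row, -1), np.where(inside, col, -1)


@dataclass
class EnvironmentStack:
    """Named covariate layers sharing one grid geometry.

    ``layers[name]`` is a 2-D array (n_rows, n_cols) for a static layer or a
    3-D array (12, n_rows, n_cols) for a monthly layer. Missing data is NaN.
    """

    grid: GridGeometry
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("environment needs at least one layer")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2:
                shape = (self.grid.n_rows, self.grid.n_cols)
            elif arr.ndim == 3:
                shape = (N_MONTHS, self.grid.n_rows, self.grid.n_cols)
            else:
                raise ValueError(f"layer {name!r}: array must be 2-D or 3-D")
            if arr.shape != shape:
                raise ValueError(f"layer {name!r}: shape {arr.shape} != expected {shape}")
            self.layers[name] = arr

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def is_monthly(self, name: str) -> bool:
        return self.layers[name].ndim == 3

    @property
    def has_monthly(self) -> bool:
        return any(self.is_monthly(n) for n in self.layers)

    def slice_of(self, name: str, month: int | None = None) -> np.ndarray:
        """The (n_rows, n_cols) slice for a layer; month 1-12 for monthly layers."""
        arr = self.layers[name]
        if arr.ndim == 2:
            return arr
        if month is None or not 1 <= int(month) <= N_MONTHS:
            raise ValueError(f"layer {name!r} is monthly: month must be in 1..12, got {month}")
        return arr[int(month) - 1]

    def standardization(self) -> pd.DataFrame:
        """Per-layer mean/SD over all non-missing cells (all slices pooled)."""
        rows = {}
        for name, arr in self.layers.items():
            vals = arr[np.isfinite(arr)]
            rows[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
        return pd.DataFrame(rows).T

    # ------------------------------------------------------------------
    def extract(self, points: pd.DataFrame) -> pd.DataFrame:
        """Covariate values at point locations (containing-cell lookup).

        ``points`` needs ``lon``/``lat`` columns, plus ``timestamp`` when any
        layer is monthly (the point's calendar month picks the slice).
        Returns one covariate column per layer, aligned with ``points``;
        out-of-grid points and missing cells yield NaN.
        """
        lon = points["lon"].to_numpy(dtype=float)
        lat = points["lat"].to_numpy(dtype=float)
        row, col = self.grid.index_of(lon, lat)
        inside = row >= 0
        months = None
        if self.has_monthly:
            if "timestamp" not in points.columns:
                raise ValueError("points need a timestamp column to sample monthly layers")
            months = pd.to_datetime(points["timestamp"]).dt.month.to_numpy()
        out = {}
        for name, arr in self.layers.items():
            vals = np.full(len(lon), np.nan)
            r = row[inside]
            c = col[inside]
            if arr.ndim == 2:
                vals[inside] = arr[r, c]
            else:
                m = months[inside] - 1
                vals[inside] = arr[m, r, c]
            out[name] = vals
        return pd.DataFrame(out, index=points.index)

    # ------------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        coords = {
            "lat": ("lat", self.grid.lat_centers),
            "lon": ("lon", self.grid.lon_centers),
            "month": ("month", np.arange(1, N_MONTHS + 1)),
        }
        data = {}
        for name, arr in self.layers.items():
            if arr.ndim == 2:
                data[name] = (("lat", "lon"), arr)
            else:
                data[name] = (("month", "lat", "lon"), arr)
        ds = xr.Dataset(data, coords=coords)
        ds.attrs.update(
            origin_lon=self.grid.origin_lon,
            origin_lat=self.grid.origin_lat,
            cell_size=self.grid.cell_size,
            n_cols=self.grid.n_cols,
            n_rows=self.grid.n_rows,
        )
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvironmentStack":
        ds = xr.load_dataset(path, engine="scipy")
        grid = GridGeometry(
            origin_lon=float(ds.attrs["origin_lon"]),
            origin_lat=float(ds.attrs["origin_lat"]),
            cell_size=float(ds.attrs["cell_size"]),
            n_cols=int(ds.attrs["n_cols"]),
            n_rows=int(ds.attrs["n_rows"]),
        )
        layers = {str(k): ds[k].to_numpy() for k in ds.data_vars}
        return cls(grid, layers)


# ---------------------------------------------------------------------------
# Model table assembly

BOOKKEEPING_COLUMNS = ["label", "animal_id", "timestamp", "lon", "lat", "method"]


def build_table(
    presences: pd.DataFrame,
    absences: pd.DataFrame,
    env: EnvironmentStack,
) -> pd.DataFrame:
    """Assemble the presence/pseudo-absence model table with covariates.

    ``presences`` (label 1) and ``absences`` (label 0) each need animal_id,
    timestamp, lon, lat; ``absences`` should also carry ``method``. Rows with
    any missing covariate are dropped (count logged per label), so the final
    label balance may deviate slightly from 1:1 where points fell on missing
    cells or outside the grid.
    """
    pres = presences.copy()
    pres["label"] = 1
    if "method" not in pres.columns:
        pres["method"] = absences["method"].iloc[0] if "method" in absences.columns and len(absences) else "presence"
    absn = absences.copy()
    absn["label"] = 0
    pts = pd.concat([pres, absn], ignore_index=True)
    cov = env.extract(pts)
    table = pd.concat([pts[[c for c in BOOKKEEPING_COLUMNS if c in pts.columns]], cov], axis=1)
    ok = cov.notna().all(axis=1)
    dropped = table.loc[~ok]
    if len(dropped):
        counts = dropped["label"].value_counts().to_dict()
        logger.info(
            "build_table: dropped %d rows with missing covariates (per label: %s)",
            len(dropped),
            counts,
        )
    table = table.loc[ok].reset_index(drop=True)
    if table.empty:
        raise ValueError("all rows fell on missing covariates; empty model table")
    return table
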