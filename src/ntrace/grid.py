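"""Model grid, gridded fields with uncertainty, and regridding.

Values are registered at cell centres; cells are half-open ``[edge, edge+res)``
in both axes and rows run south to north. Masked cells (ocean, ice, missing
data) are carried as an explicit boolean mask — masked entries never enter
arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

__all__ = ["ModelGrid", "GridField", "AnnualGridSeries", "build_grid", "regrid_linear"]


@dataclass(frozen=True)
class ModelGrid:
    """Regular latitude-longitude grid with cosine-latitude area weights."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float

    @property
    def n_rows(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def n_cols(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def lats(self) -> np.ndarray:
        """Cell-centre latitudes, ascending (south to north)."""
        return self.lat_min + self.resolution * (np.arange(self.n_rows) + 0.5)

    @property
    def lons(self) -> np.ndarray:
        return self.lon_min + self.resolution * (np.arange(self.n_cols) + 0.5)

    @property
    def cell_area(self) -> np.ndarray:
        """Relative per-cell area weights, proportional to cos(latitude)."""
        w = np.cos(np.deg2rad(self.lats))
        return np.broadcast_to(w[:, None], (self.n_rows, self.n_cols)).copy()

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_index(self, lat, lon):
        """Row/column of the half-open cell containing each point."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        i = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        j = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        inside = (i >= 0) & (i < self.n_rows) & (j >= 0) & (j < self.n_cols)
        return i, j, inside


def build_grid(resolution: float, lat_range=(-60.0, 85.0),
               lon_range=(-180.0, 180.0)) -> ModelGrid:
    """Build a regular lat-lon grid; ranges must divide the resolution exactly."""
    lat_min, lat_max = map(float, lat_range)
    lon_min, lon_max = map(float, lon_range)
    if not (lat_max > lat_min and lon_max > lon_min and resolution > 0):
        raise ValueError("ranges must be increasing and resolution positive")
    for name, span in (("latitude", lat_max - lat_min), ("longitude", lon_max - lon_min)):
        n = span / resolution
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"{name} range {span}° is not an integer multiple of the "
                f"resolution {resolution}°"
            )
    return ModelGrid(lat_min, lat_max, lon_min, lon_max, float(resolution))


@dataclass
class GridField:
    """Per-cell values with 1σ uncertainty, a unit tag and a validity mask."""

    grid: ModelGrid
    values: np.ndarray
    units: str
    sigma: np.ndarray | None = None
    mask: np.ndarray | None = None  # True where valid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid {self.grid.shape}")
        if self.sigma is None:
            self.sigma = np.zeros_like(self.values)
        else:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.values.shape:
                raise ValueError("sigma shape mismatch")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")
        if np.any(self.sigma[self.mask] < 0):
            raise ValueError("sigma must be >= 0 on valid cells")

    def to_dataset(self, name: str = "field") -> xr.Dataset:
        coords = {"lat": self.grid.lats, "lon": self.grid.lons}
        ds = xr.Dataset(
            {
                name: (("lat", "lon"), np.where(self.mask, self.values, np.nan)),
                f"{name}_sigma": (("lat", "lon"), np.where(self.mask, self.sigma, np.nan)),
            },
            coords=coords,
        )
        ds[name].attrs["units"] = self.units
        ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
        ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
        return ds

    def to_netcdf(self, path, name: str = "field") -> None:
        ds = self.to_dataset(name)
        try:
            ds.to_netcdf(path)
        except (ImportError, ValueError):  # binary backend unavailable
            ds.to_netcdf(path, engine="scipy")

    def to_csv(self, path) -> None:
        lats = np.repeat(self.grid.lats, self.grid.n_cols)
        lons = np.tile(self.grid.lons, self.grid.n_rows)
        df = pd.DataFrame(
            {
                "lat": lats,
                "lon": lons,
                "value": self.values.ravel(),
                "sigma": self.sigma.ravel(),
                "valid": self.mask.ravel().astype(int),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: ModelGrid, units: str = "") -> "GridField":
        df = pd.read_csv(path)
        values = np.full(grid.shape, np.nan)
        sigma = np.zeros(grid.shape)
        mask = np.zeros(grid.shape, dtype=bool)
        i, j, inside = grid.cell_index(df["lat"].to_numpy(), df["lon"].to_numpy())
        if not inside.all():
            raise ValueError("CSV contains points outside the grid")
        values[i, j] = df["value"].to_numpy()
        sigma[i, j] = df.get("sigma", pd.Series(np.zeros(len(df)))).to_numpy()
        valid = df.get("valid", pd.Series(np.ones(len(df)))).to_numpy().astype(bool)
        mask[i, j] = valid & np.isfinite(values[i, j])
        return cls(grid, values, units, sigma=sigma, mask=mask)


@dataclass
class AnnualGridSeries:
    """One GridField per year on a shared grid; contiguous, increasing years."""

    years: np.ndarray
    fields: list
    category: str = ""

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        if len(self.years) != len(self.fields):
            raise ValueError("years and fields length mismatch")
        d = np.diff(self.years)
        if len(d) and not np.all(d == 1):
            raise ValueError("years must be strictly increasing and contiguous")
        grids = {id(f.grid) for f in self.fields}
        if len(grids) > 1 and len({(f.grid.lat_min, f.grid.resolution, f.grid.n_rows,
                                     f.grid.lon_min, f.grid.n_cols)
                                    for f in self.fields}) > 1:
            raise ValueError("all fields must share one grid")

    @property
    def grid(self) -> ModelGrid:
        return self.fields[0].grid

    def field(self, year: int) -> GridField:
        idx = int(year) - int(self.years[0])
        if idx < 0 or idx >= len(self.fields):
            raise KeyError(f"year {year} not in series [{self.years[0]}, {self.years[-1]}]")
        return self.fields[idx]

    def stack(self) -> np.ndarray:
        """(n_years, n_rows, n_cols) array of values, NaN where masked."""
        return np.stack([np.where(f.mask, f.values, np.nan) for f in self.fields])


def regrid_linear(source: GridField, target_grid: ModelGrid) -> GridField:
    """Bilinearly interpolate a field onto the cell centres of another grid.

    Target centres outside the source centre hull are masked, as are targets
    whose bilinear stencil touches a masked source cell.
    """
    src = source.grid
    if src.n_rows == 0 or src.n_cols == 0:
        raise ValueError("empty source field")
    vals = np.where(source.mask, source.values, np.nan)
    interp = RegularGridInterpolator(
        (src.lats, src.lons), vals, method="linear",
        bounds_error=False, fill_value=np.nan,
    )
    si = RegularGridInterpolator(
        (src.lats, src.lons), np.where(source.mask, source.sigma, np.nan),
        method="linear", bounds_error=False, fill_value=np.nan,
    )
    tlat, tlon = np.meshgrid(target_grid.lats, target_grid.lons, indexing="ij")
    pts = np.column_stack([tlat.ravel(), tlon.ravel()])
    out = interp(pts).reshape(target_grid.shape)
    sig = si(pts).reshape(target_grid.shape)
    mask = np.isfinite(out)
    return GridField(target_grid, np.where(mask, out, np.nan), source.units,
                     sigma=np.where(mask, sig, 0.0), mask=mask)
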