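"""Regular lon/lat grids and named environmental covariate layers.

The covariate stack mirrors the layer set used for winter habitat
modelling around South Georgia: static bathymetry-derived layers
(``DEPTH`` as elevation in metres, sea < 0 and land >= 0; ``SLOPE`` in
degrees; ``SLOPE_SD``; ``ASPECT`` in compass degrees of the downslope
direction) and monthly dynamic layers for the May-September fishing
season (``SST`` in °C, ``CHL`` stored on the natural-log scale, and wind
stress ``CURL``).

Grids are row-major with row 0 at the southern edge and cells half-open
in both axes: a point belongs to the cell whose [edge, edge + d) interval
contains it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .projection import EARTH_RADIUS_KM

STATIC_LAYERS = ("DEPTH", "SLOPE", "SLOPE_SD", "ASPECT")
DYNAMIC_LAYERS = ("SST", "CHL", "CURL")
WINTER_MONTHS = (5, 6, 7, 8, 9)


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid: origin at the south-west cell corner."""

    lon0: float
    lat0: float
    cell_deg: float
    n_rows: int
    n_cols: int

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon0 + self.cell_deg * np.arange(self.n_cols + 1)

    @property
    def lat_edges(self) -> np.ndarray:
        return self.lat0 + self.cell_deg * np.arange(self.n_rows + 1)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon0 + self.cell_deg * (np.arange(self.n_cols) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat0 + self.cell_deg * (np.arange(self.n_rows) + 0.5)

    def cell_index(self, lon, lat):
        """Row/col of the containing cell; -1 where outside the grid."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon0) / self.cell_deg).astype(int)
        row = np.floor((lat - self.lat0) / self.cell_deg).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return np.where(inside, row, -1), np.where(inside, col, -1)

    def contains(self, lon, lat):
        row, _ = self.cell_index(lon, lat)
        return row >= 0

    def cell_areas_km2(self) -> np.ndarray:
        """Exact spherical cell areas, (n_rows, n_cols); varies with latitude."""
        dlam = np.radians(self.cell_deg)
        edges = np.radians(self.lat_edges)
        band = EARTH_RADIUS_KM**2 * dlam * (np.sin(edges[1:]) - np.sin(edges[:-1]))
        return np.repeat(band[:, None], self.n_cols, axis=1)


@dataclass
class CovariateStack:
    """Named static and monthly-dynamic covariate rasters on one grid."""

    grid: GridSpec
    static: dict[str, np.ndarray]
    dynamic: dict[str, dict[int, np.ndarray]]
    months: tuple[int, ...] = WINTER_MONTHS

    def __post_init__(self):
        shape = (self.grid.n_rows, self.grid.n_cols)
        for name, arr in self.static.items():
            if arr.shape != shape:
                raise ValueError(f"layer {name} shape {arr.shape} != grid {shape}")
        for name, by_month in self.dynamic.items():
            missing = set(self.months) - set(by_month)
            if missing:
                raise ValueError(f"dynamic layer {name} missing months {sorted(missing)}")
            for m, arr in by_month.items():
                if arr.shape != shape:
                    raise ValueError(f"layer {name}[{m}] shape {arr.shape} != grid {shape}")

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(self.static) + tuple(self.dynamic)

    @property
    def land_mask(self) -> np.ndarray:
        """Land cells: elevation-convention depth >= 0."""
        return self.static["DEPTH"] >= 0.0

    def layer(self, name: str, month: int | None = None) -> np.ndarray:
        if name in self.static:
            return self.static[name]
        if name in self.dynamic:
            if month is None:
                raise ValueError(f"dynamic layer {name} requires a month")
            return self.dynamic[name][month]
        raise KeyError(name)

    def monthly_mean(self, name: str) -> np.ndarray:
        """Across-month mean of a dynamic layer (used for pooled surfaces)."""
        if name in self.static:
            return self.static[name]
        return np.mean([self.dynamic[name][m] for m in self.months], axis=0)

    def sample(self, name: str, lon, lat, month=None) -> np.ndarray:
        """Containing-cell lookup; NaN outside the grid.

        ``month`` may be a scalar or a per-point array for dynamic layers.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        row, col = self.grid.cell_index(lon, lat)
        out = np.full(lon.shape, np.nan)
        inside = row >= 0
        if name in self.static:
            out[inside] = self.static[name][row[inside], col[inside]]
            return out
        month = np.broadcast_to(np.asarray(month), lon.shape)
        for m in np.unique(month[inside]):
            sel = inside & (month == m)
            out[sel] = self.dynamic[name][int(m)][row[sel], col[sel]]
        return out

    def is_land(self, lon, lat) -> np.ndarray:
        """Land test at point locations; points off the grid count as sea."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        row, col = self.grid.cell_index(lon, lat)
        land = self.land_mask
        out = np.zeros(lon.shape, dtype=bool)
        inside = row >= 0
        out[inside] = land[row[inside], col[inside]]
        return out

    # ---- serialization -------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        coords = {"lat": self.grid.lat_centers, "lon": self.grid.lon_centers,
                  "month": list(self.months)}
        data = {}
        for name, arr in self.static.items():
            data[name] = (("lat", "lon"), arr)
        for name, by_month in self.dynamic.items():
            cube = np.stack([by_month[m] for m in self.months])
            data[name] = (("month", "lat", "lon"), cube)
        ds = xr.Dataset(data, coords=coords)
        ds.attrs.update(lon0=self.grid.lon0, lat0=self.grid.lat0,
                        cell_deg=self.grid.cell_deg, crs="EPSG:4326")
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "CovariateStack":
        ds = xr.load_dataset(path, engine="scipy")
        grid = GridSpec(lon0=float(ds.attrs["lon0"]), lat0=float(ds.attrs["lat0"]),
                        cell_deg=float(ds.attrs["cell_deg"]),
                        n_rows=ds.sizes["lat"], n_cols=ds.sizes["lon"])
        months = tuple(int(m) for m in ds["month"].values)
        static, dynamic = {}, {}
        for name, da in ds.data_vars.items():
            if "month" in da.dims:
                dynamic[name] = {m: da.sel(month=m).values for m in months}
            else:
                static[name] = da.values
        return cls(grid=grid, static=static, dynamic=dynamic, months=months)


def covariate_frame(stack: CovariateStack, lon, lat, month, colonies) -> pd.DataFrame:
    """Assemble the model covariate columns for arbitrary points.

    Static and dynamic layers are sampled at the containing cell; CDIST is
    the great-circle distance (km) to the nearest of ``colonies``.
    """
    from .projection import haversine_km

    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    cols = {}
    for name in stack.static:
        cols[name] = stack.sample(name, lon, lat)
    for name in stack.dynamic:
        cols[name] = stack.sample(name, lon, lat, month=month)
    col_lon = np.array([c[0] for c in colonies], dtype=float)
    col_lat = np.array([c[1] for c in colonies], dtype=float)
    d = haversine_km(lon[:, None], lat[:, None], col_lon[None, :], col_lat[None, :])
    cols["CDIST"] = d.min(axis=1)
    return pd.DataFrame(cols)
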