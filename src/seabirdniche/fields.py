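"""Dated environmental raster layers and their file export.

Three co-registered daily ocean-surface variables drive the analysis:

``sst``
    Sea surface temperature (degC).
``eac_prob``
    Probability (0-1) that the surface water in a cell is of East Australian
    Current (EAC) origin; cells above 0.5 are classed as EAC water.
``sst_sd``
    Spatial SST variability (degC), a habitat-complexity covariate.

Fields are exported as NetCDF (classic format via the scipy backend) with
dimensions ``(time, lat, lon)``, or as single-day ESRI ASCII grids -- a
plain-text raster format most GIS tools read directly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec

VARIABLES = ("sst", "eac_prob", "sst_sd")


@dataclass
class EnvField:
    """One dated raster layer of one variable on a :class:`GridSpec`."""

    date: dt.date
    variable: str
    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray | None = field(default=None)  # True where cell is invalid

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}; expected one of {VARIABLES}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )
        if self.variable == "eac_prob":
            valid = self.values if self.mask is None else self.values[~self.mask]
            if valid.size and (np.nanmin(valid) < -1e-12 or np.nanmax(valid) > 1 + 1e-12):
                raise ValueError("eac_prob values must lie in [0, 1]")

    def valid_values(self) -> np.ndarray:
        if self.mask is None:
            return self.values.ravel()
        return self.values[~self.mask]

    def value_at(self, lon, lat) -> np.ndarray:
        """Cell value at each point; NaN outside the grid."""
        i, j = self.grid.cell_index(lon, lat)
        out = np.full(np.shape(i), np.nan, dtype=float)
        ok = i >= 0
        out[ok] = self.values[i[ok], j[ok]]
        return out


def fields_by_date(fields: list[EnvField]) -> dict[dt.date, dict[str, EnvField]]:
    """Index a flat field list as {date: {variable: field}}."""
    out: dict[dt.date, dict[str, EnvField]] = {}
    for f in fields:
        out.setdefault(f.date, {})[f.variable] = f
    return out


def fields_to_dataset(fields: list[EnvField]):
    """Stack fields into an xarray Dataset with dims (time, lat, lon)."""
    import xarray as xr

    by_date = fields_by_date(fields)
    dates = sorted(by_date)
    if not dates:
        raise ValueError("no fields to stack")
    grid = fields[0].grid
    data = {}
    for var in VARIABLES:
        layers = [by_date[d][var].values for d in dates if var in by_date[d]]
        if len(layers) == len(dates):
            data[var] = (("time", "lat", "lon"), np.stack(layers))
    coords = {
        "time": [np.datetime64(d) for d in dates],
        "lat": grid.lat_centers,
        "lon": grid.lon_centers,
    }
    return xr.Dataset(data, coords=coords)


def write_netcdf(fields: list[EnvField], path) -> None:
    """Write fields as a classic NetCDF file (scipy backend)."""
    ds = fields_to_dataset(fields)
    ds.to_netcdf(path, engine="scipy")


def read_netcdf(path, grid: GridSpec) -> list[EnvField]:
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    fields: list[EnvField] = []
    for t in ds["time"].values:
        date = t.astype("datetime64[D]").astype(dt.date)
        for var in VARIABLES:
            if var in ds:
                vals = np.asarray(ds[var].sel(time=t).values, dtype=float)
                fields.append(EnvField(date=date, variable=var, grid=grid, values=vals))
    ds.close()
    return fields


def write_ascii_grid(field: EnvField, path, nodata: float = -9999.0) -> None:
    """Export a single layer as an ESRI ASCII grid (text raster)."""
    grid = field.grid
    vals = field.values.copy()
    if field.mask is not None:
        vals[field.mask] = nodata
    header = (
        f"ncols {grid.n_lon}\n"
        f"nrows {grid.n_lat}\n"
        f"xllcorner {grid.lon_min}\n"
        f"yllcorner {grid.lat_min}\n"
        f"cellsize {grid.resolution}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grids are written north-to-south
        for row in vals[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")
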