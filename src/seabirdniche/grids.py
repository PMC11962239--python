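"""Regular latitude/longitude analysis grids.

All gridded quantities in the package (environmental fields, utilisation
distributions, occurrence rasters) live on a :class:`GridSpec`: a regular
WGS84 lat/lon grid with half-open cell intervals, so every point inside the
bounding box belongs to exactly one cell.  Cell areas use the spherical
approximation with 111.195 km per degree (mean Earth radius 6371.0 km),
adequate at the ~1 degree extent of a coastal study area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: km spanned by one degree of latitude on a sphere of radius 6371.0 km
KM_PER_DEG = 111.195

#: mean Earth radius in km used for all great-circle distances
EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid with half-open cell binning.

    Cell ``(i, j)`` covers latitudes ``[lat_min + i*res, lat_min + (i+1)*res)``
    and longitudes ``[lon_min + j*res, lon_min + (j+1)*res)``.  Points on the
    upper bounding edges fall outside the grid.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float

    def __post_init__(self) -> None:
        if not self.lat_min < self.lat_max:
            raise ValueError("lat_min must be < lat_max")
        if not self.lon_min < self.lon_max:
            raise ValueError("lon_min must be < lon_max")
        if not self.resolution > 0:
            raise ValueError("resolution must be > 0")

    @property
    def n_lat(self) -> int:
        return int(np.ceil((self.lat_max - self.lat_min) / self.resolution - 1e-9))

    @property
    def n_lon(self) -> int:
        return int(np.ceil((self.lon_max - self.lon_min) / self.resolution - 1e-9))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.resolution

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.resolution

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lat >= self.lat_min)
            & (lat < self.lat_max)
            & (lon >= self.lon_min)
            & (lon < self.lon_max)
        )

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the half-open cells containing each point.

        Points outside the grid get index -1 in both arrays.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        inside = self.contains(lon, lat)
        i = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        j = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        i = np.where(inside, np.clip(i, 0, self.n_lat - 1), -1)
        j = np.where(inside, np.clip(j, 0, self.n_lon - 1), -1)
        return i, j

    def cell_area_km2(self) -> np.ndarray:
        """Per-cell area in km**2 as an (n_lat, n_lon) array.

        Area of a res x res cell centred at latitude ``phi`` is
        ``(111.195*res) * (111.195*res*cos(phi))``.
        """
        lat_c = self.lat_centers
        side = KM_PER_DEG * self.resolution
        row_area = side * side * np.cos(np.deg2rad(lat_c))
        return np.broadcast_to(row_area[:, None], self.shape).copy()

    def clip_inside(self, lon, lat, eps_frac: float = 1e-6):
        """Clamp coordinates to lie strictly inside the bounding box."""
        eps = self.resolution * eps_frac
        lon = np.clip(lon, self.lon_min + eps, self.lon_max - eps)
        lat = np.clip(lat, self.lat_min + eps, self.lat_max - eps)
        return lon, lat


def study_grid(resolution: float = 0.1) -> GridSpec:
    """The default coastal study box: 36.6-35.8 S, 149.8-150.8 E."""
    return GridSpec(
        lat_min=-36.6, lat_max=-35.8, lon_min=149.8, lon_max=150.8, resolution=resolution
    )


def haversine_km(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
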