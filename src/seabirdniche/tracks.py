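"""GPS-track standardisation: 12-min centroids, trip statistics, daily pooling.

Tags programmed at different fix rates across field seasons (4-min fixes in
some years, 30-s in others) yield tracks with incomparable point densities.
Standardising to one centroid per 12-min window -- the arithmetic mean of all
fixes in the window -- makes tracks comparable across years: a 12-min window
holds 3 fixes at 4-min sampling and 24 at 30-s sampling.

Windows are half-open, anchored at each bird-day's first fix; empty windows
emit nothing.  Centroids are plain lon/lat means, valid at sub-degree extents
far from the antimeridian (do not use near +/-180 longitude).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import haversine_km

TRACK_COLUMNS = ["bird_id", "species", "timestamp", "lon", "lat"]


def _check_tracks(fixes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in fixes.columns]
    if missing:
        raise ValueError(f"track frame missing columns: {missing}")
    fixes = fixes.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"], utc=True)
    if ((fixes["lat"] < -90) | (fixes["lat"] > 90)).any():
        raise ValueError("latitudes outside [-90, 90]")
    if ((fixes["lon"] < -180) | (fixes["lon"] > 180)).any():
        raise ValueError("longitudes outside [-180, 180]")
    for bird, sub in fixes.groupby("bird_id", sort=False):
        t = sub["timestamp"].to_numpy(dtype="datetime64[ns]")
        if (np.diff(t) <= np.timedelta64(0, "ns")).any():
            raise ValueError(f"timestamps not strictly increasing for bird {bird!r}")
    return fixes


def compute_centroids(fixes: pd.DataFrame, window_minutes: float = 12.0) -> pd.DataFrame:
    """Bin fixes into half-open windows and average positions per window.

    Returns columns ``bird_id, species, day, t_start, lon, lat, n_fixes``.
    Empty input gives an empty frame.  Windows are aligned to the first fix
    of each bird-day, so the window grid does not drift across days.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be > 0")
    if len(fixes) == 0:
        return pd.DataFrame(
            columns=["bird_id", "species", "day", "t_start", "lon", "lat", "n_fixes"]
        )
    fixes = _check_tracks(fixes)
    w = pd.Timedelta(minutes=window_minutes)
    fixes["day"] = fixes["timestamp"].dt.date
    t0 = fixes.groupby(["bird_id", "day"])["timestamp"].transform("min")
    k = ((fixes["timestamp"] - t0) // w).astype(int)
    fixes["t_start"] = t0 + k * w
    out = (
        fixes.groupby(["bird_id", "species", "day", "t_start"], sort=True)
        .agg(lon=("lon", "mean"), lat=("lat", "mean"), n_fixes=("lon", "size"))
        .reset_index()
    )
    return out


def trip_statistics(track: pd.DataFrame, colony: tuple[float, float]) -> pd.DataFrame:
    """Great-circle distance summaries from the colony, per bird-day.

    Returns columns ``bird_id, day, max_dist_km, mean_dist_km`` (haversine,
    R = 6371.0 km).  Rejects an empty track.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    colony_lon, colony_lat = colony
    track = track.copy()
    if "day" not in track.columns:
        track["day"] = pd.to_datetime(track["timestamp"], utc=True).dt.date
    track["dist_km"] = haversine_km(track["lon"], track["lat"], colony_lon, colony_lat)
    out = (
        track.groupby(["bird_id", "day"], sort=True)["dist_km"]
        .agg(max_dist_km="max", mean_dist_km="mean")
        .reset_index()
    )
    return out


def pool_daily(tracks: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool all individuals' points per (species, day).

    Returns ``(points, n_tracked)``: the pooled point table with columns
    ``species, day, lon, lat`` and a per-(species, day) count of distinct
    individuals -- the sampling-effort offset for the occurrence model.
    Order-independent; days with no points simply do not appear.
    """
    if len(tracks) == 0:
        empty_pts = pd.DataFrame(columns=["species", "day", "lon", "lat"])
        empty_n = pd.DataFrame(columns=["species", "day", "n_tracked"])
        return empty_pts, empty_n
    tracks = tracks.copy()
    if "day" not in tracks.columns:
        tracks["day"] = pd.to_datetime(tracks["timestamp"], utc=True).dt.date
    points = (
        tracks[["species", "day", "lon", "lat"]]
        .sort_values(["species", "day"], kind="stable")
        .reset_index(drop=True)
    )
    n_tracked = (
        tracks.groupby(["species", "day"], sort=True)["bird_id"]
        .nunique()
        .rename("n_tracked")
        .reset_index()
    )
    return points, n_tracked


def read_tracks_csv(path) -> pd.DataFrame:
    fixes = pd.read_csv(path)
    return _check_tracks(fixes)


def write_tracks_csv(fixes: pd.DataFrame, path) -> None:
    out = fixes[TRACK_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)
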