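"""Central-place forager track simulation.

Birds perform a biased correlated random walk from a colony: each step
combines directional persistence, an optional compass bias (e.g. northward
for gulls, southward for penguin swimmers), attraction to an optional
terrestrial point (a waste facility), and an end-of-day homing pull that
returns every bird to the colony before its tag stops recording.  Proposed
steps into water with high EAC-origin probability or high thermal
variability are rejected Metropolis-style against a logistic habitat
score, producing the habitat avoidance the downstream selection models are
asked to recover.

Three archetypes mirror the study guild: a wide-ranging flyer (crested
tern), a short-range northward flyer with a terrestrial attractor (silver
gull) and a southward-biased short-range swimmer (little penguin).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..fields import EnvField, fields_by_date
from ..grids import KM_PER_DEG, GridSpec, haversine_km

#: seconds in the 12-min reference step that step_scale_km is quoted per
REFERENCE_STEP_S = 720.0


@dataclass(frozen=True)
class SpeciesArchetype:
    """Movement and habitat-avoidance parameters of one species.

    ``step_scale_km`` is the typical displacement per 12-min interval;
    shorter fix intervals scale it linearly.  Avoidance is logistic: a
    location with covariate ``x`` has preference weight
    ``1 / (1 + exp(slope * (x - threshold)))`` (slope 0 means
    indifference), and proposed steps are accepted Metropolis-style on the
    log of that weight, so long-run usage follows the logistic curve.
    """

    name: str
    step_scale_km: float
    range_limit_km: float
    heading_bias_deg: float | None = None
    heading_bias_weight: float = 0.0
    persistence: float = 1.0
    turn_kappa: float = 4.0
    eac_avoidance_slope: float = 0.0
    eac_avoidance_threshold: float = 0.5
    sstsd_avoidance_slope: float = 0.0
    sstsd_avoidance_threshold: float = 0.5
    attractor_lonlat: tuple[float, float] | None = None
    attractor_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.step_scale_km < 0:
            raise ValueError("step_scale_km must be >= 0")
        if self.range_limit_km <= 0:
            raise ValueError("range_limit_km must be > 0")
        if not 0.0 <= self.eac_avoidance_threshold <= 1.0:
            raise ValueError("eac_avoidance_threshold must be in [0, 1]")


def _unit(theta: np.ndarray) -> np.ndarray:
    """Unit vectors (dx_east, dy_north) for bearings in radians from north."""
    return np.stack([np.sin(theta), np.cos(theta)], axis=-1)


def _bearing_to(lon, lat, target_lon, target_lat) -> np.ndarray:
    """Flat-earth bearing (radians from north) toward a target; fine at <1 deg."""
    dx = (target_lon - lon) * np.cos(np.deg2rad(lat))
    dy = target_lat - lat
    return np.arctan2(dx, dy)


def simulate_tracks(
    archetype: SpeciesArchetype,
    colony: tuple[float, float],
    env: list[EnvField],
    n_birds: int,
    fix_interval_s: int = 240,
    days: list[dt.date] | None = None,
    active_hours: float = 6.0,
    active_start_hour: float = 6.0,
    seed: int = 0,
    bird_id_prefix: str | None = None,
) -> pd.DataFrame:
    """Simulate GPS fixes for ``n_birds`` over the env-field days.

    Returns a tidy frame with columns ``bird_id, species, timestamp, lon,
    lat`` (timestamps ISO UTC).  Per bird and day the number of fixes is
    ``floor(active_seconds / fix_interval) + 1``.  All fixes lie inside the
    grid bounding box; every bird starts and ends each day at the colony.
    """
    if n_birds < 1:
        raise ValueError("n_birds must be >= 1")
    by_date = fields_by_date(env)
    if days is None:
        days = sorted(by_date)
    if not days:
        raise ValueError("no days to simulate")
    grid: GridSpec = env[0].grid
    colony_lon, colony_lat = colony
    if not grid.contains(colony_lon, colony_lat):
        raise ValueError("colony must lie inside the grid")
    for d in days:
        if d not in by_date:
            raise ValueError(f"env fields missing for day {d}")

    rng = np.random.default_rng(seed)
    n_steps = int(active_hours * 3600.0 // fix_interval_s)
    step_km = archetype.step_scale_km * fix_interval_s / REFERENCE_STEP_S
    prefix = bird_id_prefix or archetype.name[:4]
    bird_ids = [f"{prefix}_{k:02d}" for k in range(n_birds)]

    records: list[pd.DataFrame] = []
    for day in days:
        eac = by_date[day].get("eac_prob")
        ssd = by_date[day].get("sst_sd")
        t0 = pd.Timestamp(
            dt.datetime.combine(day, dt.time()), tz="UTC"
        ) + pd.Timedelta(hours=active_start_hour)
        times = t0 + pd.to_timedelta(np.arange(n_steps + 1) * fix_interval_s, unit="s")

        lon = np.full(n_birds, colony_lon)
        lat = np.full(n_birds, colony_lat)
        heading = rng.uniform(0.0, 2.0 * np.pi, n_birds)
        lon_path = np.empty((n_steps + 1, n_birds))
        lat_path = np.empty((n_steps + 1, n_birds))
        lon_path[0], lat_path[0] = lon, lat

        for s in range(1, n_steps + 1):
            remaining = n_steps - s
            lon, lat, heading = _step(
                archetype, grid, colony, eac, ssd, lon, lat, heading,
                step_km, remaining, rng,
            )
            if remaining == 0:
                # tag retrieved at the nest: close every trip at the colony
                lon = np.full(n_birds, colony_lon)
                lat = np.full(n_birds, colony_lat)
            lon_path[s], lat_path[s] = lon, lat

        records.append(
            pd.DataFrame(
                {
                    "bird_id": np.repeat(bird_ids, n_steps + 1),
                    "species": archetype.name,
                    "timestamp": np.tile(times, n_birds),
                    "lon": lon_path.T.ravel(),
                    "lat": lat_path.T.ravel(),
                }
            )
        )
    out = pd.concat(records, ignore_index=True)
    return out.sort_values(["bird_id", "timestamp"], kind="stable").reset_index(drop=True)


def _step(
    archetype: SpeciesArchetype,
    grid: GridSpec,
    colony: tuple[float, float],
    eac: EnvField | None,
    ssd: EnvField | None,
    lon: np.ndarray,
    lat: np.ndarray,
    heading: np.ndarray,
    step_km: float,
    remaining_steps: int,
    rng: np.random.Generator,
    max_tries: int = 8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance all birds by one fix interval."""
    n = lon.size
    if step_km == 0.0:
        return lon, lat, heading
    colony_lon, colony_lat = colony
    dist_home = haversine_km(lon, lat, colony_lon, colony_lat)

    # end-of-day homing: weight grows as the distance home approaches the
    # maximum distance still coverable in the remaining steps
    coverable = max(remaining_steps, 1) * step_km
    w_home = np.minimum((dist_home / coverable) ** 2, 50.0)
    # range limit: strong pull back once beyond the archetype's range
    w_home = w_home + np.where(dist_home > archetype.range_limit_km, 10.0, 0.0)

    drift = archetype.persistence * _unit(heading)
    if archetype.heading_bias_deg is not None:
        drift = drift + archetype.heading_bias_weight * _unit(
            np.full(n, np.deg2rad(archetype.heading_bias_deg))
        )
    if archetype.attractor_lonlat is not None and archetype.attractor_weight > 0:
        a_lon, a_lat = archetype.attractor_lonlat
        drift = drift + archetype.attractor_weight * _unit(_bearing_to(lon, lat, a_lon, a_lat))
    drift = drift + w_home[:, None] * _unit(_bearing_to(lon, lat, colony_lon, colony_lat))
    base_heading = np.arctan2(drift[:, 0], drift[:, 1])

    new_lon = lon.copy()
    new_lat = lat.copy()
    new_heading = heading.copy()
    score_cur = _habitat_score(archetype, eac, ssd, lon, lat)
    pending = np.ones(n, dtype=bool)
    for _ in range(max_tries):
        if not pending.any():
            break
        idx = np.flatnonzero(pending)
        h = base_heading[idx] + rng.vonmises(0.0, archetype.turn_kappa, idx.size)
        length = step_km * rng.gamma(3.0, 1.0 / 3.0, idx.size)
        dlat = length * np.cos(h) / KM_PER_DEG
        dlon = length * np.sin(h) / (KM_PER_DEG * np.cos(np.deg2rad(lat[idx])))
        p_lon, p_lat = grid.clip_inside(lon[idx] + dlon, lat[idx] + dlat)
        # Metropolis acceptance on the logistic habitat score: long-run
        # usage intensity follows the avoidance curves themselves
        score_prop = _habitat_score(archetype, eac, ssd, p_lon, p_lat)
        with np.errstate(over="ignore"):
            p_acc = np.minimum(1.0, np.exp(score_prop - score_cur[idx]))
        accept = rng.random(idx.size) < p_acc
        take = idx[accept]
        new_lon[take] = p_lon[accept]
        new_lat[take] = p_lat[accept]
        new_heading[take] = h[accept]
        score_cur[take] = score_prop[accept]
        pending[take] = False
    # birds with no accepted proposal stay put this interval
    return new_lon, new_lat, new_heading


def _habitat_score(
    archetype: SpeciesArchetype,
    eac: EnvField | None,
    ssd: EnvField | None,
    lon: np.ndarray,
    lat: np.ndarray,
) -> np.ndarray:
    """Log habitat preference: sum of log-logistic avoidance terms."""
    score = np.zeros(np.shape(lon))
    if eac is not None and archetype.eac_avoidance_slope != 0.0:
        x = eac.value_at(lon, lat)
        score -= np.logaddexp(
            0.0, archetype.eac_avoidance_slope * (x - archetype.eac_avoidance_threshold)
        )
    if ssd is not None and archetype.sstsd_avoidance_slope != 0.0:
        x = ssd.value_at(lon, lat)
        score -= np.logaddexp(
            0.0, archetype.sstsd_avoidance_slope * (x - archetype.sstsd_avoidance_threshold)
        )
    return np.nan_to_num(score, nan=-np.inf)
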