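"""Synthetic daily ocean fields with a warm-tongue intrusion.

The generator emulates the statistical structure of a western-boundary-current
shelf region: a warm, saline tongue (the EAC analogue) intrudes from the
northeast with day-to-day persistence, the per-cell probability of EAC origin
is a logistic transform of the local SST anomaly (so SST and EAC probability
are strongly positively correlated across cells), and thermal variability
(SST SD) is lowest inside the uniform warm tongue (so EAC probability and
SST SD are weakly negatively correlated).  No hydrodynamics are simulated --
only the documented correlation structure the downstream analysis needs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

import numpy as np

from ..fields import EnvField
from ..grids import GridSpec


@dataclass(frozen=True)
class WarmTongueRegime:
    """Parameters of one year's ocean regime.

    Parameters
    ----------
    sst_base : degC, reference (no-intrusion) SST at the southern boundary.
    meridional_gradient : degC per degree latitude; SST warms northward
        (toward the equator).
    tongue_amplitude : degC, peak SST anomaly of a full-strength intrusion.
    tongue_extent : degrees, e-folding half-width of the tongue shape.
    intrusion_mean, intrusion_sd, intrusion_ar : mean level, innovation SD and
        lag-1 autocorrelation of the daily intrusion strength (AR(1) clipped
        to [0, 1.5]).
    noise_sd : degC, per-cell daily SST noise.
    baseline_prob : EAC-origin probability of a cell with zero SST anomaly.
    prob_scale : degC, softness of the anomaly -> probability logistic.
    sstsd_base : degC, background thermal variability outside the tongue.
    sstsd_eac_reduction : fractional reduction of SST SD inside the tongue.
    sstsd_noise_sd : degC, per-cell daily SST-SD noise.
    """

    sst_base: float = 17.5
    meridional_gradient: float = 1.5
    tongue_amplitude: float = 3.0
    tongue_extent: float = 0.7
    intrusion_mean: float = 0.5
    intrusion_sd: float = 0.15
    intrusion_ar: float = 0.7
    noise_sd: float = 0.15
    baseline_prob: float = 0.12
    prob_scale: float = 0.6
    sstsd_base: float = 0.8
    sstsd_eac_reduction: float = 0.6
    sstsd_noise_sd: float = 0.15

    def with_(self, **kw) -> "WarmTongueRegime":
        return replace(self, **kw)


#: regimes loosely matching the three study summers: 2012 cool/variable with a
#: weak tongue, 2013 coldest and most variable, 2014 warm and EAC-dominated
#: with spatially uniform temperatures.
YEAR_REGIMES: dict[str, WarmTongueRegime] = {
    "2012": WarmTongueRegime(intrusion_mean=0.35, sstsd_base=0.9, tongue_amplitude=2.5),
    "2013": WarmTongueRegime(
        sst_base=16.8, intrusion_mean=0.30, sstsd_base=1.2, sstsd_noise_sd=0.2
    ),
    "2014": WarmTongueRegime(
        sst_base=18.2, intrusion_mean=0.85, sstsd_base=0.55, tongue_amplitude=3.5
    ),
}


def _tongue_shape(grid: GridSpec, extent: float) -> np.ndarray:
    """Smooth [0, 1] intrusion footprint, strongest in the NE corner."""
    lat = grid.lat_centers[:, None]
    lon = grid.lon_centers[None, :]
    d2 = ((lon - grid.lon_max) / extent) ** 2 + ((lat - grid.lat_max) / extent) ** 2
    return np.exp(-0.5 * d2)


def _logit(p: float) -> float:
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    return float(np.log(p / (1.0 - p)))


def generate_env_fields(
    grid: GridSpec,
    dates: list[dt.date],
    regime: WarmTongueRegime | None = None,
    seed: int = 0,
) -> list[EnvField]:
    """Generate co-registered daily (sst, eac_prob, sst_sd) fields.

    Deterministic for a fixed ``seed``.  Raises on empty ``dates`` or a
    non-positive noise SD.
    """
    if len(dates) == 0:
        raise ValueError("dates must be non-empty")
    regime = regime or WarmTongueRegime()
    if regime.noise_sd <= 0 or regime.sstsd_noise_sd <= 0:
        raise ValueError("noise SDs must be positive")

    rng = np.random.default_rng(seed)
    shape = grid.shape
    lat = grid.lat_centers[:, None]
    tongue = _tongue_shape(grid, regime.tongue_extent)
    sst_ref = regime.sst_base + regime.meridional_gradient * (lat - grid.lat_min)
    sst_ref = np.broadcast_to(sst_ref, shape)
    base_logit = _logit(regime.baseline_prob)

    fields: list[EnvField] = []
    a = regime.intrusion_mean
    for date in dates:
        # AR(1) intrusion strength, clipped to a physical range
        a = (
            regime.intrusion_mean
            + regime.intrusion_ar * (a - regime.intrusion_mean)
            + rng.normal(0.0, regime.intrusion_sd)
        )
        a = float(np.clip(a, 0.0, 1.5))

        anomaly = regime.tongue_amplitude * a * tongue + rng.normal(0.0, regime.noise_sd, shape)
        sst = sst_ref + anomaly
        with np.errstate(over="ignore"):
            eac_prob = 1.0 / (1.0 + np.exp(-(anomaly / regime.prob_scale + base_logit)))
        sst_sd = np.clip(
            regime.sstsd_base * (1.0 - regime.sstsd_eac_reduction * min(a, 1.0) * tongue)
            + rng.normal(0.0, regime.sstsd_noise_sd, shape),
            0.0,
            None,
        )
        fields.append(EnvField(date=date, variable="sst", grid=grid, values=sst))
        fields.append(EnvField(date=date, variable="eac_prob", grid=grid, values=eac_prob))
        fields.append(EnvField(date=date, variable="sst_sd", grid=grid, values=sst_sd))
    return fields
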