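"""Default study conditions for the synthetic system.

These constants emulate a three-summer tracking campaign of three sympatric
seabirds breeding on an island colony inside the study grid: a wide-ranging
flyer (crested tern), a short-range northward flyer that also commutes to a
terrestrial waste facility (silver gull), and a southward-biased short-range
swimmer (little penguin).  Trip ranges follow the species' reported maxima
(about 46, 24 and 29 km from the colony); both fish specialists avoid
EAC-origin water above ~30% probability while the generalist gull responds
mainly to thermal variability.  Isotope clusters put the gull at a distinctly
lower trophic level (delta15N) with the widest niche, and the two fish
specialists close together with year-to-year changes in spread.
"""

from __future__ import annotations

import datetime as dt

from ..grids import GridSpec, study_grid
from .env import YEAR_REGIMES, WarmTongueRegime
from .isotopes import IsotopeGenParams, IsotopeGroupParams
from .movement import SpeciesArchetype

#: island colony inside the study grid
COLONY = (150.227, -36.253)

#: terrestrial waste facility ~12 km NW of the colony
WASTE_FACILITY = (150.12, -36.17)

SPECIES = ("crested_tern", "little_penguin", "silver_gull")

ARCHETYPES: dict[str, SpeciesArchetype] = {
    "crested_tern": SpeciesArchetype(
        name="crested_tern",
        step_scale_km=4.0,
        range_limit_km=46.0,
        persistence=1.0,
        turn_kappa=4.0,
        eac_avoidance_slope=12.0,
        eac_avoidance_threshold=0.3,
        sstsd_avoidance_slope=8.0,
        sstsd_avoidance_threshold=0.5,
    ),
    "little_penguin": SpeciesArchetype(
        name="little_penguin",
        step_scale_km=1.5,
        range_limit_km=25.0,
        heading_bias_deg=180.0,
        heading_bias_weight=1.5,
        persistence=1.0,
        turn_kappa=3.0,
        eac_avoidance_slope=12.0,
        eac_avoidance_threshold=0.3,
        sstsd_avoidance_slope=8.0,
        sstsd_avoidance_threshold=0.5,
    ),
    "silver_gull": SpeciesArchetype(
        name="silver_gull",
        step_scale_km=2.0,
        range_limit_km=24.0,
        heading_bias_deg=0.0,
        heading_bias_weight=1.2,
        persistence=1.0,
        turn_kappa=3.0,
        eac_avoidance_slope=2.0,
        eac_avoidance_threshold=0.5,
        sstsd_avoidance_slope=10.0,
        sstsd_avoidance_threshold=0.5,
        attractor_lonlat=WASTE_FACILITY,
        attractor_weight=1.0,
    ),
}

YEARS = ("2012", "2013", "2014")

#: birds tracked per species-year (>= 8 so the n_sub = 8 resampling applies)
N_BIRDS = {"crested_tern": 10, "little_penguin": 10, "silver_gull": 10}

#: GPS fix programming per year: 4-min fixes in 2012-13, 30-s fixes in 2014
FIX_INTERVAL_S = {"2012": 240, "2013": 240, "2014": 30}

#: sampling-window length per year (days); the field seasons ran Sep-Dec,
#: scaled here to a fortnight for a self-contained runnable study
DEFAULT_WINDOW_DAYS = 15


def year_dates(year: str, n_days: int = DEFAULT_WINDOW_DAYS) -> list[dt.date]:
    start = dt.date(int(year), 10, 1)
    return [start + dt.timedelta(days=k) for k in range(n_days)]


def default_grid() -> GridSpec:
    return study_grid(0.1)


def default_regime(year: str) -> WarmTongueRegime:
    return YEAR_REGIMES[year]


# species-year isotope clusters (permil). delta13C centres follow the fitted
# species contrasts (tern -16.8, penguin -1.1 below, gull -1.9 below); the
# gull sits ~2.4 permil lower in delta15N with the widest, most stable
# niche; tern spread peaks in 2012 and penguin spread in 2014.
_D15N_YEAR_SHIFT = {"2012": 0.3, "2013": 0.0, "2014": -0.4}


def _cov(sx2: float, sy2: float, r: float = 0.2) -> tuple:
    c = r * (sx2 * sy2) ** 0.5
    return ((sx2, c), (c, sy2))


ISOTOPE_BASE = {
    "crested_tern": {"mean": (-16.8, 15.5), "n": 11},
    "little_penguin": {"mean": (-17.9, 15.7), "n": 33},
    "silver_gull": {"mean": (-18.7, 13.1), "n": 11},
}

ISOTOPE_COVS = {
    ("crested_tern", "2012"): _cov(0.8, 0.7),
    ("crested_tern", "2013"): _cov(0.4, 0.35),
    ("crested_tern", "2014"): _cov(0.3, 0.3),
    ("little_penguin", "2012"): _cov(0.25, 0.3),
    ("little_penguin", "2013"): _cov(0.3, 0.3),
    ("little_penguin", "2014"): _cov(0.7, 0.6),
    ("silver_gull", "2012"): _cov(1.3, 1.1),
    ("silver_gull", "2013"): _cov(1.4, 1.2),
    ("silver_gull", "2014"): _cov(1.3, 1.0),
}


def default_isotope_params() -> IsotopeGenParams:
    groups = []
    for sp, base in ISOTOPE_BASE.items():
        for year in YEARS:
            mx, my = base["mean"]
            groups.append(
                IsotopeGroupParams(
                    species=sp,
                    year=year,
                    mean=(mx, my + _D15N_YEAR_SHIFT[year]),
                    cov=ISOTOPE_COVS[(sp, year)],
                    n=base["n"],
                )
            )
    return IsotopeGenParams(groups=tuple(groups))
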