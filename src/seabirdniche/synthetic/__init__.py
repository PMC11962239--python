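"""Synthetic ocean fields, seabird tracks and isotope samples.

One master seed drives all generators through deterministic child seeds
(:func:`child_seed`), so a full synthetic study is reproducible from a
single integer.
"""

from __future__ import annotations

import hashlib

from .defaults import (
    ARCHETYPES,
    COLONY,
    FIX_INTERVAL_S,
    ISOTOPE_BASE,
    N_BIRDS,
    SPECIES,
    WASTE_FACILITY,
    YEARS,
    default_grid,
    default_isotope_params,
    default_regime,
    year_dates,
)
from .env import YEAR_REGIMES, WarmTongueRegime, generate_env_fields
from .isotopes import IsotopeGenParams, IsotopeGroupParams, simulate_isotopes
from .movement import SpeciesArchetype, simulate_tracks

__all__ = [
    "ARCHETYPES",
    "COLONY",
    "FIX_INTERVAL_S",
    "ISOTOPE_BASE",
    "IsotopeGenParams",
    "IsotopeGroupParams",
    "N_BIRDS",
    "SPECIES",
    "SpeciesArchetype",
    "WASTE_FACILITY",
    "WarmTongueRegime",
    "YEARS",
    "YEAR_REGIMES",
    "child_seed",
    "default_grid",
    "default_isotope_params",
    "default_regime",
    "generate_env_fields",
    "simulate_isotopes",
    "simulate_tracks",
    "year_dates",
]


def child_seed(master_seed: int, label: str) -> int:
    """Deterministic per-generator child seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
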