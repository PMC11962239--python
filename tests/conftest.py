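import datetime as dt

import numpy as np
import pytest

from seabirdniche.grids import GridSpec, study_grid
from seabirdniche.synthetic import (
    ARCHETYPES,
    COLONY,
    default_regime,
    generate_env_fields,
    simulate_tracks,
)


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return study_grid(0.1)


@pytest.fixture(scope="session")
def dates() -> list[dt.date]:
    return [dt.date(2013, 10, 1) + dt.timedelta(days=k) for k in range(6)]


@pytest.fixture(scope="session")
def env_fields(grid, dates):
    return generate_env_fields(grid, dates, default_regime("2013"), seed=42)


@pytest.fixture(scope="session")
def tern_tracks(env_fields):
    return simulate_tracks(
        ARCHETYPES["crested_tern"], COLONY, env_fields, n_birds=6, fix_interval_s=240, seed=7
    )


@pytest.fixture()
def rng():
    # fresh generator per test so results do not depend on execution order
    return np.random.default_rng(2024)
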