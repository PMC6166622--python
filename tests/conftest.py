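"""Shared fixtures: a small island world and simple current fields."""

from datetime import datetime

import numpy as np
import pytest

from larvanet.forcing import (
    GridSpec,
    IslandSpec,
    UniformFlow,
    make_current_series,
    make_habitat_sites,
    make_island_domain,
)


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(lon_min=201.0, lon_max=201.6, lat_min=21.0, lat_max=21.5, cell_size=0.01)


@pytest.fixture(scope="session")
def island_domain(small_grid):
    isl = IslandSpec(name="focal", lon=201.3, lat=21.25, radius_m=8000.0, focal=True)
    return make_island_domain(small_grid, [isl])


@pytest.fixture(scope="session")
def ring_sites(island_domain):
    return make_habitat_sites(island_domain, n_sites=32, seed=0)


@pytest.fixture()
def still_series(small_grid, island_domain):
    return make_current_series(small_grid, UniformFlow(0.0, 0.0), n_days=40, domain=island_domain)


@pytest.fixture()
def drift_series(small_grid, island_domain):
    return make_current_series(small_grid, UniformFlow(0.1, 0.0), n_days=40, domain=island_domain)


@pytest.fixture(scope="session")
def t0():
    return datetime(2011, 1, 1)
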