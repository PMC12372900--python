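import pytest

from airburden.grids import GridDefinition
from airburden.spatial import intersect_counties
from airburden.synthetic import (
    SyntheticScenarioSpec,
    generate_counties,
    generate_grid,
    generate_population,
    generate_rate_table,
    generate_scenarios,
)


@pytest.fixture(scope="session")
def grid() -> GridDefinition:
    return generate_grid(10, 12, origin=(30.0, -100.0), resolution=(0.25, 0.3125))


@pytest.fixture(scope="session")
def scenario_set(grid):
    spec = SyntheticScenarioSpec(hotspots_per_stage=2, noise_scale=0.1, seed=7)
    return generate_scenarios(grid, spec)


@pytest.fixture(scope="session")
def counties(grid):
    return generate_counties(grid, 3, 4, seed=11)


@pytest.fixture(scope="session")
def weights(grid, counties):
    return intersect_counties(grid, counties)


@pytest.fixture(scope="session")
def population(grid):
    return generate_population(grid, total=500_000, seed=5)


@pytest.fixture(scope="session")
def rate_table(counties):
    return generate_rate_table(counties, suppression_threshold=10, seed=13)
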