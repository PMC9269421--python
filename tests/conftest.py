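import numpy as np
import pytest

from ecoclimex import (
    OccurrenceSamplingSpec,
    SoilMoistureConfig,
    SpeciesParameters,
    SyntheticClimateSpec,
    generate_climate_grid,
    run_grid,
    sample_occurrences,
)


@pytest.fixture(scope="session")
def params() -> SpeciesParameters:
    return SpeciesParameters()


@pytest.fixture(scope="session")
def soil_cfg() -> SoilMoistureConfig:
    return SoilMoistureConfig()


@pytest.fixture(scope="session")
def small_grid():
    """A 12x24 seeded synthetic globe exercising all latitude bands."""
    return generate_climate_grid(SyntheticClimateSpec(n_lat=12, n_lon=24, seed=7))


@pytest.fixture(scope="session")
def small_map(small_grid):
    return run_grid(small_grid)


@pytest.fixture(scope="session")
def sampled_points(small_map):
    return sample_occurrences(
        small_map, OccurrenceSamplingSpec(n_points=150, contamination_fraction=0.0, seed=11)
    )


def constant_cell_grid(tmean: float, precip: float, rh: float = 0.7, diurnal: float = 0.0):
    """Single-cell grid with a flat annual cycle — handy for analytic checks."""
    from ecoclimex import ClimateGrid

    ones = np.ones((1, 12))
    return ClimateGrid(
        lat=np.array([0.0]),
        lon=np.array([0.0]),
        tmin=ones * (tmean - diurnal / 2),
        tmax=ones * (tmean + diurnal / 2),
        precip=ones * precip,
        rh09=ones * rh,
        rh15=ones * rh,
    )
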