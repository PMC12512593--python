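"""Shared fixtures: small synthetic cities generated once per session."""

import numpy as np
import pytest

import greenequity as ge


@pytest.fixture(scope="session")
def small_city() -> ge.SyntheticCity:
    """A compact Aarhus-like city (rich, dirty centre) for fast pipeline tests."""
    cfg = ge.CityConfig.aarhus_like(seed=7, extent_m=3000.0, n_zones=9, n_buildings=120)
    return ge.generate_city(cfg)


@pytest.fixture(scope="session")
def small_city_surfaces(small_city) -> ge.ScenarioSurfaces:
    """Meta-model surfaces for the small city with unchanged land cover."""
    return ge.scenario_surfaces(
        ge.AARHUS,
        small_city.landcover,
        small_city.landcover,
        small_city.coarse_pm25.grid,
        small_city.coarse_pm25,
        small_city.fine_pm25,
    )


@pytest.fixture(scope="session")
def small_city_table(small_city, small_city_surfaces) -> ge.ExposureTable:
    return ge.exposure_table(
        small_city.buildings,
        small_city.zone_table,
        small_city_surfaces,
        small_city.landcover,
        small_city.landcover,
    )


def uniform_landcover(code: int, n: int = 40, res: float = 5.0) -> ge.LandCoverRaster:
    """A single-class n x n land-cover raster with origin (0, n*res)."""
    grid = ge.GridSpec(0.0, n * res, res, n, n)
    return ge.LandCoverRaster(grid, np.full((n, n), code, dtype=np.uint8))
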