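"""Readers and writers for the pipeline's on-disk formats.

Rasters are single-band GeoTIFFs in a planar metric CRS; georeferencing is
carried by the standard GeoTIFF ModelPixelScale (33550) and ModelTiepoint
(33922) tags, written and read through ``tifffile``.  Land cover is a uint8
band using the :class:`~greenequity.raster_core.LandClass` code table;
concentration rasters are float64 so values round-trip exactly.  Vector data
(buildings, zones) are GeoJSON FeatureCollections with planar coordinates;
zone tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Point, mapping, shape

from .errors import ConfigurationError
from .exposure import Building, ZoneTable
from .raster_core import ConcentrationRaster, GridSpec, LandCoverRaster
from .zones import Zone

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_geotiff(path, values: np.ndarray, grid: GridSpec) -> None:
    """Write a single-band GeoTIFF with north-up georeferencing tags."""
    res = float(grid.res_m)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (res, res, 0.0), False),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0), False),
    ]
    tifffile.imwrite(str(path), values, extratags=extratags)


def read_geotiff(path) -> tuple[np.ndarray, GridSpec]:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise ConfigurationError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy, _ = tags[_MODEL_PIXEL_SCALE].value
        i, j, _, x, y, _ = tags[_MODEL_TIEPOINT].value
        if abs(sx - sy) > 1e-9:
            raise ConfigurationError(f"{path}: non-square pixels ({sx} x {sy}) unsupported")
        if i != 0 or j != 0:
            raise ConfigurationError(f"{path}: tiepoint not at the raster origin")
    nrows, ncols = values.shape
    return values, GridSpec(origin_x=float(x), origin_y=float(y), res_m=float(sx), nrows=nrows, ncols=ncols)


def write_landcover(path, lc: LandCoverRaster) -> None:
    write_geotiff(path, lc.classes.astype(np.uint8), lc.grid)


def read_landcover(path) -> LandCoverRaster:
    values, grid = read_geotiff(path)
    return LandCoverRaster(grid, values.astype(np.uint8))


def write_concentration(path, r: ConcentrationRaster) -> None:
    write_geotiff(path, r.values.astype(np.float64), r.grid)


def read_concentration(path, role: str = "baseline") -> ConcentrationRaster:
    values, grid = read_geotiff(path)
    return ConcentrationRaster(grid, values.astype(np.float64), role=role)


# ---------------------------------------------------------------------------
# vectors
# ---------------------------------------------------------------------------

def write_buildings(path, buildings: list[Building]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(Point(b.x, b.y)),
            "properties": {"id": b.id, "population": b.population, "zone_id": b.zone_id},
        }
        for b in buildings
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_buildings(path) -> list[Building]:
    fc = json.loads(Path(path).read_text())
    out = []
    for f in fc.get("features", []):
        geom = shape(f["geometry"])
        props = f["properties"]
        out.append(
            Building(
                id=int(props["id"]),
                x=float(geom.x),
                y=float(geom.y),
                population=float(props["population"]),
                zone_id=int(props["zone_id"]),
            )
        )
    return out


def write_zones(path, zones: list[Zone]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(z.polygon),
            "properties": {"zone_id": z.zone_id},
        }
        for z in zones
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_zones(path) -> list[Zone]:
    fc = json.loads(Path(path).read_text())
    return [
        Zone(zone_id=int(f["properties"]["zone_id"]), polygon=shape(f["geometry"]))
        for f in fc.get("features", [])
    ]


# ---------------------------------------------------------------------------
# zone tables
# ---------------------------------------------------------------------------

def write_zone_table(counts_path, income_path, table: ZoneTable) -> None:
    table.counts.sort_values(["zone_id", "category", "subcategory"]).to_csv(counts_path, index=False)
    pd.DataFrame(
        {
            "zone_id": table.population.index,
            "population": table.population.to_numpy(),
            "median_income": table.median_income.reindex(table.population.index).to_numpy(),
        }
    ).to_csv(income_path, index=False)


def read_zone_table(counts_path, income_path) -> ZoneTable:
    counts = pd.read_csv(counts_path)
    income = pd.read_csv(income_path).set_index("zone_id")
    return ZoneTable(
        population=income["population"],
        counts=counts,
        median_income=income["median_income"],
    )


# ---------------------------------------------------------------------------
# whole cities
# ---------------------------------------------------------------------------

CITY_FILES = {
    "landcover": "landcover.tif",
    "fine_pm25": "pm25_fine.tif",
    "coarse_pm25": "pm25_coarse.tif",
    "buildings": "buildings.geojson",
    "zones": "zones.geojson",
    "zone_counts": "zone_counts.csv",
    "zone_income": "zone_income.csv",
    "meta": "city_meta.json",
}


def write_city(city, directory) -> None:
    """Write every component of a synthetic city to a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_landcover(d / CITY_FILES["landcover"], city.landcover)
    write_concentration(d / CITY_FILES["fine_pm25"], city.fine_pm25)
    write_concentration(d / CITY_FILES["coarse_pm25"], city.coarse_pm25)
    write_buildings(d / CITY_FILES["buildings"], city.buildings)
    write_zones(d / CITY_FILES["zones"], city.zones)
    write_zone_table(d / CITY_FILES["zone_counts"], d / CITY_FILES["zone_income"], city.zone_table)
    meta = {"config": city.config.to_dict(), "truth": city.truth}
    (d / CITY_FILES["meta"]).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_city(directory):
    """Read a city directory back into a :class:`SyntheticCity`."""
    from .synthetic_city import CityConfig, SyntheticCity

    d = Path(directory)
    meta = json.loads((d / CITY_FILES["meta"]).read_text())
    return SyntheticCity(
        config=CityConfig.from_dict(meta["config"]),
        landcover=read_landcover(d / CITY_FILES["landcover"]),
        buildings=read_buildings(d / CITY_FILES["buildings"]),
        zones=read_zones(d / CITY_FILES["zones"]),
        zone_table=read_zone_table(d / CITY_FILES["zone_counts"], d / CITY_FILES["zone_income"]),
        coarse_pm25=read_concentration(d / CITY_FILES["coarse_pm25"]),
        fine_pm25=read_concentration(d / CITY_FILES["fine_pm25"]),
        truth=meta["truth"],
    )
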