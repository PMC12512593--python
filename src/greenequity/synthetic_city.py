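"""Synthetic-city generator.

Emulates the data structure of the real study inputs — a 5 m categorical
land-cover raster, residential building points with population, statistical
zones with subgroup count tables and a single median income, and coarse
(3 km) plus fine (1 km) PM2.5 baseline rasters — with controllable radial
spatial gradients, so every downstream stage (greening, air quality,
exposure, equity reporting) runs and is testable with no external data.

Each continuous field (baseline PM2.5, tree-canopy probability, median
income) is ``centre + slope * distance_from_centre + Gaussian noise``.  The
signs of the planted slopes determine the social geography: a "Paris-like"
city has a poor, dirty, tree-sparse centre (income rises with distance from
the centre while PM2.5 falls), an "Aarhus-like" city a rich, dirty centre
(income and PM2.5 both fall with distance).  The planted gradients are
recorded on the generated city so recovery tests can check the pipeline
reproduces them.

Randomness uses one root seed with an independent child stream per field,
so changing one gradient's parameters never perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .exposure import CATEGORIES, Building, ZoneTable
from .raster_core import ConcentrationRaster, GridSpec, LandClass, LandCoverRaster
from .zones import Zone, tessellate, zone_of_point

#: child RNG stream ids, one per generated field
_STREAMS = {"landcover": 0, "pm25": 1, "income": 2, "buildings": 3, "population": 4, "subgroups": 5}

#: minimum admissible PM2.5 concentration after noise (ug m-3)
_PM_FLOOR = 0.1


@dataclass(frozen=True)
class GradientSpec:
    """Radial linear field: centre value + slope * distance + noise."""

    centre: float
    slope_per_m: float
    noise_sd: float


@dataclass
class CityConfig:
    """Parameters of a synthetic city.

    Resolutions must nest: ``extent_m`` divisible by ``coarse_res_m``,
    coarse by fine, fine by the land-cover resolution.  Subgroup proportions
    per zone come from a softmax (logistic) link on standardised zone median
    income, with per-category effect strengths in ``subgroup_effects``.
    """

    extent_m: float = 9000.0
    landcover_res_m: float = 5.0
    fine_res_m: float = 1000.0
    coarse_res_m: float = 3000.0
    n_zones: int = 25
    n_buildings: int = 2000
    seed: int = 0
    baseline_pm25: GradientSpec = field(default_factory=lambda: GradientSpec(12.0, -2.0e-4, 0.15))
    tree_fraction: GradientSpec = field(default_factory=lambda: GradientSpec(0.08, 3.0e-5, 0.02))
    income: GradientSpec = field(default_factory=lambda: GradientSpec(22_000.0, 1.0, 800.0))
    #: non-tree land cover shares (renormalised over the non-tree remainder)
    class_mix: dict[int, float] = field(
        default_factory=lambda: {
            int(LandClass.GRASS): 0.50,
            int(LandClass.MINERAL): 0.35,
            int(LandClass.BARE): 0.08,
            int(LandClass.WATER): 0.07,
        }
    )
    #: log-normal (mu, sigma) of persons per building
    population_lognormal: tuple[float, float] = (3.0, 0.7)
    #: per category: subcategory -> effect of standardised zone income on the
    #: softmax score (positive = subgroup overrepresented in richer zones)
    subgroup_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "age": {"<18": -0.15, "18-64": 0.10, ">=65": 0.0},
            "citizenship": {"citizen": 0.35, "non-citizen": -0.35},
            "education": {"primary": -0.40, "secondary": 0.0, "tertiary": 0.40},
            "employment": {"unemployed": -0.50, "employed": 0.50},
        }
    )
    #: city-wide baseline shares per category (same subcategory order)
    subgroup_base_shares: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "age": {"<18": 0.21, "18-64": 0.62, ">=65": 0.17},
            "citizenship": {"citizen": 0.86, "non-citizen": 0.14},
            "education": {"primary": 0.25, "secondary": 0.45, "tertiary": 0.30},
            "employment": {"unemployed": 0.07, "employed": 0.93},
        }
    )
    #: sd of zone-level noise added to the standardised-income predictor
    subgroup_noise_sd: float = 0.10
    #: >0 concentrates buildings toward the centre, <0 toward the edge
    building_density_bias: float = 0.0

    # -- canned study conditions ----------------------------------------
    @classmethod
    def paris_like(cls, seed: int = 0, **overrides: Any) -> "CityConfig":
        """Poor, dirty, tree-sparse centre: income rises outward, PM2.5 falls."""
        cfg = cls(
            seed=seed,
            baseline_pm25=GradientSpec(15.5, -2.0e-4, 0.15),
            tree_fraction=GradientSpec(0.06, 3.0e-5, 0.02),
            income=GradientSpec(22_000.0, 1.0, 800.0),
        )
        return replace(cfg, **overrides)

    @classmethod
    def aarhus_like(cls, seed: int = 0, **overrides: Any) -> "CityConfig":
        """Rich, dirty centre: income and PM2.5 both fall outward."""
        cfg = cls(
            seed=seed,
            baseline_pm25=GradientSpec(10.8, -2.0e-4, 0.15),
            tree_fraction=GradientSpec(0.10, 3.0e-5, 0.02),
            income=GradientSpec(32_000.0, -1.0, 800.0),
        )
        return replace(cfg, **overrides)

    def validate(self) -> None:
        for name, res in (
            ("landcover_res_m", self.landcover_res_m),
            ("fine_res_m", self.fine_res_m),
            ("coarse_res_m", self.coarse_res_m),
        ):
            if res <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {res}")
        pairs = [
            ("extent_m", self.extent_m, "coarse_res_m", self.coarse_res_m),
            ("coarse_res_m", self.coarse_res_m, "fine_res_m", self.fine_res_m),
            ("fine_res_m", self.fine_res_m, "landcover_res_m", self.landcover_res_m),
        ]
        for big_name, big, small_name, small in pairs:
            if abs((big / small) - round(big / small)) > 1e-9:
                raise ConfigurationError(
                    f"{big_name} ({big}) is not an integer multiple of {small_name} ({small})"
                )
        if self.n_zones < 3:
            raise ConfigurationError(f"n_zones must be >= 3, got {self.n_zones}")
        if self.n_buildings < 1:
            raise ConfigurationError("n_buildings must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CityConfig":
        d = dict(d)
        for key in ("baseline_pm25", "tree_fraction", "income"):
            if isinstance(d.get(key), (list, tuple, dict)):
                v = d[key]
                d[key] = GradientSpec(**v) if isinstance(v, dict) else GradientSpec(*v)
        if "class_mix" in d:
            d["class_mix"] = {int(k): float(v) for k, v in d["class_mix"].items()}
        if "population_lognormal" in d:
            d["population_lognormal"] = tuple(d["population_lognormal"])
        return cls(**d)


@dataclass
class SyntheticCity:
    """A fully generated city plus the record of its planted gradients."""

    config: CityConfig
    landcover: LandCoverRaster
    buildings: list[Building]
    zones: list[Zone]
    zone_table: ZoneTable
    coarse_pm25: ConcentrationRaster
    fine_pm25: ConcentrationRaster
    truth: dict


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[stream])))


def _radial_field(
    spec: GradientSpec,
    xs: np.ndarray,
    ys: np.ndarray,
    centre_xy: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Evaluate a radial gradient field on a center-coordinate mesh."""
    dist = np.hypot(xs[None, :] - centre_xy[0], ys[:, None] - centre_xy[1])
    out = spec.centre + spec.slope_per_m * dist
    if spec.noise_sd > 0:
        out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
    return out


def generate_city(config: CityConfig) -> SyntheticCity:
    """Generate a deterministic synthetic city from a config and seed."""
    config.validate()
    ext = config.extent_m
    centre = (ext / 2.0, ext / 2.0)

    lc_grid = GridSpec(0.0, ext, config.landcover_res_m, int(round(ext / config.landcover_res_m)), int(round(ext / config.landcover_res_m)))
    fine_grid = GridSpec(0.0, ext, config.fine_res_m, int(round(ext / config.fine_res_m)), int(round(ext / config.fine_res_m)))
    coarse_grid = GridSpec(0.0, ext, config.coarse_res_m, int(round(ext / config.coarse_res_m)), int(round(ext / config.coarse_res_m)))

    # -- land cover ------------------------------------------------------
    rng_lc = _rng(config.seed, "landcover")
    p_tree = np.clip(
        _radial_field(config.tree_fraction, lc_grid.x_centers(), lc_grid.y_centers(), centre, rng_lc),
        0.0,
        1.0,
    )
    u_tree = rng_lc.random(lc_grid.shape)
    classes = np.empty(lc_grid.shape, dtype=np.uint8)
    tree = u_tree < p_tree
    classes[tree] = int(LandClass.TREE)
    mix_codes = list(config.class_mix.keys())
    mix_probs = np.asarray([config.class_mix[c] for c in mix_codes], dtype=float)
    mix_probs = mix_probs / mix_probs.sum()
    u_other = rng_lc.random(lc_grid.shape)
    idx = np.searchsorted(np.cumsum(mix_probs), u_other[~tree], side="right")
    classes[~tree] = np.asarray(mix_codes, dtype=np.uint8)[np.minimum(idx, len(mix_codes) - 1)]

    # -- buildings -------------------------------------------------------
    rng_b = _rng(config.seed, "buildings")
    n = config.n_buildings
    if config.building_density_bias == 0.0:
        bx = rng_b.random(n) * ext
        by = rng_b.random(n) * ext
    else:
        # rejection sampling against a radial exponential density profile,
        # normalised so the acceptance probability peaks at 1
        bias = config.building_density_bias
        d_max = math.sqrt(0.5)  # corner distance in extent units
        peak = 1.0 if bias > 0 else math.exp(-bias * d_max)
        bx = np.empty(0)
        by = np.empty(0)
        while len(bx) < n:
            cx = rng_b.random(2 * n) * ext
            cy = rng_b.random(2 * n) * ext
            d = np.hypot(cx - centre[0], cy - centre[1]) / ext
            accept = rng_b.random(2 * n) < np.exp(-bias * d) / peak
            bx = np.concatenate([bx, cx[accept]])
            by = np.concatenate([by, cy[accept]])
        bx, by = bx[:n], by[:n]
    rng_pop = _rng(config.seed, "population")
    mu, sigma = config.population_lognormal
    pops = rng_pop.lognormal(mean=mu, sigma=sigma, size=n)

    zones = tessellate(ext, config.n_zones)
    zone_ids = np.array([zone_of_point(zones, ext, x, y) for x, y in zip(bx, by)])
    buildings = [
        Building(id=i, x=float(bx[i]), y=float(by[i]), population=float(pops[i]), zone_id=int(zone_ids[i]))
        for i in range(n)
    ]
    # stamp building cells into the land cover
    rows = np.floor((lc_grid.origin_y - by) / lc_grid.res_m).astype(int).clip(0, lc_grid.nrows - 1)
    cols = np.floor((bx - lc_grid.origin_x) / lc_grid.res_m).astype(int).clip(0, lc_grid.ncols - 1)
    classes[rows, cols] = int(LandClass.BUILDING)
    landcover = LandCoverRaster(lc_grid, classes)

    # -- PM2.5 baselines (coarse modelled field, fine satellite-style) ---
    rng_pm = _rng(config.seed, "pm25")
    coarse_vals = np.maximum(
        _radial_field(config.baseline_pm25, coarse_grid.x_centers(), coarse_grid.y_centers(), centre, rng_pm),
        _PM_FLOOR,
    )
    fine_vals = np.maximum(
        _radial_field(config.baseline_pm25, fine_grid.x_centers(), fine_grid.y_centers(), centre, rng_pm),
        _PM_FLOOR,
    )
    coarse_pm25 = ConcentrationRaster(coarse_grid, coarse_vals)
    fine_pm25 = ConcentrationRaster(fine_grid, fine_vals)

    # -- zone table ------------------------------------------------------
    rng_inc = _rng(config.seed, "income")
    cx = np.array([z.centroid[0] for z in zones])
    cy = np.array([z.centroid[1] for z in zones])
    d = np.hypot(cx - centre[0], cy - centre[1])
    incomes = config.income.centre + config.income.slope_per_m * d
    if config.income.noise_sd > 0:
        incomes = incomes + rng_inc.normal(0.0, config.income.noise_sd, size=len(zones))
    zone_pop = pd.Series(0.0, index=pd.Index(range(config.n_zones), name="zone_id"))
    for b in buildings:
        zone_pop[b.zone_id] += b.population

    sd = incomes.std()
    z_income = (incomes - incomes.mean()) / sd if sd > 0 else np.zeros_like(incomes)
    rng_sub = _rng(config.seed, "subgroups")
    records = []
    for category, subcats in CATEGORIES.items():
        base = config.subgroup_base_shares[category]
        betas = config.subgroup_effects[category]
        eps = (
            rng_sub.normal(0.0, config.subgroup_noise_sd, size=len(zones))
            if config.subgroup_noise_sd > 0
            else np.zeros(len(zones))
        )
        scores = np.stack(
            [np.log(base[s]) + betas[s] * (z_income + eps) for s in subcats], axis=1
        )
        p = np.exp(scores - scores.max(axis=1, keepdims=True))
        p = p / p.sum(axis=1, keepdims=True)
        for j, s in enumerate(subcats):
            for zid in range(config.n_zones):
                records.append(
                    {
                        "zone_id": zid,
                        "category": category,
                        "subcategory": s,
                        "count": p[zid, j] * zone_pop[zid],
                    }
                )
    zone_table = ZoneTable(
        population=zone_pop,
        counts=pd.DataFrame.from_records(records),
        median_income=pd.Series(incomes, index=zone_pop.index),
    )

    truth = {
        "pm25_slope": config.baseline_pm25.slope_per_m,
        "tree_slope": config.tree_fraction.slope_per_m,
        "income_slope": config.income.slope_per_m,
        # sign of the expected zone-level income vs PM2.5 association:
        # both fields are radial, so the product of slope signs decides it
        "income_pm25_corr_sign": int(np.sign(config.income.slope_per_m * config.baseline_pm25.slope_per_m)),
        "income_tree_corr_sign": int(np.sign(config.income.slope_per_m * config.tree_fraction.slope_per_m)),
    }

    return SyntheticCity(
        config=config,
        landcover=landcover,
        buildings=buildings,
        zones=zones,
        zone_table=zone_table,
        coarse_pm25=coarse_pm25,
        fine_pm25=fine_pm25,
        truth=truth,
    )


def write_city(city: SyntheticCity, directory) -> None:
    """Serialise a city to a directory of GeoTIFF / GeoJSON / CSV / JSON files."""
    from . import equity_io

    equity_io.write_city(city, directory)
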