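"""Disaggregation, weighted means, income quintiles, the exposure table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import greenequity as ge
from greenequity.errors import (
    DisaggregationError,
    SingleClassError,
    UndefinedExposureError,
)
from greenequity.exposure import CATEGORIES, buildings_frame


def simple_zone_table(populations: dict[int, float], incomes: dict[int, float] | None = None,
                      employed_share: float = 0.4) -> ge.ZoneTable:
    """Zone table with a uniform subgroup split in every category."""
    records = []
    for zid, pop in populations.items():
        for category, subcats in CATEGORIES.items():
            if category == "employment":
                shares = [1 - employed_share, employed_share]  # unemployed, employed
            else:
                shares = [1.0 / len(subcats)] * len(subcats)
            for s, share in zip(subcats, shares):
                records.append(
                    {"zone_id": zid, "category": category, "subcategory": s, "count": share * pop}
                )
    incomes = incomes or {zid: 1000.0 + zid for zid in populations}
    return ge.ZoneTable(
        population=pd.Series(populations),
        counts=pd.DataFrame.from_records(records),
        median_income=pd.Series(incomes),
    )


class TestDisaggregate:
    def test_proportion_times_building_population(self):
        zt = simple_zone_table({0: 100.0}, employed_share=0.4)
        b = [ge.Building(id=0, x=0, y=0, population=10.0, zone_id=0)]
        w = ge.disaggregate(zt, b)
        assert w.loc[0, ("employment", "employed")] == pytest.approx(4.0, abs=1e-12)

    def test_single_building_inherits_all_zone_counts(self):
        zt = simple_zone_table({0: 85.0})
        b = [ge.Building(id=0, x=0, y=0, population=85.0, zone_id=0)]
        w = ge.disaggregate(zt, b)
        wide = zt.counts_wide()
        np.testing.assert_allclose(w.loc[0].to_numpy(), wide.loc[0].to_numpy(), atol=1e-9)

    def test_conservation_across_random_city(self):
        city = ge.generate_city(
            ge.CityConfig(extent_m=6000.0, n_zones=20, n_buildings=400, seed=21)
        )
        w = ge.disaggregate(city.zone_table, city.buildings)
        bframe = buildings_frame(city.buildings)
        got = w.groupby(bframe["zone_id"]).sum()
        wide = city.zone_table.counts_wide().loc[got.index]
        # building populations sum to zone populations by construction, so
        # per-zone sums of building subgroup populations equal zone counts
        np.testing.assert_allclose(got.to_numpy(), wide.to_numpy(), atol=1e-9)

    def test_zero_population_zone_with_buildings_rejected(self):
        zt = simple_zone_table({0: 0.0})
        b = [ge.Building(id=0, x=0, y=0, population=5.0, zone_id=0)]
        with pytest.raises(DisaggregationError):
            ge.disaggregate(zt, b)


class TestWeightedMean:
    def test_single_building(self):
        assert ge.weighted_mean([15.30], [7.0]) == 15.30

    def test_hand_arithmetic(self):
        assert ge.weighted_mean([10.0, 20.0], [1.0, 3.0]) == pytest.approx(17.5)

    def test_zero_total_weight_rejected(self):
        with pytest.raises(UndefinedExposureError):
            ge.weighted_mean([1.0, 2.0], [0.0, 0.0])

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        values=st.lists(st.floats(-100, 100), min_size=1, max_size=20),
        seed=st.integers(0, 10_000),
        scale=st.floats(0.1, 50),
    )
    def test_bounded_and_scale_invariant(self, values, seed, scale):
        rng = np.random.default_rng(seed)
        weights = rng.random(len(values)) + 0.01
        wm = ge.weighted_mean(values, weights)
        assert min(values) - 1e-9 <= wm <= max(values) + 1e-9
        assert ge.weighted_mean(values, weights * scale) == pytest.approx(wm, rel=1e-9, abs=1e-9)

    def test_constant_values_give_the_constant(self):
        assert ge.weighted_mean([4.2] * 5, [1, 2, 3, 4, 5]) == pytest.approx(4.2)


class TestIncomeClasses:
    def test_five_equal_zones_one_per_quintile(self):
        zt = simple_zone_table(
            {z: 100.0 for z in range(5)}, incomes={0: 30.0, 1: 10.0, 2: 50.0, 3: 20.0, 4: 40.0}
        )
        b = [ge.Building(id=z, x=0, y=0, population=100.0, zone_id=z) for z in range(5)]
        cls = ge.income_classes(zt, b)
        assert cls[1] == "bottom quintile"  # lowest income
        assert cls[2] == "top quintile"  # highest income
        assert (cls == "middle quintiles").sum() == 3

    def test_tied_incomes_broken_by_zone_id(self):
        zt = simple_zone_table({z: 100.0 for z in range(5)}, incomes={z: 10.0 if z < 2 else 20.0 for z in range(5)})
        b = [ge.Building(id=z, x=0, y=0, population=100.0, zone_id=z) for z in range(5)]
        cls = ge.income_classes(zt, b)
        assert cls[0] == "bottom quintile"  # tie at 10.0 -> zone 0 first
        assert cls[1] == "middle quintiles"

    def test_cumulative_population_shares_near_quintiles(self):
        city = ge.generate_city(ge.CityConfig(seed=13, n_buildings=500, extent_m=6000.0))
        cls = ge.income_classes(city.zone_table, city.buildings)
        bframe = buildings_frame(city.buildings)
        pop = bframe.groupby("zone_id")["population"].sum().reindex(cls.index, fill_value=0.0)
        total = pop.sum()
        max_zone = pop.max()
        shares = pop.groupby(cls).sum() / total
        assert abs(shares.get("bottom quintile", 0) - 0.2) <= max_zone / total
        assert abs(shares.get("top quintile", 0) - 0.2) <= max_zone / total
        assert abs(shares.get("middle quintiles", 0) - 0.6) <= 2 * max_zone / total

    def test_identical_incomes_rejected(self):
        zt = simple_zone_table({z: 10.0 for z in range(5)}, incomes={z: 7.0 for z in range(5)})
        b = [ge.Building(id=z, x=0, y=0, population=10.0, zone_id=z) for z in range(5)]
        with pytest.raises(SingleClassError):
            ge.income_classes(zt, b)


class TestExposureTable:
    def test_uniform_surface_gives_identical_subgroup_exposures(self, small_city):
        grid = small_city.fine_pm25.grid
        flat = ge.ConcentrationRaster(grid, np.full(grid.shape, 9.5))
        surfaces = ge.ScenarioSurfaces(flat, flat, small_city.coarse_pm25, small_city.coarse_pm25)
        t = ge.exposure_table(
            small_city.buildings, small_city.zone_table, surfaces,
            small_city.landcover, small_city.landcover,
        )
        assert np.allclose(t.data["pm25_baseline"], 9.5, atol=1e-12)
        assert np.allclose(t.data["pm25_delta"], 0.0, atol=1e-12)

    def test_subgroup_present_at_one_building_samples_that_building(self):
        grid = ge.GridSpec(0.0, 2000.0, 1000.0, 2, 2)
        surface = ge.ConcentrationRaster(grid, np.array([[5.0, 6.0], [7.0, 8.0]]))
        surfaces = ge.ScenarioSurfaces(surface, surface, surface, surface)
        lc = ge.LandCoverRaster(
            ge.GridSpec(0.0, 2000.0, 5.0, 400, 400),
            np.full((400, 400), int(ge.LandClass.GRASS), dtype=np.uint8),
        )
        # employed people exist only in zone 1; everyone else is unemployed
        employment = {0: (10.0, 0.0), 1: (0.0, 20.0), 2: (10.0, 0.0), 3: (10.0, 0.0), 4: (10.0, 0.0)}
        records = []
        for zid, (unemp, emp) in employment.items():
            for category, subcats in CATEGORIES.items():
                if category == "employment":
                    shares = [unemp, emp]
                else:
                    shares = [(unemp + emp) / len(subcats)] * len(subcats)
                for s, share in zip(subcats, shares):
                    records.append({"zone_id": zid, "category": category, "subcategory": s, "count": share})
        zt = ge.ZoneTable(
            population=pd.Series({z: sum(employment[z]) for z in employment}),
            counts=pd.DataFrame.from_records(records),
            median_income=pd.Series({z: 100.0 + z for z in employment}),
        )
        # one building per zone; the employed subgroup lives only at building 1,
        # which sits in fine cell (1, 1) and therefore samples 8.0
        coords = [(250.0, 1750.0), (1750.0, 250.0), (250.0, 250.0), (750.0, 1750.0), (1250.0, 250.0)]
        buildings = [
            ge.Building(id=z, x=coords[z][0], y=coords[z][1], population=sum(employment[z]), zone_id=z)
            for z in employment
        ]
        t = ge.exposure_table(buildings, zt, surfaces, lc, lc)
        assert t.row("employment", "employed")["pm25_baseline"] == pytest.approx(8.0)
        assert t.row("employment", "employed")["pm25_scenario"] == pytest.approx(8.0)

    def test_partition_consistency_per_category(self, small_city, small_city_table):
        t = small_city_table.data
        total = small_city_table.row("total", "total")
        for category in list(CATEGORIES) + ["income"]:
            sub = t[t["category"] == category]
            for col in ["pm25_baseline", "pm25_scenario", "tree_ha_baseline"]:
                lhs = (sub["population"] * sub[col]).sum()
                rhs = total["population"] * total[col]
                assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_subgroup_populations_sum_to_total(self, small_city_table):
        t = small_city_table.data
        total_pop = small_city_table.row("total", "total")["population"]
        for category in list(CATEGORIES) + ["income"]:
            sub = t[t["category"] == category]
            assert sub["population"].sum() == pytest.approx(total_pop, rel=1e-9)

    def test_scaling_all_populations_leaves_weighted_means_unchanged(self, small_city, small_city_surfaces, small_city_table):
        c = 3.7
        zt = small_city.zone_table
        scaled_zt = ge.ZoneTable(
            population=zt.population * c,
            counts=zt.counts.assign(count=zt.counts["count"] * c),
            median_income=zt.median_income,
        )
        scaled_buildings = [
            ge.Building(id=b.id, x=b.x, y=b.y, population=b.population * c, zone_id=b.zone_id)
            for b in small_city.buildings
        ]
        t2 = ge.exposure_table(
            scaled_buildings, scaled_zt, small_city_surfaces,
            small_city.landcover, small_city.landcover,
        )
        for col in ["pm25_baseline", "pm25_scenario", "tree_ha_baseline", "tree_ha_scenario"]:
            np.testing.assert_allclose(
                t2.data[col].to_numpy(), small_city_table.data[col].to_numpy(), rtol=1e-9
            )

    def test_csv_roundtrip_and_display_rounding(self, tmp_path, small_city_table):
        path = tmp_path / "exposure.csv"
        small_city_table.to_csv(path)
        back = ge.ExposureTable.from_csv(path)
        np.testing.assert_allclose(
            back.data["pm25_baseline"].to_numpy(),
            small_city_table.data["pm25_baseline"].to_numpy(),
            atol=1e-12,
        )
        disp = small_city_table.display()
        assert (disp["pm25_baseline"].round(2) == disp["pm25_baseline"]).all()
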