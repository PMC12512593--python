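"""Equity-gap statistics over exposure tables, and planted-pattern recovery.

The central quantities are simple differences of population-weighted PM2.5
means: per category the subgroup *range* (max - min weighted concentration),
and for income the *top-vs-bottom quintile gap* at baseline and under the
greening scenario, with a direction flag saying whether greening widened or
narrowed the gap.  Values are carried at full precision and compared /
displayed after rounding to 2 decimals, the convention of published city
summary tables.

Published population-weighted exposure summaries for Aarhus and Paris ship
as fixture CSVs (see :func:`published_table`); they are reference outputs
for checking the gap arithmetic, not inputs to the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ReportError
from .exposure import CATEGORIES, INCOME_CLASSES, ExposureTable

#: display rounding used when comparing against printed tables
_DISPLAY_DECIMALS = 2


def published_table(city: str) -> ExposureTable:
    """Load the shipped published exposure summary for ``"aarhus"`` or ``"paris"``."""
    name = f"{city.lower()}_published_exposure.csv"
    ref = resources.files("greenequity.data") / name
    with resources.as_file(ref) as path:
        return ExposureTable(pd.read_csv(path))


@dataclass
class CategoryGap:
    """Spread of weighted PM2.5 across one category's subgroups."""

    baseline_range: float
    scenario_range: float
    most_benefited: str  # subgroup with the largest |delta PM2.5|
    least_benefited: str


@dataclass
class IncomeGap:
    """Top-vs-bottom income quintile difference in weighted PM2.5."""

    baseline_gap: float
    scenario_gap: float
    gap_change: float
    direction: str  # "widened" | "narrowed" | "unchanged" (after display rounding)


@dataclass
class GapReport:
    categories: dict[str, CategoryGap]
    income: IncomeGap

    def to_dict(self) -> dict:
        return {
            "categories": {
                k: {
                    "baseline_range": v.baseline_range,
                    "scenario_range": v.scenario_range,
                    "most_benefited": v.most_benefited,
                    "least_benefited": v.least_benefited,
                }
                for k, v in self.categories.items()
            },
            "income": {
                "baseline_gap": self.income.baseline_gap,
                "scenario_gap": self.income.scenario_gap,
                "gap_change": self.income.gap_change,
                "direction": self.income.direction,
            },
            "max_baseline_range": self.max_baseline_range,
        }

    @property
    def max_baseline_range(self) -> float:
        """Largest baseline subgroup variation across all categories."""
        return max(v.baseline_range for v in self.categories.values())


def _rounded(x: float) -> float:
    return float(np.round(x, _DISPLAY_DECIMALS))


def gaps(t: ExposureTable) -> GapReport:
    """Gap statistics of an exposure table.

    Per category the baseline/scenario subgroup ranges (max - min weighted
    PM2.5) and the most/least benefited subgroup by |delta|; for income the
    top-vs-bottom quintile gap per scenario and its change.  All values are
    reported after 2-decimal display rounding; the underlying table retains
    full precision.
    """
    df = t.data
    cats: dict[str, CategoryGap] = {}
    for category in list(CATEGORIES) + ["income"]:
        sub = df[df["category"] == category]
        if sub.empty:
            raise ReportError(f"exposure table has no rows for category {category!r}")
        base = sub["pm25_baseline"].round(_DISPLAY_DECIMALS)
        scen = sub["pm25_scenario"].round(_DISPLAY_DECIMALS)
        deltas = sub["pm25_delta"].abs()
        cats[category] = CategoryGap(
            baseline_range=_rounded(base.max() - base.min()),
            scenario_range=_rounded(scen.max() - scen.min()),
            most_benefited=str(sub.loc[deltas.idxmax(), "subcategory"]),
            least_benefited=str(sub.loc[deltas.idxmin(), "subcategory"]),
        )

    try:
        bottom = t.row("income", INCOME_CLASSES[0])
        top = t.row("income", INCOME_CLASSES[2])
    except ReportError as err:
        raise ReportError(f"income quintile rows missing: {err}") from err
    baseline_gap = _rounded(
        abs(round(top["pm25_baseline"], _DISPLAY_DECIMALS) - round(bottom["pm25_baseline"], _DISPLAY_DECIMALS))
    )
    scenario_gap = _rounded(
        abs(round(top["pm25_scenario"], _DISPLAY_DECIMALS) - round(bottom["pm25_scenario"], _DISPLAY_DECIMALS))
    )
    change = _rounded(scenario_gap - baseline_gap)
    direction = "unchanged" if change == 0 else ("widened" if change > 0 else "narrowed")
    income = IncomeGap(
        baseline_gap=baseline_gap,
        scenario_gap=scenario_gap,
        gap_change=change,
        direction=direction,
    )
    return GapReport(categories=cats, income=income)


def pattern_check(t: ExposureTable, truth: dict) -> dict[str, dict]:
    """Verify that planted synthetic gradients are recovered in the table.

    ``truth`` is the record attached to a generated city.  For a planted
    negative income-PM2.5 association (Paris-like: poorer zones breathe
    worse air) the bottom income quintile's baseline exposure must exceed
    the top quintile's; for a positive association (Aarhus-like) the
    reverse.  Analogously for the income-tree-cover association.  Returns
    one verdict per planted relationship with the achieved margin.
    """
    bottom = t.row("income", INCOME_CLASSES[0])
    top = t.row("income", INCOME_CLASSES[2])
    out: dict[str, dict] = {}

    sign = int(truth.get("income_pm25_corr_sign", 0))
    if sign != 0:
        # sign > 0: richer zones dirtier -> top exposure above bottom
        margin = float(sign * (top["pm25_baseline"] - bottom["pm25_baseline"]))
        expected = "top > bottom" if sign > 0 else "bottom > top"
        out["income_pm25"] = {"expected": expected, "passed": margin > 0, "margin": margin}

    sign = int(truth.get("income_tree_corr_sign", 0))
    if sign != 0:
        margin = float(sign * (top["tree_ha_baseline"] - bottom["tree_ha_baseline"]))
        expected = "top > bottom" if sign > 0 else "bottom > top"
        out["income_tree"] = {"expected": expected, "passed": margin > 0, "margin": margin}

    return out
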