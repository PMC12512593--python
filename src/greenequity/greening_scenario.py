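"""The '3' and '30' components of the 3-30-300 greening rule as a
deterministic land-cover editing algorithm.

The rule's first two targets, as implemented here, are:

* '3'  — every residential building has at least ``min_viewable_tree_cells``
  (default 2) tree raster cells within ``viewable_radius_m`` (default 30 m)
  of its location, the raster proxy for "three viewable trees";
* '30' — every neighbourhood (here: statistical zone) has at least
  ``neighbourhood_target`` (default 30%) of its cells under green/blue cover
  (tree canopy + water by default; grass is excluded but configurable).

The editor only ever converts *eligible* cells (grass, bare soil, sealed
mineral surface — never buildings or water) to tree canopy, so tree count is
monotone non-decreasing and the pass is idempotent.  Buildings are processed
in ascending id with candidate cells converted nearest-first (ties broken by
row then column); the zone pass prefers cells adjacent to existing canopy
(a simple contiguity heuristic) and uses the seed only to order otherwise
equal-priority candidates.  Units whose target cannot be met with the
eligible cells available are reported as infeasible, never raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError
from .exposure import Building
from .raster_core import LandClass, LandCoverRaster, cells_within
from .zones import Zone, zone_cell_mask


@dataclass
class GreeningParams:
    """Tunable parameters of the 3-30 scenario editor."""

    viewable_radius_m: float = 30.0
    min_viewable_tree_cells: int = 2
    neighbourhood_target: float = 0.30
    green_blue_codes: frozenset = field(
        default_factory=lambda: frozenset({int(LandClass.TREE), int(LandClass.WATER)})
    )
    eligible_codes: frozenset = field(
        default_factory=lambda: frozenset(
            {int(LandClass.GRASS), int(LandClass.BARE), int(LandClass.MINERAL)}
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.neighbourhood_target <= 1):
            raise ConfigurationError(
                f"neighbourhood_target must be in (0, 1], got {self.neighbourhood_target}"
            )
        if self.min_viewable_tree_cells < 1:
            raise ConfigurationError("min_viewable_tree_cells must be >= 1")
        forbidden = {int(LandClass.BUILDING), int(LandClass.WATER)} & set(self.eligible_codes)
        if forbidden:
            raise ConfigurationError(
                f"classes {sorted(forbidden)} may never be converted to trees"
            )


@dataclass
class GreeningResult:
    """Scenario land cover plus the audit trail of the edit."""

    landcover_scenario: LandCoverRaster
    #: one row per converted cell: row, col, prior_class, reason
    placements: pd.DataFrame
    #: units whose target could not be met: dicts {"kind": "building"|"zone", "id": ...}
    infeasible: list[dict]


def viewable_deficit(lc: LandCoverRaster, b: Building, p: GreeningParams) -> int:
    """How many more tree cells the building needs within viewing distance."""
    count, _ = cells_within(lc, b.x, b.y, p.viewable_radius_m, {int(LandClass.TREE)})
    return max(0, p.min_viewable_tree_cells - count)


def neighbourhood_fraction(lc: LandCoverRaster, zone: Zone, p: GreeningParams) -> float:
    """Fraction of zone-interior cells under green/blue cover."""
    mask, (r0, c0) = zone_cell_mask(zone, lc)
    window = lc.classes[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
    member = np.isin(window, list(p.green_blue_codes))
    return float(np.count_nonzero(member & mask) / np.count_nonzero(mask))


def _candidate_cells_near(
    lc: LandCoverRaster, x: float, y: float, radius_m: float, eligible: frozenset
) -> np.ndarray:
    """Eligible cells (row, col, dist2) with centers within radius, nearest first."""
    g = lc.grid
    res = g.res_m
    c0 = max(0, int(math.floor((x - radius_m - g.origin_x) / res - 0.5)))
    c1 = min(g.ncols - 1, int(math.ceil((x + radius_m - g.origin_x) / res - 0.5)))
    r0 = max(0, int(math.floor((g.origin_y - y - radius_m) / res - 0.5)))
    r1 = min(g.nrows - 1, int(math.ceil((g.origin_y - y + radius_m) / res - 0.5)))
    if c0 > c1 or r0 > r1:
        return np.empty((0, 2), dtype=int)
    xs = g.origin_x + (np.arange(c0, c1 + 1) + 0.5) * res
    ys = g.origin_y - (np.arange(r0, r1 + 1) + 0.5) * res
    d2 = (ys[:, None] - y) ** 2 + (xs[None, :] - x) ** 2
    inside = d2 <= radius_m * radius_m
    member = np.isin(lc.classes[r0 : r1 + 1, c0 : c1 + 1], list(eligible))
    rr, cc = np.nonzero(inside & member)
    if len(rr) == 0:
        return np.empty((0, 2), dtype=int)
    order = np.lexsort((cc, rr, d2[rr, cc]))
    return np.column_stack([rr[order] + r0, cc[order] + c0])


def apply_330(
    lc: LandCoverRaster,
    buildings: list[Building],
    zones: list[Zone],
    p: GreeningParams | None = None,
) -> GreeningResult:
    """Edit the land cover until both greening targets hold or are infeasible.

    Postconditions: tree cells are only ever added; after the pass every
    building has a zero viewable deficit or is flagged infeasible, and every
    zone reaches the neighbourhood target or is flagged infeasible; the
    output is a fixed point (re-applying changes nothing); deterministic for
    a fixed seed.
    """
    if p is None:
        p = GreeningParams()
    scenario = lc.copy()
    rng = np.random.default_rng(p.seed)
    placements: list[tuple[int, int, int, str]] = []
    infeasible: list[dict] = []

    # -- '3': viewable trees per building, ascending id ------------------
    for b in sorted(buildings, key=lambda b: b.id):
        deficit = viewable_deficit(scenario, b, p)
        if deficit == 0:
            continue
        cands = _candidate_cells_near(scenario, b.x, b.y, p.viewable_radius_m, p.eligible_codes)
        take = cands[:deficit]
        for r, c in take:
            placements.append((int(r), int(c), int(scenario.classes[r, c]), "viewable"))
            scenario.classes[r, c] = int(LandClass.TREE)
        if len(cands) < deficit:
            infeasible.append({"kind": "building", "id": b.id})

    # -- '30': neighbourhood green/blue cover per zone, ascending id ------
    tree_adjacent = ndimage.binary_dilation(
        scenario.classes == int(LandClass.TREE), structure=np.ones((3, 3), dtype=bool)
    )
    for zone in sorted(zones, key=lambda z: z.zone_id):
        mask, (r0, c0) = zone_cell_mask(zone, scenario)
        window = scenario.classes[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
        n_cells = int(np.count_nonzero(mask))
        current = int(np.count_nonzero(np.isin(window, list(p.green_blue_codes)) & mask))
        needed = math.ceil(p.neighbourhood_target * n_cells - 1e-9)
        shortfall = needed - current
        if shortfall <= 0:
            continue
        elig = np.isin(window, list(p.eligible_codes)) & mask
        rr, cc = np.nonzero(elig)
        # adjacency-to-canopy first; the seed orders within each priority class
        priority = (~tree_adjacent[rr + r0, cc + c0]).astype(int)
        perm = rng.permutation(len(rr))
        order = np.lexsort((perm, priority))
        take = order[:shortfall]
        take_r = rr[take] + r0
        take_c = cc[take] + c0
        prior = scenario.classes[take_r, take_c]
        placements.extend(
            (int(r), int(c), int(pc), "neighbourhood")
            for r, c, pc in zip(take_r, take_c, prior)
        )
        scenario.classes[take_r, take_c] = int(LandClass.TREE)
        if len(rr) < shortfall:
            infeasible.append({"kind": "zone", "id": zone.zone_id})

    placements_df = pd.DataFrame(placements, columns=["row", "col", "prior_class", "reason"])
    return GreeningResult(
        landcover_scenario=scenario, placements=placements_df, infeasible=infeasible
    )
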