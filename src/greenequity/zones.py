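"""Statistical zones: the areal units socio-demographic data are published on.

Zones play the role of IRIS units (France) or districts (Denmark): polygons
that tile the city, each carrying a population table and a single median
income.  The synthetic generator tessellates the square domain into a regular
grid of rectangles, which keeps point-in-zone assignment exact and trivially
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon, box

from .errors import ZoneCoverageError
from .raster_core import LandCoverRaster


@dataclass
class Zone:
    """One statistical zone: an id and its polygon footprint."""

    zone_id: int
    polygon: Polygon

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)


def tessellate(extent_m: float, n_zones: int) -> list[Zone]:
    """Tile the square [0, extent] x [0, extent] domain into ``n_zones`` rectangles.

    The grid is ``nrows x ncols`` with ``nrows`` the largest divisor of
    ``n_zones`` not exceeding its square root (a prime count degenerates to
    strips, which is still a valid tessellation).  Zone ids run row-major
    from the top-left.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    nrows = max(d for d in range(1, int(np.sqrt(n_zones)) + 1) if n_zones % d == 0)
    ncols = n_zones // nrows
    w = extent_m / ncols
    h = extent_m / nrows
    out: list[Zone] = []
    for i in range(nrows):
        for j in range(ncols):
            top = extent_m - i * h
            poly = box(j * w, top - h, (j + 1) * w, top)
            out.append(Zone(zone_id=i * ncols + j, polygon=poly))
    return out


def zone_of_point(zones: list[Zone], extent_m: float, x: float, y: float) -> int:
    """Zone id containing (x, y) for a regular tessellation (half-open cells)."""
    n_zones = len(zones)
    nrows = max(d for d in range(1, int(np.sqrt(n_zones)) + 1) if n_zones % d == 0)
    ncols = n_zones // nrows
    w = extent_m / ncols
    h = extent_m / nrows
    j = min(int(x // w), ncols - 1)
    i = min(int((extent_m - y) // h), nrows - 1)
    return i * ncols + j


def zone_cell_mask(zone: Zone, lc: LandCoverRaster) -> tuple[np.ndarray, tuple[int, int]]:
    """Boolean mask of land-cover cells whose centers lie inside the zone.

    Returns (mask, (row_offset, col_offset)) where the mask covers only the
    window of the raster overlapping the zone's bounding box.  Membership is
    strict interior containment of the cell center; zone boundaries aligned
    to cell edges therefore never double-count a cell.
    """
    g = zone.polygon.bounds  # (minx, miny, maxx, maxy)
    grid = lc.grid
    res = grid.res_m
    c0 = max(0, int(np.floor((g[0] - grid.origin_x) / res)))
    c1 = min(grid.ncols - 1, int(np.ceil((g[2] - grid.origin_x) / res)))
    r0 = max(0, int(np.floor((grid.origin_y - g[3]) / res)))
    r1 = min(grid.nrows - 1, int(np.ceil((grid.origin_y - g[1]) / res)))
    if c0 > c1 or r0 > r1:
        raise ZoneCoverageError(f"zone {zone.zone_id} does not overlap the raster")
    xs = grid.origin_x + (np.arange(c0, c1 + 1) + 0.5) * res
    ys = grid.origin_y - (np.arange(r0, r1 + 1) + 0.5) * res
    xx, yy = np.meshgrid(xs, ys)
    mask = shapely.contains_xy(zone.polygon, xx.ravel(), yy.ravel()).reshape(xx.shape)
    if not mask.any():
        raise ZoneCoverageError(f"zone {zone.zone_id} contains no cell centers")
    return mask, (r0, c0)
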