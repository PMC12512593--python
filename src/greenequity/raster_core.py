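"""Planar grid algebra shared by every pipeline stage.

All rasters live in a single planar metric CRS (coordinates in metres); there
is no geodesy anywhere in the package.  Grids are north-up and row-major with
row 0 at the top.  Cell (r, c) covers the half-open box

    x in [origin_x + c*res, origin_x + (c+1)*res)
    y in (origin_y - (r+1)*res, origin_y - r*res]

so a point exactly on an interior vertical edge belongs to the cell on the
right, and a point on a horizontal edge to the cell below's upper neighbour's
lower side — i.e. the cell whose half-open interval contains it.  These
conventions are load-bearing: point sampling, buffer queries and resampling
all assume them, and the tests pin them down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable

import numpy as np

from .errors import GridAlignmentError, SamplingError


class LandClass(IntEnum):
    """Land-cover class codes used in categorical rasters (band value)."""

    TREE = 1
    GRASS = 2
    WATER = 3
    BUILDING = 4
    MINERAL = 5
    BARE = 6


#: every code a land-cover raster may legally contain
KNOWN_CLASSES = frozenset(int(c) for c in LandClass)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid.

    ``origin_x, origin_y`` are the coordinates of the *outer* (top-left)
    corner of cell (0, 0); ``res_m`` is the square cell size in metres.
    """

    origin_x: float
    origin_y: float
    res_m: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.res_m <= 0:
            raise ValueError(f"res_m must be > 0, got {self.res_m}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError(f"grid must have >= 1 row and column, got {self.nrows}x{self.ncols}")

    # -- extent ----------------------------------------------------------
    @property
    def xmin(self) -> float:
        return self.origin_x

    @property
    def xmax(self) -> float:
        return self.origin_x + self.ncols * self.res_m

    @property
    def ymax(self) -> float:
        return self.origin_y

    @property
    def ymin(self) -> float:
        return self.origin_y - self.nrows * self.res_m

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    # -- point <-> cell --------------------------------------------------
    def contains(self, x: float, y: float) -> bool:
        """True if (x, y) lies in some cell (half-open convention)."""
        return (self.xmin <= x < self.xmax) and (self.ymin < y <= self.ymax)

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell containing (x, y).

        Raises :class:`SamplingError` if the point is outside the extent.
        """
        if not self.contains(x, y):
            raise SamplingError(
                f"point ({x}, {y}) outside raster extent "
                f"[{self.xmin}, {self.xmax}) x ({self.ymin}, {self.ymax}]"
            )
        c = int(math.floor((x - self.origin_x) / self.res_m))
        t = (self.origin_y - y) / self.res_m
        r = int(math.floor(t))
        # y on the top edge of row r maps to r exactly; guard float edge cases
        if r == self.nrows:
            r -= 1
        if c == self.ncols:
            c -= 1
        return r, c

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.ncols) + 0.5) * self.res_m

    def y_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.nrows) + 0.5) * self.res_m

    def cell_center(self, r: int, c: int) -> tuple[float, float]:
        return (
            self.origin_x + (c + 0.5) * self.res_m,
            self.origin_y - (r + 0.5) * self.res_m,
        )


@dataclass
class LandCoverRaster:
    """Categorical 5 m land-cover grid (codes from :class:`LandClass`)."""

    grid: GridSpec
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.shape != self.grid.shape:
            raise ValueError(
                f"class array shape {self.classes.shape} != grid shape {self.grid.shape}"
            )
        unknown = set(np.unique(self.classes)) - KNOWN_CLASSES
        if unknown:
            raise ValueError(f"unknown land-cover codes: {sorted(unknown)}")

    def copy(self) -> "LandCoverRaster":
        return LandCoverRaster(self.grid, self.classes.copy())

    def class_mask(self, codes: Iterable[int]) -> np.ndarray:
        codes = list(codes)
        return np.isin(self.classes, codes)


@dataclass
class ConcentrationRaster:
    """PM2.5 field on a grid (ug m-3).

    ``role`` distinguishes baseline concentration fields (values must be
    finite and >= 0) from delta fields (differences; may be negative).
    """

    grid: GridSpec
    values: np.ndarray
    role: str = "baseline"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.role not in ("baseline", "delta"):
            raise ValueError(f"role must be 'baseline' or 'delta', got {self.role!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("concentration raster contains non-finite values")
        if self.role == "baseline" and np.any(self.values < 0):
            raise ValueError("baseline concentration raster contains negative values")

    def copy(self) -> "ConcentrationRaster":
        return ConcentrationRaster(self.grid, self.values.copy(), self.role)


# ---------------------------------------------------------------------------
# nesting / alignment helpers
# ---------------------------------------------------------------------------

def _is_integer(x: float, tol: float = 1e-9) -> bool:
    return abs(x - round(x)) <= tol


def require_nesting(fine: GridSpec, coarse: GridSpec) -> tuple[int, int, int]:
    """Check that ``coarse`` cells exactly tile groups of ``fine`` cells.

    Returns (factor, row_offset, col_offset): each coarse cell covers a
    ``factor x factor`` block of fine cells, with the coarse origin located
    ``row_offset/col_offset`` fine cells into the fine grid.
    """
    ratio = coarse.res_m / fine.res_m
    if not _is_integer(ratio) or ratio < 1:
        raise GridAlignmentError(
            f"coarse resolution {coarse.res_m} is not an integer multiple "
            f"of fine resolution {fine.res_m}"
        )
    factor = int(round(ratio))
    dc = (coarse.origin_x - fine.origin_x) / fine.res_m
    dr = (fine.origin_y - coarse.origin_y) / fine.res_m
    if not (_is_integer(dc) and _is_integer(dr)):
        raise GridAlignmentError("coarse grid origin does not sit on a fine cell corner")
    col_off, row_off = int(round(dc)), int(round(dr))
    if col_off < 0 or row_off < 0:
        raise GridAlignmentError("coarse grid extends beyond the fine grid origin")
    if row_off + coarse.nrows * factor > fine.nrows or col_off + coarse.ncols * factor > fine.ncols:
        raise GridAlignmentError("coarse grid extends beyond the fine grid extent")
    return factor, row_off, col_off


def require_aligned(a: GridSpec, b: GridSpec) -> None:
    """Check two grids are identical (same origin, resolution, shape)."""
    same = (
        math.isclose(a.origin_x, b.origin_x, abs_tol=1e-9)
        and math.isclose(a.origin_y, b.origin_y, abs_tol=1e-9)
        and math.isclose(a.res_m, b.res_m, abs_tol=1e-9)
        and a.shape == b.shape
    )
    if not same:
        raise GridAlignmentError(f"grids are not aligned: {a} vs {b}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def class_fraction(
    lc: LandCoverRaster, target: GridSpec, codes: Iterable[int]
) -> np.ndarray:
    """Fraction of each target cell covered by the given land-cover codes.

    The target grid must exactly tile groups of land-cover cells (resolution
    nesting); each target cell's value is the count of member cells with a
    code in ``codes`` divided by the cells per target cell, hence in [0, 1].
    """
    factor, row_off, col_off = require_nesting(lc.grid, target)
    mask = lc.class_mask(codes).astype(np.float64)
    window = mask[
        row_off : row_off + target.nrows * factor,
        col_off : col_off + target.ncols * factor,
    ]
    blocks = window.reshape(target.nrows, factor, target.ncols, factor)
    return blocks.mean(axis=(1, 3))


def cells_within(
    lc: LandCoverRaster,
    x: float,
    y: float,
    radius_m: float,
    codes: Iterable[int],
) -> tuple[int, float]:
    """Count raster cells of the given classes within a radius of a point.

    A cell is counted when its *center* lies within Euclidean distance
    ``radius_m`` (inclusive) of (x, y); the returned area is
    ``count * res**2`` in m2.  Cells outside the raster extent contribute
    nothing, so a point outside the raster simply returns (0, 0.0).
    """
    if radius_m <= 0:
        raise ValueError(f"radius_m must be > 0, got {radius_m}")
    g = lc.grid
    res = g.res_m
    # conservative window of candidate columns/rows (centers within radius)
    c0 = max(0, int(math.floor((x - radius_m - g.origin_x) / res - 0.5)))
    c1 = min(g.ncols - 1, int(math.ceil((x + radius_m - g.origin_x) / res - 0.5)))
    r0 = max(0, int(math.floor((g.origin_y - y - radius_m) / res - 0.5)))
    r1 = min(g.nrows - 1, int(math.ceil((g.origin_y - y + radius_m) / res - 0.5)))
    if c0 > c1 or r0 > r1:
        return 0, 0.0
    xs = g.origin_x + (np.arange(c0, c1 + 1) + 0.5) * res
    ys = g.origin_y - (np.arange(r0, r1 + 1) + 0.5) * res
    d2 = (ys[:, None] - y) ** 2 + (xs[None, :] - x) ** 2
    inside = d2 <= radius_m * radius_m
    member = np.isin(lc.classes[r0 : r1 + 1, c0 : c1 + 1], list(codes))
    count = int(np.count_nonzero(inside & member))
    return count, count * res * res


def sample_at(r: ConcentrationRaster, x: float, y: float) -> float:
    """Value of the cell containing (x, y); no interpolation."""
    row, col = r.grid.cell_index(x, y)
    return float(r.values[row, col])


def sample_many(r: ConcentrationRaster, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Vectorised :func:`sample_at` over arrays of coordinates."""
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    g = r.grid
    ok = (xs >= g.xmin) & (xs < g.xmax) & (ys > g.ymin) & (ys <= g.ymax)
    if not np.all(ok):
        bad = np.argwhere(~ok)[0][0]
        raise SamplingError(f"point ({xs.flat[bad]}, {ys.flat[bad]}) outside raster extent")
    cols = np.floor((xs - g.origin_x) / g.res_m).astype(np.int64)
    rows = np.floor((g.origin_y - ys) / g.res_m).astype(np.int64)
    rows = np.clip(rows, 0, g.nrows - 1)
    cols = np.clip(cols, 0, g.ncols - 1)
    return r.values[rows, cols]


def bilinear_resample(src: ConcentrationRaster, target: GridSpec) -> ConcentrationRaster:
    """Bilinearly interpolate a raster's cell-center lattice onto a new grid.

    Each target cell center receives the bilinear interpolation of the four
    surrounding source cell-center values.  Outside the source center lattice
    the field is clamped to the nearest edge/corner value (constant
    extrapolation); constant fields are therefore preserved exactly.
    """
    if target.nrows < 1 or target.ncols < 1:
        raise ValueError("empty target grid")
    g = src.grid
    # fractional index of target centers into the source center lattice
    fx = (target.x_centers() - (g.origin_x + 0.5 * g.res_m)) / g.res_m
    fy = ((g.origin_y - 0.5 * g.res_m) - target.y_centers()) / g.res_m
    fx = np.clip(fx, 0.0, g.ncols - 1.0)
    fy = np.clip(fy, 0.0, g.nrows - 1.0)
    c0 = np.clip(np.floor(fx).astype(np.int64), 0, g.ncols - 2) if g.ncols > 1 else np.zeros_like(fx, dtype=np.int64)
    r0 = np.clip(np.floor(fy).astype(np.int64), 0, g.nrows - 2) if g.nrows > 1 else np.zeros_like(fy, dtype=np.int64)
    wx = fx - c0
    wy = fy - r0
    v = src.values
    if g.ncols > 1:
        c1 = c0 + 1
    else:
        c1, wx = c0, np.zeros_like(wx)
    if g.nrows > 1:
        r1 = r0 + 1
    else:
        r1, wy = r0, np.zeros_like(wy)
    # two 1-D lerps; exact for constant fields (increments vanish)
    v00 = v[np.ix_(r0, c0)]
    v01 = v[np.ix_(r0, c1)]
    v10 = v[np.ix_(r1, c0)]
    v11 = v[np.ix_(r1, c1)]
    top = v00 + wx[None, :] * (v01 - v00)
    bot = v10 + wx[None, :] * (v11 - v10)
    out = top + wy[:, None] * (bot - top)
    return ConcentrationRaster(target, out, role=src.role)
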