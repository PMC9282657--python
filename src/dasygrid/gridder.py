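"""Mass-conserving rasterization of populated target zones.

A target zone carries, for each population variable, a uniform density in
people/m2 (its parent zone's count divided by the target's area).  Gridding
multiplies that density by the *exact* area of intersection between the
target geometry and every raster cell it touches, so the sum over all pixels
equals the sum of the input populations up to floating-point rounding — no
centroid shortcuts, no supersampling.

Pixel convention: "people per pixel" values on a north-up regular grid,
row 0 at the top.  Cells are half-open, [x, x+r) horizontally and (y-r, y]
vertically from the top-left grid origin, so a boundary shared by two cells
belongs to exactly one of them.  Exact-area clipping makes this convention
matter only for measure-zero edges.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

__all__ = [
    "GridExtentError",
    "GridSpec",
    "PopulationGrid",
    "assign_density",
    "rasterize",
    "uniform_grid",
    "zone_targets",
    "aggregate_grid",
    "diff_grids",
]

_REL_TOL = 1e-9


class GridExtentError(ValueError):
    """Geometry falls outside the grid extent, or grids are misaligned."""


@dataclass(frozen=True)
class GridSpec:
    """Georeferencing of a regular, north-up raster in a projected meter CRS.

    ``origin_x``/``origin_y`` are the coordinates of the *top-left corner* and
    are required to be integer multiples of ``resolution``, so independently
    produced grids of the same resolution always share cell boundaries.
    """

    crs: str
    origin_x: float
    origin_y: float
    resolution: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have at least one row and column")
        for name, value in (("origin_x", self.origin_x), ("origin_y", self.origin_y)):
            ratio = value / self.resolution
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"{name}={value} is not an integer multiple of the "
                    f"resolution ({self.resolution})"
                )

    @classmethod
    def from_bounds(
        cls,
        bounds: tuple[float, float, float, float],
        resolution: float,
        crs: str,
    ) -> "GridSpec":
        """Smallest snapped grid covering ``bounds`` = (minx, miny, maxx, maxy)."""
        minx, miny, maxx, maxy = bounds
        if maxx <= minx or maxy <= miny:
            raise ValueError("bounds must have positive extent")
        origin_x = math.floor(minx / resolution) * resolution
        origin_y = math.ceil(maxy / resolution) * resolution
        n_cols = max(1, math.ceil((maxx - origin_x) / resolution - 1e-12))
        n_rows = max(1, math.ceil((origin_y - miny) / resolution - 1e-12))
        return cls(crs, origin_x, origin_y, resolution, n_rows, n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.resolution,
            self.origin_x + self.n_cols * self.resolution,
            self.origin_y,
        )

    @property
    def cell_area(self) -> float:
        return self.resolution * self.resolution

    def cell_polygon(self, row: int, col: int) -> BaseGeometry:
        x0 = self.origin_x + col * self.resolution
        y1 = self.origin_y - row * self.resolution
        return box(x0, y1 - self.resolution, x0 + self.resolution, y1)


@dataclass
class PopulationGrid:
    """People-per-pixel raster for one variable (float64 in memory)."""

    spec: GridSpec
    variable: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match spec "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("grid values must be finite")

    @property
    def total(self) -> float:
        """Total people in the grid."""
        return float(self.values.sum())


def assign_density(zone, target):
    """Fill a target zone's per-variable density from its parent zone.

    density_v = pop_v / target_area, so density_v * area reproduces the zone
    count exactly; this is where the mass-conservation guarantee is anchored.
    """
    area = target.area_m2
    if area <= 0:
        raise ValueError(f"target for zone {zone.zone_id} has zero area")
    target.density = {v: p / area for v, p in zone.pop.items()}
    return target


def _is_axis_rectangle(geom: BaseGeometry, bounds) -> bool:
    # Area equal to the bounding-box area implies the geometry fills its box
    # up to measure zero, which is all that exact-area clipping can see.
    minx, miny, maxx, maxy = bounds
    bbox_area = (maxx - minx) * (maxy - miny)
    return bbox_area > 0 and abs(geom.area - bbox_area) <= 1e-12 * bbox_area


def _cell_cover(geom: BaseGeometry, spec: GridSpec):
    """(rows, cols, areas) of exact intersection between ``geom`` and cells."""
    minx, miny, maxx, maxy = geom.bounds
    gminx, gminy, gmaxx, gmaxy = spec.bounds
    tol = _REL_TOL * max(spec.resolution, 1.0)
    if minx < gminx - tol or miny < gminy - tol or maxx > gmaxx + tol or maxy > gmaxy + tol:
        raise GridExtentError(
            f"geometry bounds {geom.bounds} extend outside grid extent {spec.bounds}"
        )
    res = spec.resolution
    c0 = max(0, int(math.floor((minx - spec.origin_x) / res)))
    c1 = min(spec.n_cols - 1, int(math.ceil((maxx - spec.origin_x) / res)) - 1)
    r0 = max(0, int(math.floor((spec.origin_y - maxy) / res)))
    r1 = min(spec.n_rows - 1, int(math.ceil((spec.origin_y - miny) / res)) - 1)
    if c1 < c0 or r1 < r0:
        return np.empty(0, int), np.empty(0, int), np.empty(0)

    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    x_left = spec.origin_x + cols * res
    y_top = spec.origin_y - rows * res

    if _is_axis_rectangle(geom, (minx, miny, maxx, maxy)):
        # Exact analytic overlap for axis-aligned rectangles (the common case
        # for enumeration zones, parcels and buildings built from boxes).
        wx = np.clip(np.minimum(maxx, x_left + res) - np.maximum(minx, x_left), 0, None)
        wy = np.clip(np.minimum(maxy, y_top) - np.maximum(miny, y_top - res), 0, None)
        areas = np.outer(wy, wx)
        rr, cc = np.nonzero(areas > 0)
        return rows[rr], cols[cc], areas[rr, cc]

    shapely.prepare(geom)
    out_rows: list[int] = []
    out_cols: list[int] = []
    out_areas: list[float] = []
    cell_area = spec.cell_area
    for ri, r in enumerate(rows):
        yt = y_top[ri]
        for ci, c in enumerate(cols):
            cell = box(x_left[ci], yt - res, x_left[ci] + res, yt)
            if shapely.contains_properly(geom, cell):
                a = cell_area
            elif shapely.intersects(geom, cell):
                a = geom.intersection(cell).area
            else:
                continue
            if a > 0:
                out_rows.append(r)
                out_cols.append(c)
                out_areas.append(a)
    return np.asarray(out_rows, int), np.asarray(out_cols, int), np.asarray(out_areas)


def rasterize(
    targets: Iterable,
    spec: GridSpec,
    variables: Sequence[str] | None = None,
) -> dict[str, PopulationGrid]:
    """Rasterize density-carrying targets to one people-per-pixel grid per variable.

    Each target needs ``geometry`` and a ``density`` mapping (people/m2).
    Overlapping targets sum; pixels touched by no target stay 0.  Accumulation
    is float64 throughout.
    """
    targets = list(targets)
    if variables is None:
        variables = sorted({v for t in targets for v in t.density})
    arrays = {v: np.zeros((spec.n_rows, spec.n_cols)) for v in variables}
    for t in targets:
        rows, cols, areas = _cell_cover(t.geometry, spec)
        if rows.size == 0:
            continue
        for v in variables:
            d = t.density.get(v, 0.0)
            if d:
                arrays[v][rows, cols] += d * areas
    return {v: PopulationGrid(spec, v, arr) for v, arr in arrays.items()}


@dataclass
class _UniformTarget:
    geometry: BaseGeometry
    density: dict[str, float]

    @property
    def area_m2(self) -> float:
        return self.geometry.area


def zone_targets(zones: Iterable) -> list[_UniformTarget]:
    """Each source zone as its own uniform-density target (areal weighting)."""
    out = []
    for z in zones:
        area = z.geometry.area
        if area <= 0:
            raise ValueError(f"zone {z.zone_id} has zero area")
        out.append(_UniformTarget(z.geometry, {v: p / area for v, p in z.pop.items()}))
    return out


def uniform_grid(
    zones: Iterable,
    spec: GridSpec,
    variables: Sequence[str] | None = None,
) -> dict[str, PopulationGrid]:
    """Uniform areal-weighting baseline: population spread over whole zones."""
    return rasterize(zone_targets(zones), spec, variables)


def aggregate_grid(grid: PopulationGrid, out_resolution: float) -> PopulationGrid:
    """Block-aggregate a people-per-pixel grid to a coarser resolution.

    Implemented as a block *sum* of people per pixel, which is algebraically
    identical to the convert-to-density / average / convert-back recipe:
    mean(v / r^2) * (k r)^2 = sum(v) over each k-by-k block.  Total mass is
    therefore preserved exactly.  The extent must tile evenly.
    """
    res = grid.spec.resolution
    ratio = out_resolution / res
    factor = round(ratio)
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise GridExtentError(
            f"output resolution {out_resolution} is not an integer multiple "
            f"of the grid resolution {res}"
        )
    if factor == 1:
        return PopulationGrid(grid.spec, grid.variable, grid.values.copy())
    n_rows, n_cols = grid.values.shape
    if n_rows % factor or n_cols % factor:
        raise GridExtentError(
            f"grid shape {(n_rows, n_cols)} does not tile evenly into "
            f"{factor}x{factor} blocks"
        )
    blocks = grid.values.reshape(n_rows // factor, factor, n_cols // factor, factor)
    out = blocks.sum(axis=(1, 3))
    spec = GridSpec(
        grid.spec.crs,
        grid.spec.origin_x,
        grid.spec.origin_y,
        out_resolution,
        n_rows // factor,
        n_cols // factor,
    )
    return PopulationGrid(spec, grid.variable, out)


def diff_grids(
    a: PopulationGrid, b: PopulationGrid, out_resolution: float | None = None
) -> PopulationGrid:
    """Difference a - b after bringing both grids to a common resolution.

    Both inputs are aggregated (density-average, mass-preserving) to
    ``out_resolution`` and subtracted; the result is signed people per pixel.
    """
    if a.spec.crs != b.spec.crs:
        raise GridExtentError(f"CRS mismatch: {a.spec.crs!r} vs {b.spec.crs!r}")
    if out_resolution is None:
        out_resolution = max(a.spec.resolution, b.spec.resolution)
    ra = aggregate_grid(a, out_resolution)
    rb = aggregate_grid(b, out_resolution)
    if (ra.spec.origin_x, ra.spec.origin_y) != (rb.spec.origin_x, rb.spec.origin_y):
        raise GridExtentError("grid origins do not align")
    if ra.values.shape != rb.values.shape:
        raise GridExtentError(
            f"aggregated shapes differ: {ra.values.shape} vs {rb.values.shape}"
        )
    return PopulationGrid(ra.spec, f"{a.variable}_minus_{b.variable}", ra.values - rb.values)
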