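"""Raster surfaces: IDW gridding, DEM/CHM construction, bilinear sampling.

All gridding is inverse-distance-weighted (power 2, 12 neighbours by
default).  The DEM builder detrends by the least-squares ground plane
before interpolating so that sloped terrain is reproduced without the
edge and occlusion-gap bias plain IDW has on inclines; the interpolated
quantity is then the residual relief, which is what IDW handles well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import PointCloud, RasterGrid, GROUND

COINCIDENT = 1e-9


@dataclass
class IDWParams:
    """Inverse-distance weighting parameters.

    max_radius defaults to 10 cell widths when left as None.
    """

    power: float = 2.0
    neighbors: int = 12
    max_radius: float | None = None

    def __post_init__(self):
        if self.power <= 0:
            raise ValueError("power must be positive")
        if self.neighbors < 1:
            raise ValueError("neighbors must be >= 1")

    def radius_for(self, cell: float) -> float:
        return self.max_radius if self.max_radius is not None else 10.0 * cell


def grid_for_bounds(bounds, cell: float, pad_cells: int = 1) -> RasterGrid:
    """Empty (NaN) grid covering ``(xmin, ymin, xmax, ymax)`` with the
    lower-left cell centre at ``xmin - pad_cells*cell``."""
    xmin, ymin, xmax, ymax = bounds
    x0 = xmin - pad_cells * cell
    y0 = ymin - pad_cells * cell
    ncols = int(np.ceil((xmax - x0) / cell)) + 1 + pad_cells
    nrows = int(np.ceil((ymax - y0) / cell)) + 1 + pad_cells
    return RasterGrid((x0, y0), cell, np.full((nrows, ncols), np.nan))


def _idw_at(xy_query: np.ndarray, xy_src: np.ndarray, z_src: np.ndarray,
            params: IDWParams, radius: float) -> np.ndarray:
    """IDW estimate at arbitrary query locations (NaN where no neighbour)."""
    tree = cKDTree(xy_src)
    k = min(params.neighbors, len(z_src))
    dist, idx = tree.query(xy_query, k=k, distance_upper_bound=radius)
    dist = np.atleast_2d(dist.reshape(len(xy_query), k))
    idx = np.atleast_2d(idx.reshape(len(xy_query), k))
    valid = np.isfinite(dist)
    idx_safe = np.where(valid, idx, 0)
    zn = z_src[idx_safe]
    out = np.full(len(xy_query), np.nan)

    coincident = valid & (dist < COINCIDENT)
    has_coincident = coincident.any(axis=1)
    if has_coincident.any():
        first = np.argmax(coincident, axis=1)
        out[has_coincident] = zn[np.arange(len(xy_query)), first][has_coincident]

    rest = ~has_coincident & valid.any(axis=1)
    if rest.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(valid, dist, np.inf) ** (-params.power)
            w[~valid] = 0.0
            out[rest] = (w * zn).sum(axis=1)[rest] / w.sum(axis=1)[rest]
    return out


def idw_interpolate(points: PointCloud | tuple, target: RasterGrid,
                    params: IDWParams | None = None) -> RasterGrid:
    """IDW-grid point elevations onto the geometry of ``target``.

    ``points`` is either a PointCloud (its z is gridded) or an
    ``(x, y, values)`` triple.  A cell coincident with a point takes that
    point's value; cells with no neighbour within the search radius are
    nodata.
    """
    params = params or IDWParams()
    if isinstance(points, PointCloud):
        xy, z = points.xy, points.z
    else:
        x, y, z = points
        xy = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
        z = np.asarray(z, float)
    if len(z) == 0:
        raise ValueError("no input points to interpolate")
    xs, ys = target.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    q = np.column_stack([gx.ravel(), gy.ravel()])
    vals = _idw_at(q, xy, z, params, params.radius_for(target.cell))
    return target.copy_with(vals.reshape(target.nrows, target.ncols))


def _fit_plane(x, y, z):
    """Least-squares plane z = a*x + b*y + c through the points."""
    A = np.column_stack([x, y, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    return coef


def build_dem(cloud: PointCloud, cell: float = 0.3,
              params: IDWParams | None = None) -> RasterGrid:
    """Bare-earth DEM from the ground-classified returns.

    Detrends by the best-fit ground plane, IDW-interpolates the residual
    relief, and restores the plane at cell centres; exact on planar
    terrain regardless of canopy occlusion gaps.  Extent is the cloud's
    bounding box padded by one cell.  The default search radius is 15 m
    (not the generic 10-cell default) so interpolation spans the ground
    gap occluded by even the largest crowns.
    """
    params = params or IDWParams(max_radius=15.0)
    mask = cloud.classification == GROUND
    if not mask.any():
        raise ValueError("cloud contains no ground-classified points")
    g = cloud.subset(mask)
    grid = grid_for_bounds(cloud.bounds(), cell)
    a, b, c = _fit_plane(g.x, g.y, g.z)
    resid = g.z - (a * g.x + b * g.y + c)
    out = idw_interpolate((g.x, g.y, resid), grid, params)
    xs, ys = out.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    return out.copy_with(out.values + a * gx + b * gy + c)


def build_dsm(cloud: PointCloud, cell: float = 0.3,
              params: IDWParams | None = None) -> RasterGrid:
    """Top-of-canopy surface from all first returns (plain IDW)."""
    first = cloud.subset(cloud.return_number == 1)
    grid = grid_for_bounds(cloud.bounds(), cell)
    return idw_interpolate(first, grid, params)


def sample_surface(grid: RasterGrid, x, y) -> np.ndarray:
    """Bilinear surface value at (x, y) from the four surrounding cell
    centres; nodata corners are dropped from the weighting, a fully
    nodata neighbourhood or a location outside the grid extent raises."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    scalar = x.size == 1
    x0, y0 = grid.origin
    gx = (x - x0) / grid.cell
    gy = (y - y0) / grid.cell
    # allow up to half a cell beyond the outer centres (the cell's support)
    if np.any(gx < -0.5) or np.any(gx > grid.ncols - 0.5) \
            or np.any(gy < -0.5) or np.any(gy > grid.nrows - 0.5):
        bad = np.where((gx < -0.5) | (gx > grid.ncols - 0.5)
                       | (gy < -0.5) | (gy > grid.nrows - 0.5))[0]
        raise ValueError(f"{bad.size} locations outside grid extent "
                         f"(first index {bad[0]})")
    gx = np.clip(gx, 0, grid.ncols - 1)
    gy = np.clip(gy, 0, grid.nrows - 1)
    c0 = np.clip(np.floor(gx).astype(int), 0, grid.ncols - 2) \
        if grid.ncols > 1 else np.zeros(x.size, int)
    r0 = np.clip(np.floor(gy).astype(int), 0, grid.nrows - 2) \
        if grid.nrows > 1 else np.zeros(x.size, int)
    fx = gx - c0
    fy = gy - r0
    c1 = np.minimum(c0 + 1, grid.ncols - 1)
    r1 = np.minimum(r0 + 1, grid.nrows - 1)
    corners = np.stack([grid.values[r0, c0], grid.values[r0, c1],
                        grid.values[r1, c0], grid.values[r1, c1]])
    weights = np.stack([(1 - fx) * (1 - fy), fx * (1 - fy),
                        (1 - fx) * fy, fx * fy])
    ok = np.isfinite(corners)
    weights = np.where(ok, weights, 0.0)
    wsum = weights.sum(axis=0)
    if np.any(wsum <= 0):
        raise ValueError("surface is nodata around a sampled location")
    vals = np.nansum(np.where(ok, corners, 0.0) * weights, axis=0) / wsum
    return float(vals[0]) if scalar else vals


def conventional_normalize(cloud: PointCloud, dem: RasterGrid) -> np.ndarray:
    """Per-point height above ground by per-point DEM subtraction
    (h_j = z_j - DEM(x_j, y_j)); this is the uncorrected normalization
    whose terrain bias the per-tree correction removes."""
    return cloud.z - sample_surface(dem, cloud.x, cloud.y)


def build_chm(x, y, heights, cell: float = 0.3,
              params: IDWParams | None = None,
              bounds=None) -> RasterGrid:
    """Canopy height model: IDW raster of normalized heights.

    Used for both the uncorrected (CHM I) and corrected (CHM II)
    products; negative cells are permitted (they flag normalization
    artefacts worth seeing, not clipping).
    """
    heights = np.asarray(heights, dtype=float)
    if heights.size == 0:
        raise ValueError("no heights to grid")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if bounds is None:
        bounds = (x.min(), y.min(), x.max(), y.max())
    grid = grid_for_bounds(bounds, cell)
    return idw_interpolate((x, y, heights), grid, params)


def difference_raster(a: RasterGrid, b: RasterGrid) -> RasterGrid:
    """Cellwise a - b where both carry data, nodata elsewhere."""
    if a.values.shape != b.values.shape or a.origin != b.origin \
            or a.cell != b.cell:
        raise ValueError("grids are not aligned")
    both = np.isfinite(a.values) & np.isfinite(b.values)
    out = np.where(both, a.values - b.values, np.nan)
    return a.copy_with(out)
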