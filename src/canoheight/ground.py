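"""Multiscale curvature classification (MCC) of ground vs vegetation.

Iteratively interpolates a provisional ground surface from the current
candidate-ground points at three scale domains (0.5x, 1x, 1.5x the base
post-spacing), smooths it with a 3x3 mean kernel, and discards candidates
whose elevation exceeds the smoothed surface by more than the curvature
tolerance.  Only positive residuals are ever discarded — points below the
surface stay, matching the asymmetry of curvature filtering in forests
(canopy is above the ground surface, never below).

The provisional surface is built on slope-detrended residuals (best-fit
plane removed, cell-mean binning, IDW gap fill, plane restored), so a
perfectly planar scene yields zero curvature everywhere and retains
every ground return regardless of slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import PointCloud, RasterGrid, GROUND, VEGETATION
from .surfaces import IDWParams, grid_for_bounds, _idw_at, _fit_plane, sample_surface

_DOMAIN_FACTORS = (0.5, 1.0, 1.5)


@dataclass
class MCCParams:
    """Tunables of the curvature filter.

    scale : post-spacing of the provisional surface, m (0.8-1.5 sensible).
    curvature_tolerance : max positive residual a ground return may have, m
        (0.01-0.10 sensible; looser keeps more ground).
    """

    scale: float = 1.5
    curvature_tolerance: float = 0.05
    max_iterations: int = 20
    convergence_fraction: float = 0.001

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.curvature_tolerance <= 0:
            raise ValueError("curvature_tolerance must be positive")


def _smooth3x3(values: np.ndarray) -> np.ndarray:
    """NaN-aware 3x3 mean filter."""
    filled = np.nan_to_num(values, nan=0.0)
    valid = np.isfinite(values).astype(float)
    kernel = np.ones((3, 3))
    total = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    count = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore"):
        out = total / count
    out[count == 0] = np.nan
    return out


def _trimmed_plane(x, y, z):
    """Robust detrend plane: refit twice on the lower-residual half so
    above-ground candidates (canopy still in the candidate set during
    early passes) cannot tilt the reference plane."""
    coef = _fit_plane(x, y, z)
    for _ in range(2):
        resid = z - (coef[0] * x + coef[1] * y + coef[2])
        keep = resid <= np.median(resid)
        if keep.sum() < 3:
            break
        coef = _fit_plane(x[keep], y[keep], z[keep])
    return coef


def _provisional_surface(x, y, z, bounds, spacing: float) -> RasterGrid:
    """Detrended, binned, IDW-filled and 3x3-smoothed candidate surface."""
    a, b, c = _trimmed_plane(x, y, z)
    resid = z - (a * x + b * y + c)
    grid = grid_for_bounds(bounds, spacing)
    col = np.clip(np.round((x - grid.origin[0]) / spacing).astype(int),
                  0, grid.ncols - 1)
    row = np.clip(np.round((y - grid.origin[1]) / spacing).astype(int),
                  0, grid.nrows - 1)
    flat = row * grid.ncols + col
    sums = np.bincount(flat, weights=resid, minlength=grid.nrows * grid.ncols)
    counts = np.bincount(flat, minlength=grid.nrows * grid.ncols)
    occupied = counts > 0
    means = np.full(grid.nrows * grid.ncols, np.nan)
    means[occupied] = sums[occupied] / counts[occupied]

    xs, ys = grid.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    vals = means.reshape(grid.nrows, grid.ncols)
    empty = ~np.isfinite(vals)
    if empty.any() and occupied.any():
        src_xy = np.column_stack([gx.ravel()[occupied], gy.ravel()[occupied]])
        q = np.column_stack([gx[empty], gy[empty]])
        fill = _idw_at(q, src_xy, means[occupied],
                       IDWParams(neighbors=8), radius=10.0 * spacing)
        vals[empty] = fill
    vals = _smooth3x3(vals)
    return grid.copy_with(vals + a * gx + b * gy + c)


def classify_ground(cloud: PointCloud, params: MCCParams | None = None) -> PointCloud:
    """Label every return GROUND or VEGETATION by multiscale curvature.

    Returns a new cloud; the input is not modified.  Raises if fewer than
    three candidate ground points remain during any pass.
    """
    params = params or MCCParams()
    n = len(cloud)
    if n < 10:
        raise ValueError("need at least 10 points to classify")
    bounds = cloud.bounds()
    if (bounds[2] - bounds[0]) <= 2 * params.scale \
            and (bounds[3] - bounds[1]) <= 2 * params.scale:
        raise ValueError("planar extent too small for the chosen scale")

    candidate = np.ones(n, dtype=bool)
    for iteration in range(params.max_iterations):
        removed_this_iter = 0
        for factor in _DOMAIN_FACTORS:
            if candidate.sum() < 3:
                raise ValueError(
                    f"fewer than 3 ground candidates left in iteration "
                    f"{iteration + 1} (scale domain {factor:g}x)")
            spacing = factor * params.scale
            surf = _provisional_surface(cloud.x[candidate], cloud.y[candidate],
                                        cloud.z[candidate], bounds, spacing)
            est = sample_surface(surf, cloud.x[candidate], cloud.y[candidate])
            above = cloud.z[candidate] > est + params.curvature_tolerance
            idx = np.flatnonzero(candidate)[above]
            candidate[idx] = False
            removed_this_iter += idx.size
        if removed_this_iter / n < params.convergence_fraction:
            break

    classification = np.where(candidate, GROUND, VEGETATION)
    return cloud.with_classification(classification)
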