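"""Core in-memory containers for the canopy-height pipeline.

All coordinates are metres in a projected planar CRS.  The tan(i)
terrain-error geometry this package implements is meaningless in
geographic (degree) coordinates, so no CRS handling is attempted:
callers are expected to supply projected data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from shapely.validation import explain_validity

# ASPRS-style class codes used throughout.
UNCLASSIFIED = 1
GROUND = 2
VEGETATION = 5

_VALID_CLASSES = frozenset({UNCLASSIFIED, GROUND, VEGETATION})


@dataclass
class PointCloud:
    """A set of LiDAR returns with per-return number and class label.

    Parameters
    ----------
    x, y, z : float arrays, metres (easting, northing, elevation).
    return_number : int array, >= 1; first returns carry the canopy surface.
    classification : int array; one of UNCLASSIFIED (1), GROUND (2),
        VEGETATION (5).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    return_number: np.ndarray = None
    classification: np.ndarray = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.x.size
        if n == 0:
            raise ValueError("point cloud must contain at least one point")
        if self.y.size != n or self.z.size != n:
            raise ValueError("x, y, z must have equal length")
        if self.return_number is None:
            self.return_number = np.ones(n, dtype=int)
        else:
            self.return_number = np.asarray(self.return_number, dtype=int)
        if self.classification is None:
            self.classification = np.full(n, UNCLASSIFIED, dtype=int)
        else:
            self.classification = np.asarray(self.classification, dtype=int)
        if self.return_number.size != n or self.classification.size != n:
            raise ValueError("attribute arrays must match coordinate length")
        for arr, name in ((self.x, "x"), (self.y, "y"), (self.z, "z")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if np.any(self.return_number < 1):
            raise ValueError("return_number must be >= 1")
        bad = set(np.unique(self.classification)) - _VALID_CLASSES
        if bad:
            raise ValueError(f"unknown class codes: {sorted(bad)}")

    def __len__(self) -> int:
        return self.x.size

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of planimetric coordinates."""
        return np.column_stack([self.x, self.y])

    def subset(self, mask_or_index) -> "PointCloud":
        """New cloud restricted to a boolean mask or index array."""
        return PointCloud(
            self.x[mask_or_index],
            self.y[mask_or_index],
            self.z[mask_or_index],
            self.return_number[mask_or_index],
            self.classification[mask_or_index],
        )

    def with_classification(self, classification: np.ndarray) -> "PointCloud":
        return PointCloud(self.x, self.y, self.z, self.return_number,
                          np.asarray(classification, dtype=int))

    def bounds(self):
        """(xmin, ymin, xmax, ymax)."""
        return (self.x.min(), self.y.min(), self.x.max(), self.y.max())


@dataclass
class RasterGrid:
    """Axis-aligned regular grid (DEM / DSM / CHM / difference surface).

    ``origin`` is the (x, y) of the LOWER-LEFT CELL CENTRE; row index
    increases northward, column index eastward, so ``values[r, c]`` sits at
    ``(origin[0] + c*cell, origin[1] + r*cell)``.  Nodata is represented as
    NaN in memory and never mixed into arithmetic; writers translate it to
    a sentinel on disk.
    """

    origin: tuple
    cell: float
    values: np.ndarray

    def __post_init__(self):
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self):
        """1-D arrays of x (cols) and y (rows) cell-centre coordinates."""
        x0, y0 = self.origin
        xs = x0 + self.cell * np.arange(self.ncols)
        ys = y0 + self.cell * np.arange(self.nrows)
        return xs, ys

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.origin, self.cell, np.asarray(values, float))


@dataclass
class CrownSet:
    """Closed crown-boundary polygons, each grouping one tree's returns."""

    polygons: list = field(default_factory=list)  # list of (id, shapely Polygon)

    def __post_init__(self):
        for pid, poly in self.polygons:
            if not isinstance(poly, Polygon):
                raise ValueError(f"crown {pid}: not a polygon")
            if not poly.is_valid:
                raise ValueError(
                    f"crown {pid}: invalid geometry ({explain_validity(poly)})")
            if poly.area <= 0:
                raise ValueError(f"crown {pid}: zero area")

    def __len__(self) -> int:
        return len(self.polygons)

    @property
    def ids(self):
        return [pid for pid, _ in self.polygons]

    @property
    def geometries(self):
        return [poly for _, poly in self.polygons]
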