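"""Closed-form geometry of terrain-induced canopy-height error.

When heights are normalized by per-point DEM subtraction on a uniform
slope of angle i, a return at signed horizontal offset c from the trunk
(positive upslope) is biased by -c*tan(i): upslope returns are depressed,
downslope returns elevated.  The worst case over a crown of diameter d is
at the crown edge, (d/2)*tan(i).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

DEFAULT_DIAMETERS = (3.0, 5.0, 10.0, 15.0)
DEFAULT_SLOPES = (5.0, 10.0, 20.0, 30.0, 40.0, 50.0)


def point_bias(offset, slope_deg) -> np.ndarray | float:
    """Conventional-normalization height bias (m) of a return at signed
    horizontal ``offset`` from the trunk (positive upslope)."""
    offset = np.asarray(offset, dtype=float)
    slope = np.asarray(slope_deg, dtype=float)
    if np.any(np.abs(slope) >= 90):
        raise ValueError("slope must satisfy |slope| < 90 degrees")
    out = -offset * np.tan(np.radians(slope))
    return float(out) if out.ndim == 0 else out


def max_difference(crown_diameter: float, slope_deg: float) -> float:
    """Maximum |bias| (m) over a crown: (d/2)*tan(i)."""
    if crown_diameter <= 0:
        raise ValueError("crown diameter must be positive")
    if not 0 <= slope_deg < 90:
        raise ValueError("slope must be in [0, 90) degrees")
    return crown_diameter / 2.0 * math.tan(math.radians(slope_deg))


def max_difference_table(diameters=DEFAULT_DIAMETERS,
                         slopes=DEFAULT_SLOPES) -> pd.DataFrame:
    """Matrix of maximum differences, crown diameter (rows, m) by slope
    gradient (columns, degrees).  The defaults span 3-15 m crowns and
    5-50 degree slopes."""
    diameters = list(diameters)
    slopes = list(slopes)
    if not diameters or not slopes:
        raise ValueError("diameter and slope lists must be non-empty")
    vals = [[max_difference(d, s) for s in slopes] for d in diameters]
    return pd.DataFrame(vals, index=pd.Index(diameters, name="crown_d_m"),
                        columns=pd.Index(slopes, name="slope_deg"))
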