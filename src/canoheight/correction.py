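"""Per-tree terrain correction of normalized canopy heights.

Conventional normalization subtracts the DEM under each return, which on
sloping ground tilts every crown: returns upslope of the trunk come out
too low and returns downslope too high, by offset x tan(slope).  The
correction implemented here instead renormalizes all of a crown's
returns against a single elevation — the DEM value at the crown's
height-weighted planimetric gravity centre, taken as the tree-base
elevation.  Each crown is thus shifted rigidly: intra-crown structure is
preserved exactly and the terrain tilt is removed.

For crown i with member returns (x_ij, y_ij, z_ij) and DEM elevations
A_ij under them, the gravity centre is

    x_ig = sum_j x_ij * w_j / sum_j w_j,   w_j = z_ij - mean_j(A_ij)

(and likewise y_ig); the corrected heights are z_ij - DEM(x_ig, y_ig).
Negative weights (returns below the group's mean ground elevation) are
clamped to zero so the centre stays a convex combination of member
locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .core import PointCloud, RasterGrid, CrownSet, VEGETATION
from .surfaces import sample_surface, conventional_normalize

LOW_CONFIDENCE_MEMBERS = 3


class DegenerateGroupError(ValueError):
    """Raised when a crown group has no positive height weight."""


@dataclass
class TreeGroup:
    """One crown's returns and their corrected heights."""

    crown_id: object
    indices: np.ndarray                    # member indices into the cloud
    gravity_xy: tuple | None = None        # (x_ig, y_ig)
    base_elevation: float | None = None    # z_ig, m
    corrected_heights: np.ndarray | None = None
    low_confidence: bool = False

    @property
    def n(self) -> int:
        return self.indices.size


@dataclass
class CorrectionConfig:
    vegetation_threshold: float = 1.8   # m above ground; shrub/gap cutoff
    gap_removal: bool = True

    def __post_init__(self):
        if self.vegetation_threshold < 0:
            raise ValueError("vegetation_threshold must be >= 0")


def group_by_crown(cloud: PointCloud, crowns: CrownSet):
    """Assign first-return vegetation points to the crown polygon
    containing them.

    Points on a shared boundary or inside overlapping polygons go to the
    lowest crown id.  Returns ``(groups, gap_indices)`` where gap points
    are the candidates inside no polygon; empty groups are kept (n = 0).
    """
    if len(crowns) == 0:
        raise ValueError("crown set is empty")
    candidate = (cloud.return_number == 1) & (cloud.classification == VEGETATION)
    cand_idx = np.flatnonzero(candidate)
    pts = shapely.points(cloud.x[cand_idx], cloud.y[cand_idx])
    tree = STRtree(crowns.geometries)
    pt_i, poly_i = tree.query(pts, predicate="covered_by")

    ids = crowns.ids
    order = np.argsort([ids[i] for i in poly_i], kind="stable") \
        if len(poly_i) else np.empty(0, int)
    assigned = {}
    for k in order:
        p = pt_i[k]
        if p not in assigned:
            assigned[p] = poly_i[k]

    members = {i: [] for i in range(len(crowns))}
    gap = []
    for local, global_idx in enumerate(cand_idx):
        if local in assigned:
            members[assigned[local]].append(global_idx)
        else:
            gap.append(global_idx)

    groups = [TreeGroup(crown_id=ids[i],
                        indices=np.asarray(members[i], dtype=int),
                        low_confidence=len(members[i]) < LOW_CONFIDENCE_MEMBERS)
              for i in range(len(crowns))]
    return groups, np.asarray(gap, dtype=int)


def gravity_centre(cloud: PointCloud, indices: np.ndarray,
                   dem: RasterGrid) -> tuple:
    """Height-weighted planimetric centre of a crown's returns."""
    if indices.size == 0:
        raise DegenerateGroupError("empty group")
    x = cloud.x[indices]
    y = cloud.y[indices]
    z = cloud.z[indices]
    A = sample_surface(dem, x, y)
    A = np.atleast_1d(A)
    w = z - A.mean()
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise DegenerateGroupError(
            "group has no return above its mean ground elevation")
    return float((x * w).sum() / total), float((y * w).sum() / total)


def correct_group(cloud: PointCloud, group: TreeGroup,
                  dem: RasterGrid) -> TreeGroup:
    """Fill in the group's gravity centre, base elevation z_ig and the
    rigidly shifted corrected heights z_ij - z_ig."""
    gx, gy = gravity_centre(cloud, group.indices, dem)
    z_ig = sample_surface(dem, gx, gy)
    group.gravity_xy = (gx, gy)
    group.base_elevation = float(z_ig)
    group.corrected_heights = cloud.z[group.indices] - z_ig
    return group


@dataclass
class CorrectionResult:
    """Both normalizations for every retained point, plus the tree table."""

    point_indices: np.ndarray       # indices into the input cloud
    conventional: np.ndarray        # DEM-subtraction heights, m
    corrected: np.ndarray           # per-tree base-elevation heights, m
    groups: list = field(default_factory=list)
    gap_indices: np.ndarray = None

    def tree_table(self) -> pd.DataFrame:
        rows = [(g.crown_id,
                 g.gravity_xy[0] if g.gravity_xy else np.nan,
                 g.gravity_xy[1] if g.gravity_xy else np.nan,
                 g.base_elevation if g.base_elevation is not None else np.nan,
                 g.n,
                 float(np.max(g.corrected_heights))
                 if g.corrected_heights is not None and g.n else np.nan,
                 g.low_confidence)
                for g in self.groups]
        return pd.DataFrame(rows, columns=["crown_id", "x_ig", "y_ig", "z_ig",
                                           "n", "max_corrected_height",
                                           "low_confidence"])


def correct_scene(cloud: PointCloud, crowns: CrownSet, dem: RasterGrid,
                  config: CorrectionConfig | None = None) -> CorrectionResult:
    """Run the whole correction: group by crown, locate each gravity
    centre, renormalize each group against its base elevation.

    Gap points (vegetation candidates outside every crown) keep their
    conventional heights; with ``gap_removal`` those at or below the
    vegetation threshold are dropped from the output.  Degenerate groups
    are skipped with a warning; only if every group degenerates does the
    call fail.
    """
    config = config or CorrectionConfig()
    groups, gap_idx = group_by_crown(cloud, crowns)
    conv_all = conventional_normalize(cloud, dem)

    corrected_groups = []
    n_ok = 0
    for g in groups:
        if g.n == 0:
            corrected_groups.append(g)
            continue
        try:
            correct_group(cloud, g, dem)
            n_ok += 1
        except DegenerateGroupError as exc:
            warnings.warn(f"crown {g.crown_id} skipped: {exc}")
        corrected_groups.append(g)
    if n_ok == 0:
        raise DegenerateGroupError("all crown groups are degenerate")

    idx_parts, conv_parts, corr_parts = [], [], []
    for g in corrected_groups:
        if g.corrected_heights is None or g.n == 0:
            continue
        idx_parts.append(g.indices)
        conv_parts.append(conv_all[g.indices])
        corr_parts.append(g.corrected_heights)

    if gap_idx.size:
        keep = np.ones(gap_idx.size, dtype=bool)
        if config.gap_removal:
            keep = conv_all[gap_idx] > config.vegetation_threshold
        kept_gap = gap_idx[keep]
        if kept_gap.size:
            idx_parts.append(kept_gap)
            conv_parts.append(conv_all[kept_gap])
            corr_parts.append(conv_all[kept_gap])  # no crown: unchanged

    return CorrectionResult(
        point_indices=np.concatenate(idx_parts),
        conventional=np.concatenate(conv_parts),
        corrected=np.concatenate(corr_parts),
        groups=corrected_groups,
        gap_indices=gap_idx,
    )
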