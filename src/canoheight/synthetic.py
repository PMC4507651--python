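"""Synthetic LiDAR scenes with known ground truth.

Emulates first-return point clouds over planar (optionally gently rough)
terrain with parametric tree crowns, at the nominal survey density of
15 points/m^2.  Every downstream stage — ground filtering, DEM/CHM
construction, the per-tree terrain correction, plot statistics — can be
validated against the generated truth (per-point ground flags, per-tree
base elevations, true canopy heights, crown polygons).

The simulation is deliberately minimal: only first returns are drawn
(the correction operates on first echoes), crown footprints occlude the
ground beneath them (no ground returns under crowns, which stresses DEM
interpolation exactly where it matters), and terrain roughness is a
seeded low-frequency cosine mixture rather than white noise so that
curvature-based ground filtering remains meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .core import PointCloud, CrownSet

_N_COSINES = 8


@dataclass
class TreeSpec:
    """One parametric tree: position, height and crown geometry (metres)."""

    base_xy: tuple
    height: float
    crown_diameter: float
    crown_shape: str = "spheroid"  # or "cone"
    crown_base_height: float = 0.0

    def __post_init__(self):
        if not self.height > self.crown_base_height >= 0:
            raise ValueError("need height > crown_base_height >= 0")
        if self.crown_diameter <= 0:
            raise ValueError("crown_diameter must be positive")
        if self.crown_shape not in ("spheroid", "cone"):
            raise ValueError(f"unknown crown_shape {self.crown_shape!r}")

    @property
    def radius(self) -> float:
        return self.crown_diameter / 2.0

    def envelope_height(self, rho) -> np.ndarray:
        """Height of the crown's upper envelope above the tree base at
        horizontal distance ``rho`` from the trunk axis (NaN outside)."""
        rho = np.asarray(rho, dtype=float)
        r = self.radius
        frac = np.clip(rho / r, 0.0, None)
        if self.crown_shape == "spheroid":
            zc = (self.crown_base_height + self.height) / 2.0
            b = (self.height - self.crown_base_height) / 2.0
            with np.errstate(invalid="ignore"):
                h = zc + b * np.sqrt(1.0 - frac ** 2)
        else:  # cone: apex at `height`, base rim at `crown_base_height`
            h = self.height - (self.height - self.crown_base_height) * frac
        return np.where(frac <= 1.0, h, np.nan)


@dataclass
class SceneSpec:
    """Terrain + forest + sensor parameters of one simulated scene.

    ``aspect_deg`` is the compass direction pointing UPslope (0 = +y).
    ``density`` is the first-return density in points/m^2; ``noise_sd_z``
    the Gaussian ranging noise (sensor-grade ~0.04 m).
    """

    extent: tuple = (30.0, 30.0)
    slope_deg: float = 0.0
    aspect_deg: float = 0.0
    roughness_sd: float = 0.0
    trees: list = field(default_factory=list)
    density: float = 15.0
    noise_sd_z: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")
        if not 0 <= self.slope_deg < 90:
            raise ValueError("slope_deg must be in [0, 90)")
        self.trees = [t if isinstance(t, TreeSpec) else TreeSpec(**t)
                      for t in self.trees]

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    def _upslope_unit(self):
        a = math.radians(self.aspect_deg)
        return math.sin(a), math.cos(a)

    def _roughness_params(self):
        rng = np.random.default_rng(self.seed + 977)
        lmin = min(self.extent)
        wavelengths = rng.uniform(lmin / 8.0, lmin / 2.0, _N_COSINES)
        theta = rng.uniform(0, 2 * np.pi, _N_COSINES)
        phase = rng.uniform(0, 2 * np.pi, _N_COSINES)
        amp = rng.uniform(0.5, 1.0, _N_COSINES)
        # sd of a sum of cosines is sqrt(sum amp^2 / 2); rescale to target
        amp *= self.roughness_sd / math.sqrt(np.sum(amp ** 2) / 2.0)
        return wavelengths, theta, phase, amp


def terrain_elevation(spec: SceneSpec, x, y) -> np.ndarray:
    """True bare-earth elevation at (x, y): a plane of gradient
    tan(slope) along the aspect direction plus the seeded smooth
    roughness field (zero-mean, sd = ``roughness_sd``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ux, uy = spec._upslope_unit()
    z = math.tan(math.radians(spec.slope_deg)) * (x * ux + y * uy)
    if spec.roughness_sd > 0:
        wavelengths, theta, phase, amp = spec._roughness_params()
        for lam, th, ph, a in zip(wavelengths, theta, phase, amp):
            k = 2 * np.pi / lam
            z = z + a * np.cos(k * (x * np.cos(th) + y * np.sin(th)) + ph)
    return z


@dataclass
class SceneTruth:
    """Ground truth aligned with the sampled cloud (one row per point)."""

    is_ground: np.ndarray            # bool per point
    tree_id: np.ndarray              # int per point, -1 for ground
    true_height: np.ndarray          # noiseless canopy height above base, m
    base_elevation: np.ndarray       # per tree, m
    trees: list                      # the TreeSpec list
    overlapping: np.ndarray          # per tree: footprint intersects another


def truth_crown_polygons(spec: SceneSpec, quad_segs: int = 16) -> CrownSet:
    """Circular crown-footprint polygons (>= 32 vertices), one per tree.

    Stands in for image-based crown segmentation: the generator knows the
    true footprints, so downstream grouping can be tested in isolation.
    """
    polys = [(i, Point(t.base_xy).buffer(t.radius, quad_segs=quad_segs))
             for i, t in enumerate(spec.trees)]
    return CrownSet(polys)


def sample_scene(spec: SceneSpec):
    """Draw one simulated first-return cloud and its truth.

    Ground returns are Poisson-sampled on bare (non-crown) area; each
    crown contributes Poisson(density * footprint area) returns on its
    upper envelope.  All z receive N(0, noise_sd_z^2) noise.  The same
    seed always yields the identical cloud.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.extent
    area = w * h

    centers = np.array([t.base_xy for t in spec.trees], dtype=float).reshape(-1, 2)
    radii = np.array([t.radius for t in spec.trees], dtype=float)

    # ground returns, thinned where crowns occlude
    n_g = rng.poisson(spec.density * area)
    gx = rng.uniform(0, w, n_g)
    gy = rng.uniform(0, h, n_g)
    if len(spec.trees):
        d2 = ((gx[:, None] - centers[None, :, 0]) ** 2
              + (gy[:, None] - centers[None, :, 1]) ** 2)
        bare = ~np.any(d2 <= radii[None, :] ** 2, axis=1)
        gx, gy = gx[bare], gy[bare]
    gz = terrain_elevation(spec, gx, gy)

    xs, ys, zs = [gx], [gy], [gz]
    tree_ids = [np.full(gx.size, -1, dtype=int)]
    true_h = [np.zeros(gx.size)]

    base_elev = terrain_elevation(spec, centers[:, 0], centers[:, 1]) \
        if len(spec.trees) else np.empty(0)

    for i, tree in enumerate(spec.trees):
        n_t = rng.poisson(spec.density * math.pi * tree.radius ** 2)
        rho = tree.radius * np.sqrt(rng.uniform(0, 1, n_t))
        theta = rng.uniform(0, 2 * np.pi, n_t)
        tx = tree.base_xy[0] + rho * np.cos(theta)
        ty = tree.base_xy[1] + rho * np.sin(theta)
        env = tree.envelope_height(rho)
        tz = base_elev[i] + env
        xs.append(tx)
        ys.append(ty)
        zs.append(tz)
        tree_ids.append(np.full(n_t, i, dtype=int))
        true_h.append(env)

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    z = np.concatenate(zs)
    tid = np.concatenate(tree_ids)
    th = np.concatenate(true_h)
    if spec.noise_sd_z > 0:
        z = z + rng.normal(0, spec.noise_sd_z, z.size)

    overlap = np.zeros(len(spec.trees), dtype=bool)
    for i in range(len(spec.trees)):
        for j in range(i + 1, len(spec.trees)):
            if np.hypot(*(centers[i] - centers[j])) < radii[i] + radii[j]:
                overlap[i] = overlap[j] = True

    cloud = PointCloud(x, y, z)
    truth = SceneTruth(is_ground=tid < 0, tree_id=tid, true_height=th,
                       base_elevation=np.asarray(base_elev),
                       trees=list(spec.trees), overlapping=overlap)
    return cloud, truth


# ---------------------------------------------------------------------------
# convenience generators used by the test-bench and the evaluation scripts
# ---------------------------------------------------------------------------

def random_forest_scene(seed: int,
                        slope_deg: float,
                        n_trees: int = 4,
                        crown_range: tuple = (3.0, 10.0),
                        extent: tuple = (30.0, 30.0),
                        density: float = 15.0,
                        noise_sd_z: float = 0.04,
                        roughness_sd: float = 0.0,
                        crown_shape: str = "spheroid") -> SceneSpec:
    """A plot-sized scene with randomly placed, non-overlapping crowns.

    Crowns are kept wholly inside the extent (margin = radius + 1.5 m)
    and pairwise disjoint so that per-tree truth is unambiguous; heights
    scale loosely with crown size as in closed-canopy broadleaf stands.
    """
    rng = np.random.default_rng(seed)
    w, h = extent
    trees = []
    placed = []
    attempts = 0
    while len(trees) < n_trees and attempts < 500:
        attempts += 1
        d = rng.uniform(*crown_range)
        r = d / 2.0
        margin = r + 1.5
        if w - 2 * margin <= 0 or h - 2 * margin <= 0:
            continue
        bx = rng.uniform(margin, w - margin)
        by = rng.uniform(margin, h - margin)
        if any(np.hypot(bx - px, by - py) < r + pr + 0.5
               for px, py, pr in placed):
            continue
        height = rng.uniform(8.0, 12.0) + 1.2 * d
        cbh = rng.uniform(0.25, 0.40) * height
        trees.append(TreeSpec((bx, by), height, d,
                              crown_shape=crown_shape, crown_base_height=cbh))
        placed.append((bx, by, r))
    if not trees:
        raise ValueError("could not place any tree in the given extent")
    return SceneSpec(extent=extent, slope_deg=slope_deg, aspect_deg=0.0,
                     roughness_sd=roughness_sd, trees=trees, density=density,
                     noise_sd_z=noise_sd_z, seed=int(seed))


def synthetic_plot_table(n_plots: int = 41,
                         seed: int = 0,
                         beta0: float = 2.0,
                         beta1: float = 1.0,
                         noise_sd: float = 0.1,
                         term: str = "h90") -> pd.DataFrame:
    """Plot-level percentile metrics with a known generating model.

    Each plot gets a correlated but jittered set of height percentiles
    (h10..h90, hmean) and a response ``lorey = beta0 + beta1*<term> +
    N(0, noise_sd^2)``, for exercising recovery behaviour of the stepwise
    percentile regression on the study's n = 41 plot count.
    """
    rng = np.random.default_rng(seed)
    qs = np.linspace(0.45, 1.0, 9)  # relative percentile profile h10..h90
    rows = []
    for p in range(n_plots):
        scale = rng.uniform(8.0, 18.0)
        perc = np.sort(scale * qs + rng.normal(0, 0.5, 9))
        hmean = perc.mean() + rng.normal(0, 0.3)
        rows.append([p] + list(perc) + [hmean])
    cols = ["plot_id"] + [f"h{k}0" for k in range(1, 10)] + ["hmean"]
    df = pd.DataFrame(rows, columns=cols)
    df["lorey"] = beta0 + beta1 * df[term] + rng.normal(0, noise_sd, n_plots)
    return df
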