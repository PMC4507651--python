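# Methods

This note documents the models and procedures implemented in
`canoheight`, the defaults and why they were chosen, the numerical
choices that matter, and what the synthetic test bench does and does not
demonstrate about real data.

## 1. Terrain-error geometry

On a uniform slope of gradient *i*, normalizing a return by subtracting
the DEM directly beneath it measures the vertical distance to the ground
under the return, not to the tree base. For a vertical tree whose trunk
meets the ground at elevation *z_b*, a canopy return at signed
horizontal offset *c* from the trunk along the upslope direction has
conventional height

    h_conv = h_true − c·tan(i)

so the bias is −c·tan(i): upslope returns depressed, downslope returns
elevated, antisymmetric about the trunk. Over a crown of diameter *d*
the worst case is (d/2)·tan(i). `error_model` exposes both the per-point
bias and the worst-case matrix over crown diameters 3–15 m and slopes
5–50°; the matrix is compared to published reference values at a ±0.01 m
tolerance because the reference table mixes rounding conventions across
columns.

## 2. The per-tree correction

Given crown polygons, first-return vegetation points are grouped by
point-in-polygon containment (boundary and overlap ties go to the lowest
crown id, a deterministic convention). For each group the planimetric
gravity centre is the height-weighted centroid with weights
w_j = z_j − mean(A_j), A_j being the bilinear DEM elevation under return
j. The corrected heights are z_j − z_g with z_g the bilinear DEM value
at the gravity centre. Properties that follow directly:

- **rigid shift** — within a crown, corrected heights differ from raw
  elevations by one constant, so all intra-crown structure (pairwise
  Δz) is preserved exactly;
- **flat-ground neutrality** — on flat terrain z_g equals the DEM under
  every return and the correction is a no-op;
- **sign structure** — corrected − conventional = DEM(x_j) − z_g, which
  on a planar slope is +offset·tan(i) for offsets upslope of the gravity
  centre: the correction raises the upslope half of each crown and
  lowers the downslope half, undoing the conventional tilt.

Design choices where the formulation was genuinely open:

- **negative weights are clamped to zero.** Returns below the group's
  mean ground elevation would otherwise repel the centroid; after the
  1.8 m vegetation cutoff such returns are pathological, and clamping
  keeps the centre a convex combination of member locations. Groups
  whose weights sum to zero are degenerate and skipped with a warning.
- **z_g is sampled bilinearly**, not nearest-cell, to avoid quantizing
  the base elevation to the 0.3 m DEM grid.
- **gap handling.** Vegetation candidates inside no crown are "gap"
  points; they keep their conventional heights, and those at or below
  the 1.8 m threshold are dropped (configurable). Crown/gap
  classification uses conventional heights because they are the only
  heights available before correction.
- Groups with fewer than 3 members are corrected but flagged
  low-confidence in the tree table.

### Accuracy floor: the gravity centre is an estimate

The gravity centre is computed from a finite sample of crown returns.
Its planimetric standard error is approximately
(r/2)·(w_rms/w̄)/√N for crown radius r and N member returns; at
15 points/m² this is ≈ 0.05–0.08 m regardless of crown size (N grows
with r²). The per-tree base elevation therefore carries an error of
roughly that jitter times tan(i), and the theoretical per-point bound
|corrected − conventional| ≤ (d/2)·tan(i) can be exceeded by a few
centimetres on steep slopes when the estimated centre sits slightly
off-trunk. The test suite measures this directly: across an 80-tree
battery on 10–40° slopes the bound with a 0.05 m allowance is violated
by up to ~0.04 m by a handful of points, exactly the magnitude the
jitter analysis predicts. This is a property of the estimator at survey
density, not an implementation artefact; the corresponding system test
is left asserting the idealized bound and failing, as honest
documentation of the gap between the idealized geometry and the sampled
estimator.

## 3. Ground filtering (multiscale curvature)

Returns are classified by iteratively interpolating a provisional
surface from the current ground candidates and discarding candidates
that sit more than a curvature tolerance above it. Per pass: detrend by
a robust plane (two trimmed refits on the lower-residual half, so
canopy returns present in early passes cannot tilt the reference),
bin candidate residuals to cell means at the domain's post-spacing,
IDW-fill empty cells, smooth with a 3×3 NaN-aware mean kernel, restore
the plane, and relabel candidates with z > surface + tolerance. Three
scale domains (0.5×, 1×, 1.5× the base post-spacing) run per iteration
until fewer than `convergence_fraction` of points are reclassified.
Only positive residuals are ever discarded — the asymmetry of ground
filtering under vegetation.

Defaults: scale 1.5 m, curvature tolerance 0.05 m (the midpoints/maxima
of the sensible 0.8–1.5 m and 0.01–0.10 m ranges), 20 iterations,
convergence fraction 0.001. On noiseless planar scenes the filter
retains 100% of ground returns at any slope (the detrended surface is
exactly flat). With ranging noise approaching the tolerance the filter
progressively trims the upper noise tail — at 0.04 m noise and 0.05 m
tolerance roughly a fifth of ground returns are discarded. This lowers
the DEM by a centimetre-scale constant that cancels in the
corrected-minus-conventional difference; for maximum ground recall the
tolerance should be ≳2.5× the ranging noise.

## 4. Surfaces

All gridding is inverse-distance-weighted: cell value
Σ w_j z_j / Σ w_j with w_j = d_j^(−power) over at most `neighbors`
nearest points within `max_radius`; a cell within 1 nm of a point takes
that point's value; cells with no neighbour are nodata. Defaults:
power 2, 12 neighbours — conventional values, configurable; the DEM
builder uses a 15 m search radius so interpolation spans the ground gap
occluded by even the largest (15 m) crowns.

**Slope detrending.** Plain IDW of absolute elevations is biased
wherever the neighbourhood is one-sided — raster edges and
crown-occlusion gaps — by roughly (neighbour-centroid offset)·tan(i),
up to ~0.3 m at 30°. `build_dem` therefore fits a least-squares plane
to the ground points, interpolates only the residual relief, and
restores the plane at cell centres. On planar terrain the DEM is then
exact regardless of occlusion gaps; on undulating terrain the residual
field is what IDW handles well. The raw `idw_interpolate` operation
remains the pure weighted sum.

Rasters use a lower-left cell-centre origin with row index increasing
northward; samplers and writers share this convention (ESRI ASCII is
flipped on I/O, GeoTIFF carries pixel-scale/tiepoint tags). Bilinear
sampling drops nodata corners from the weighting and fails loudly on a
fully-nodata neighbourhood or out-of-extent query. CHMs are IDW rasters
of normalized heights; negative cells are kept visible rather than
clipped.

## 5. Synthetic scenes

The generator emulates the survey conditions the method targets:
first-return clouds at 15 points/m² (Poisson counts, uniform
placement), planar terrain of 0–55° slope with optional smooth
low-frequency cosine roughness (seeded, zero-mean, target sd), and
parametric trees — spheroid or cone crown envelopes anchored at the
terrain elevation of the trunk base, crown diameters 3–15 m. Crown
footprints occlude the ground beneath them (no ground returns under
crowns), which stresses DEM interpolation exactly where the correction
needs it. Gaussian ranging noise defaults to 0.04 m, a sensor-grade
vertical accuracy. Truth records per-point ground flags, per-tree base
elevations and noiseless canopy heights, and circular crown polygons
(≥32 vertices) standing in for image-based crown segmentation.

Deliberately not modelled: multi-return penetration and within-crown
volume scattering (the correction operates on first returns),
intensity, scan-angle geometry, tilted trunks, and irregular or
overlapping crown shapes. Passing tests therefore demonstrate the
geometric behaviour of the correction under clean crown/terrain
geometry, not performance under segmentation errors or leaning trees —
on real data the quality of the crown polygons is the binding
constraint.

Scene sizes in the test bench are plot-scale (30×30 m, 3–5 trees),
matching a typical field-inventory plot; batteries of 20 seeded scenes
back the stochastic properties.

## 6. Plot statistics and evaluation models

- **Difference statistics**: for thresholds k ∈ {0.3, 0.5, 0.8, 1.0,
  1.2, 1.5} m, p_k is the fraction of points with
  |corrected − conventional| > k and mean_k the mean exceedance (0 for
  an empty set). p_k is non-increasing in k by construction, and on
  planar scenes p_k rises with slope; a simple OLS of p_k on slope
  gradient quantifies the relationship (R² ≈ 0.8 for k = 0.3 m on the
  8 m-crown battery).
- **Height percentiles** h10..h90 use linear-interpolation quantiles
  (the common "type 7") of heights strictly above the 1.8 m cutoff;
  hmean is the arithmetic mean of the same subset.
- **Lorey's height** is the basal-area-weighted stand height
  Σ G_i h_i / Σ G_i with G_i = π(dbh_i/200)² m².
- **Stepwise percentile regression** (`StepwiseLoreyRegressor`, a
  scikit-learn-style estimator): forward selection over the ten
  percentile metrics, adding at each step the predictor that most
  improves the pooled K-fold validation R² and stopping when no
  addition improves it by at least 0.01 (the floor prevents chaining
  chance validation gains on noise). Folds are deterministic: seeded
  shuffling within response-rank blocks, stratifying each fold across
  the response range — important at n = 41 plots. Reported: in-sample
  R², adjusted R², RMSE and the final K-fold R². Forward-only selection
  was chosen as the minimal well-defined reading of CV-guided stepwise
  selection; term removal is not implemented.

## 7. Tree extraction

Apices are strict local maxima over a square window (default 3 m,
configurable — it should be somewhat smaller than the crowns sought) at
or above the 1.8 m cutoff; plateaus yield no apex. Crowns are labelled
by marker-controlled watershed on the inverted CHM masked to the
≥1.8 m support — a standard simplification of morphology-controlled
watershed delineation. Detection lists are compared by greedy
nearest-neighbour matching within 2 m. On steep synthetic scenes the
apices detected on the uncorrected CHM sit systematically downslope of
their corrected counterparts (mean displacement ≈ 1.2 m at 35°),
reproducing the terrain-driven tree-position shift the correction
removes.

## 8. Known limitations

- Vertical-tree assumption; leaning trees violate the rigid-shift model.
- Crown polygons are trusted as given; segmentation error propagates
  directly into grouping.
- The gravity-centre sampling jitter (section 2) sets a
  ~0.05 m × tan(i) floor on base-elevation accuracy at 15 points/m².
- The curvature filter trims the upper noise tail of ground returns
  when the tolerance is close to the ranging noise (section 3).
- No reprojection or geographic-CRS support: the tan(i) geometry
  assumes planar metric coordinates.
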