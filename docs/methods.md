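# Methods

`rootphene` asks a methodological question about root phenotyping: when a
root system is summarised by aggregate architecture metrics — total
length, convex hull volume, bushiness, fractal dimension and the rest —
how much of the underlying phenotype do those numbers actually pin down,
and how robust are they to the imaging plane and to the day of
measurement?  The package answers it in silico: it grows root systems
whose elementary phenes (root counts, diameters, growth angles, lateral
root branching density, elongation rates) are known exactly because they
are simulation inputs, measures both the phenes and the aggregates back
from the geometry, and compares their reliability.

## The root growth model

Root systems are grown as chains of straight segments of at most 0.5 cm
(growth per time step is subdivided below this cap, which keeps angle
measurement and box counting resolution-independent).  Coordinates are in
cm with y the depth axis, positive downward; the soil surface is y = 0
and the stem base the origin.

Each root class — bean: primary, basal whorls 1–5, hypocotyl-borne;
maize: primary, seminal, nodal positions 1–4; plus first-order laterals
on every axial class — carries the phenes:

| phene | unit | meaning |
|---|---|---|
| `count` | – | roots of the class (whorl/node size) |
| `emergence_day` | d | day the class starts growing |
| `diameter` | cm | root diameter, constant along the root |
| `growth_rate` | cm d⁻¹ | tip elongation rate |
| `growth_angle` | ° | angle from horizontal at emergence |
| `gravitropism` | ° cm⁻¹ | deflection toward vertical per cm grown |
| `lrbd` | cm⁻¹ | lateral branches per cm of parent |
| `stochastic_cv` | – | coefficient of variation of all of the above |

Modelling choices where the underlying biology admits several forms:

- **Gravitropism.** Constant angular deflection toward the downward
  vertical per cm grown, capped at the remaining deviation, applied in
  the vertical plane of the current direction.  This is the simplest rule
  that yields the familiar curving trajectories and a single tunable
  shallow/deep axis.
- **Stochasticity.** Multiplicative Gaussian noise (sd = cv·value) on
  every continuous phene, realised once per root; Gaussian angular jitter
  (sd = cv·10° per 0.5 cm step) on growth directions; additive azimuth
  jitter (sd = cv·30°) on emergence azimuths.  One parameter (`cv`)
  controls all three, keeping the noise model parameter-sparse.
- **Whorl geometry.** Axial roots of a class are evenly spaced in
  azimuth with a fixed per-whorl offset; maize nodal classes emerge at
  staggered days (later nodes later, with more and thicker roots),
  reproducing the continual emergence of crown roots in monocots.
- **Laterals.** Branch points are laid along the parent's arc length at
  mean spacing 1/LRBD (multiplicative jitter cv), starting after a 2 cm
  basal non-branching zone and never within 2 cm of the growing tip (the
  tip exclusion is re-evaluated as the root grows).  Laterals emerge
  perpendicular to the local parent tangent at a uniformly random azimuth
  and then follow their own gravitropism.  No second-order laterals.
- **Carbon limitation.** Full resource physiology is out of scope.  An
  optional *elongation budget* (cm/day) proportionally scales all tip
  elongation when total demand exceeds it, which is enough to reproduce
  the qualitative trade-off (more/thicker axials ⇒ shorter laterals) that
  couples phenes in mechanistic models.  Default: off.
- **Boundaries.** None — roots grow in unbounded soil; the only
  constraint is the surface clamp y ≥ 0 (a tip reaching the surface is
  flattened to horizontal).

Simulation is deterministic given (spec, seed) to full floating
precision; snapshot extraction never consumes random numbers, so the
day-10..40 series is internally consistent (segment sets are nested).

## Phene measurement

- **Angle at 5 cm**: the angle between the horizontal and the chord from
  the root base to the point at 5 cm *arc length* along the root
  (interpolated within a segment), in [0°, 90°].  Arc length, not depth,
  keeps the measure defined for shallow roots that never reach 5 cm
  depth; roots shorter than 5 cm fall back to the base→tip chord and are
  flagged truncated.
- **Measured LRBD**: laterals per cm of branched zone (first to last
  branch point); the whole root if exactly one lateral, 0 if none.  With
  k evenly spaced branch points this estimator returns lrbd·k/(k−1) — a
  one-lateral edge effect of order 1/k that decays as the parent
  elongates.  Tests account for this analytically rather than hiding it.
- Class values are means over the roots of the class (angle, diameter,
  LRBD) or class sums (axial/lateral length), one value per class as in
  phenotype heat maps.

With `stochastic_cv = 0` and zero gravitropism, every input phene is
recovered exactly (LRBD up to the edge factor); with noise, class means
over replicate seeds converge to the inputs.

## Aggregate metrics

Seventeen metrics per root system and representation:

- **Totals**: summed segment length, cylinder lateral area 2πrℓ and
  volume πr²ℓ.
- **Maximum depth**: deepest segment endpoint.  **Maximum width**:
  diameter of the exact minimum enclosing circle of all endpoints
  projected to the horizontal plane (GEOS implementation; validated
  against an O(n³) support-set search).
- **Root counts**: segments crossing 50 horizontal planes at the
  midpoints of equal depth bins over (0, max depth).  A segment covers
  the half-open interval [min y, max y) so shared polyline vertices are
  counted once.  Median count uses the midpoint rule; "maximum" count is
  the 84th percentile by nearest rank on the sorted counts; bushiness is
  their ratio (≥ 1 by construction).
- **Volume distribution**: root volume above one-third of maximum depth
  over volume below it, with crossing segments split exactly by length
  fraction; ∞ (flagged) when nothing lies below the plane.
- **Convex hull** volume and surface area of the segment endpoints (the
  hull of a polyline equals the hull of its vertices); degenerate
  (coplanar) systems return volume 0 with the planar hull area, flagged.
  **Solidity** = total volume / hull volume.
- **Minimum enclosing ellipse** (2D only): Khachiyan iteration on the
  convex hull vertices, capped at 2000 iterations, followed by an exact
  containment correction (the ellipse is inflated to the farthest
  support vertex, which is where the convex quadratic attains its
  maximum).  Reported as full axis lengths and aspect ≥ 1.  For 3D
  studies the ellipse fields carry the mean over the rotational series,
  as no 3D ellipsoid is computed.
- **Fractal dimension / abundance**: segments are densified to point
  samples at 0.1 cm; grids with box edges halving from the bounding-cube
  edge down to 0.2 cm are anchored at the bounding-box minimum corner;
  FD is the least-squares slope of log₁₀N against log₁₀(1/s) and FA the
  intercept, i.e. log₁₀ of the extrapolated box count at 1 cm boxes.
  Fewer than three usable scales flags the estimate unreliable (still
  returned).  For 3D systems the point cloud is first rotated into a
  canonical frame (principal horizontal axis → x, sign fixed by the
  farthest point) so that FD/FA are properties of the architecture, not
  of the azimuthal orientation of the coordinate grid; 2D projections
  are deliberately *not* canonicalised — their orientation dependence is
  the phenomenon under study.

## 2D rotational projections

The system is rotated about the vertical axis in 20° steps (18 views)
and orthographically projected onto the x–y plane; depth is preserved
exactly.  Projections are vector projections of the segments — there is
no rasterisation and no occlusion modelling.  In 2D, "convex hull
volume" is the area of the planar hull and "convex hull area" its
perimeter; max width is the horizontal extent; 2D solidity uses a
silhouette proxy (projected length × mean diameter / hull area), flagged
as such, because projected volume is undefined.  Apparent growth angles
are re-measured on the projected polylines, which is the mechanism
behind angle inflation out of plane (a 45° root viewed 60° off its
vertical plane appears at atan(tan 45°/cos 60°) ≈ 63.4°).

Per metric, the mean and the coefficient of variation (sample sd / mean)
across views quantify projection sensitivity.  Rotation-invariant
quantities (depth, slice counts) have CV 0 up to numerical noise;
shape/angle metrics do not.

## Statistical stage

- Min–max scaling per column (constant columns → 0, flagged);
  pairwise-complete Spearman correlations; average-linkage hierarchical
  clustering of phenotypes on 1 − Spearman distance.
- **Random forest**: each aggregate metric is regressed on the phene
  table (default ntree = 1000, mtry = 8 clamped to the predictor count),
  refit `n_repeats` = 50 times with distinct seeds.  Importance is the
  permutation increase in out-of-bag MSE, averaged over trees (the
  regression form of mean decrease in accuracy), computed per tree on
  its own OOB samples.  A predictor is selected when its importance is
  positive at the 90% level across repeats (10th percentile of its
  importance distribution > 0); a pooled-percentile threshold
  (90th percentile of all importance samples, select if the median
  exceeds it) is available as an alternative rule but cannot by
  construction select more than ~10% of predictors, which is too
  restrictive when several phenes genuinely drive a metric.  The reduced
  model (selected predictors only) is refit the same number of times and
  accepted when its OOB R² (reported as % variance explained) is within
  2 percentage points of the full model or better.
- **Timecourse**: metric trajectories over days 10–40 are classified
  increasing/decreasing (|Spearman ρ(day, value)| > 0.7),
  static (relative range < 5%), else neither.  The thresholds are
  package-defined conventions.
- **Degeneracy search**: phenotypes within a relative tolerance (default
  1%, 5% for the existence check) of a reference value of one aggregate
  metric form a group; the within-group spread of every phene is
  reported on the batch min–max scale.  Groups whose spread exceeds 0.5
  are phenotypes that an aggregate metric cannot tell apart although
  their phenes differ by more than half the population range.

## Synthetic data: what it does and does not emulate

The generator produces architecturally diverse, asymmetric bean- and
maize-like systems with realistic sizes (primary roots ~80–100 cm by day
40, thousands of laterals) and the qualitative species contrast
(topsoil-heavy maize with continually emerging nodal roots vs more
evenly distributed bean).  It does not model nutrient uptake, soil
heterogeneity, plastic responses, root mortality, secondary thickening
or second-order laterals, and its parameter ranges are configurable
conventions rather than measurements.  Passing tests therefore
demonstrate properties of the *measurement pipeline* (exact geometry,
rotation invariance, projection sensitivity, estimator convergence,
selection behaviour) — not claims about any real genotype.

## Problem sizes

Default analysis and test sizes are chosen so the full suite runs on one
CPU in minutes: batches of 50–500 phenotypes, snapshots at day 10–20 for
projection work (day 40 systems are an order of magnitude larger and are
exercised in the timecourse analyses), 18 views per phenotype, RF at
ntree = 200 / 50 repeats for the planted-signal checks.  All sizes are
parameters of the respective functions.

## Known limitations

- The LRBD estimator's k/(k−1) edge bias (documented above).
- 2D solidity is a proxy, not a volume ratio; its absolute level is not
  comparable to 3D solidity.
- FD estimates on sparse systems carry grid-discretisation noise of a
  few hundredths even in the canonical frame; comparisons finer than
  that are not meaningful.
- The elongation budget is a global scalar; it cannot reproduce
  class-specific carbon priority rules.
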