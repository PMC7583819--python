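# Methods

This note documents the models and procedures implemented in
`crownlidar`, the defaults and why they were chosen, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Data model and coordinate conventions

Point clouds are columnar (x, y, z in metres, ASPRS-style class codes,
integer tree labels).  Rasters use half-open cells:
`col = floor((x − x_min)/res)`, row 0 at the southern edge; no-data is
NaN in memory and −9999 in the ESRI ASCII grid files.  All file formats
are plain text (CSV, optionally gzipped, and .asc grids) so artifacts
are diffable and portable.

## Preprocessing

**Noise removal.**  Isolated points are those with fewer than
`min_neighbors` (default 4) other returns within a 5 m search radius —
implemented via the k-th-nearest-neighbour distance, which is the same
predicate at a fraction of the cost at high point density.  The filter
is single-pass: neighbour counts refer to the input cloud.  (On
LiDAR-density clouds the pass is idempotent; on adversarial sparse
clouds a second pass could remove more points.)  Air points are removed
above the 99.9th height percentile + 10 m and low points below the
per-cell (2 m) 1st height percentile − 1 m; the 1st percentile tracks
the lowest genuine returns even under a dense crown, where any higher
quantile sits inside the crown.

**Ground and normalization.**  A deliberately simple terrain model
replaces full progressive-TIN ground filtering: per-cell (2 m) minimum
points seed a Delaunay TIN, and points within ±0.3 m of the surface are
ground.  Seeds that sit more than 1 m above the median of their
neighbouring seeds are discarded — a cell fully occluded by a crown
would otherwise seed the TIN inside the canopy.  This suits gentle
terrain (≤ ~25° slopes) with reasonable ground visibility; it is not a
substitute for a production ground filter on steep or complex terrain.
Heights are normalized by subtracting the TIN elevation (nearest-
neighbour extrapolation outside the seed hull, logged); negative
residuals clip to 0.

**CHM.**  Cell value = maximum normalized height per cell at 0.25 m
resolution (≥4 cells across a ~1.1 m mean crown radius).  Interior
empty cells are filled iteratively with the 3×3 median of their
non-empty neighbours (a light-weight pit-free scheme); cells outside
the point footprint stay no-data.

## Crown delineation (RHCSA)

The CHM is cut by horizontal planes from its maximum down to
`min_tree_height` (2 m) in `level_step` = 0.1 m steps.  Cross-section
regions (8-connected components of CHM ≥ cut) are *tracked* across
levels:

* no predecessor region → new marker at the region's maximum cell;
* one predecessor → the region grows;
* several predecessors that sat in **distinct** regions at the previous
  cut → a merge event.  If the union's compactness 4πA/P² is at least
  `circularity_threshold` (0.5) the union is one crown and only the
  marker with the greatest apex height survives (ties: earlier level,
  then row-major order); otherwise the union is split by
  marker-controlled watershed on −CHM seeded at the markers.

Two timing properties make the 0.5 threshold work.  At a 0.1 m step,
two distinct crowns meet while their sections *barely touch*, and the
compactness of two equal tangent disks is exactly 1/2 — so tree–tree
merges fall below the threshold.  A branch bump joins its parent as a
pimple on a disk and scores ≈0.7 — above it.  The test fires only at
the merge event: re-testing the same union as it grows would reclassify
overlapping neighbours (compactness 0.67–0.73 once overlapped) as one
crown and collapse dense stands.

The perimeter in 4πA/P² is the marching-squares boundary smoothed by
two Chaikin corner-cutting passes.  Raw cell-edge counting is a
taxicab length that caps a disk's score at ≈0.62; the smoothed boundary
is asymptotically exact for smooth shapes (rasterized disk ≈ 0.91,
square ≈ 0.82, 1×20 line ≈ 0.15).  Hole boundaries count toward the
perimeter, so porous multi-crown unions score low.

After the final cut each label is refined by a binary opening (disk,
radius 1 cell); the component containing the marker survives (the
largest, if the opening removed the marker cell), and regions smaller
than 5 cells are dropped.  Per-tree point clouds take the label of the
CHM cell below each point, over all heights.

Known limitation: trees without a distinct protrusion on the CHM
(suppressed trees, flat deciduous crowns) are not detected — inherent
to CHM-based delineation.

## Crown metrics

CBH uses the vertical point-count profile in 0.5 m bins anchored at
z = 0: percentages Np = 100·nᵢ/N are smoothed with a 3-tap Gaussian
(σ = 0.5 bins, edge-renormalized) and the CBH is the lower edge of the
first **non-empty** bin, scanning upward, whose smoothed share reaches
p = 1%.  Two choices here deserve a note.  σ = 0.5 is the conventional
3×1 Gaussian; a σ = 1 kernel leaks 27% of the crown-base bin's mass
into the bin below and systematically trips the threshold half a bin
early (recovery tests: 75% of trees within 0.5 m at σ = 1 versus 100%
at σ = 0.5).  The non-empty guard exists because a bin holding zero
returns cannot be the crown base, however much smoothing leaks into it.
Trees with fewer than 10 points are rejected.

TH is the maximum height, the apex its (x, y); CL = TH − CBH.  LCR is
the mean distance from the *vertices* of the 2-D convex hull of the
crown projection (points with z ≥ CBH) to the apex — hull vertices, not
all boundary points.

## Profile points

Each crown is collapsed about the vertical axis through its apex.
Bins of 0.5 m run from the tree top down (half-open,
[TH−(k+1)·0.5, TH−k·0.5)); per bin, the 90th/95th/99th percentiles of
the horizontal distances (linear interpolation between closest ranks —
documented so downstream comparisons are reproducible) estimate OR.
The bin's representative depth is its midpoint; a bin emits nothing
with fewer than 3 points (guards against single-return bins).
RDINC = DINC/CL, clipped to [0, 1].  The upper (light) crown is the
subset at depths up to the largest observed OR (ties → smallest depth),
per tree and percentile.

## Profile models and fitting

All four families satisfy OR(0) = 0 (for the beta family when its
shape exponents exceed 1; it is evaluated by continuity at the interval
ends, via log-gamma for stability).  Fitting is trust-region nonlinear
least squares from five deterministic starts, exploiting linear
substructure: the parabola is linear in its parameters (its first start
is the exact least-squares solution), and the power/beta radial scales
are linear given fixed shape exponents.  Convergence tolerances are
1e−12 with up to 500·p function evaluations; the beta shape `a` is
bounded below by 1 so the curve stays finite at RDINC = 1 (clipping can
place points exactly there).  Standard errors come from the Jacobian at
the optimum (σ̂²·(JᵀJ)⁻¹); a singular normal matrix is flagged and
yields NaN errors rather than failure.  R² = 1 − SSE/SST,
RMSE = √(SSE/n).

Cross-validation defaults to leave-one-**tree**-out, because profile
points within a tree share the same crown and are strongly correlated;
a literal leave-one-point-out mode is available.  MAE% omits points
with OR = 0.  Fold refit failures are skipped and logged.

The field-based reference profile (a Kozak-type equation in DBH,
CH = CL/TH and HD = TH/DBH with user-supplied coefficients a₁…a₆) is
implemented from a best-effort reading of its printed form, whose
typography is ambiguous in the source literature; it is exposed as a
pluggable callable so any alternative reading — or any reference curve
at all — can be injected wherever a profile callable is accepted.  This
package does not estimate a₁…a₆.

## Volumes

Solid of revolution: V = π·CL·∫₀¹ OR(x)² dx by adaptive quadrature
(relative tolerance 1e−8).  Each tree rotates its own curve (the fitted
family evaluated at that tree's LCR and CL); a pooled-curve variant
would ignore tree size.  The cone uses the measured LCR and CL; the
3-D hull volume comes from the convex hull of the crown points.
Pairwise paired t-tests are two-sided; zero-variance difference pairs
are reported as "no difference" explicitly instead of NaN.

## Tree matching

The average tree distance of a plot is √(area/n_reference) by default
(a mean nearest-neighbour rule is available).  Candidate pairs need
horizontal distance < 60% of that and height difference < 15% of the
tallest reference tree; conflicts resolve greedily by ascending
distance with each tree used once.  DA = 100·matches/n_reference.

## The synthetic stand: what it emulates, and what it does not

Defaults mirror a dense, even-aged larch plantation scanned from above:
jittered 2 m planting grid (≈2500 stems/ha), TH ~ N(9.7, 1.3²) m
truncated to [5.8, 13.0], crown ratio ~ N(0.55, 0.05²) in [0.40, 0.70],
LCR covariate 0.25 + 0.10·TH + N(0, 0.15²) m (giving ≈1.1–1.4 m crown
radii), true profile = the modified beta equation with plantation-scale
coefficients, 370 returns/m² of crown footprint, planar terrain at 5°
slope, ±3 cm ranging noise.  Crown returns are 80% near-surface / 20%
interior (a down-looking scanner sees mostly the canopy surface — this
is what lets a high width percentile track the true outer profile), and
surface density decays linearly to 30% at the crown base, emulating
occlusion of the lower crown.  Sparse stem returns (2 per metre of
stem), gridded ground returns and a few air/low blunders complete the
cloud; air blunders sit well above the tallest possible crown, as real
multipath/bird returns do.  A single seeded generator makes output
byte-identical per seed.

What passing tests on these stands demonstrate: the pipeline's stages
are internally correct (oracle equivalences), the delineation logic
separates touching conical crowns at realistic spacing, and profile
fitting recovers a known generating curve through the whole chain.
What they do not demonstrate: performance on real canopies with
asymmetric crowns, species mixtures, wind-blown or leaning stems,
understory vegetation, beam-divergence effects or true multi-return
waveforms — none of which the generator simulates.  Detection-accuracy
figures on synthetic stands are analogues at desk scale, not
reproductions of field campaign results.

## Problem sizes and runtime

The shipped test suite and the acceptance script run plots of 20×20 m
(≈100 trees, ≈250k points) and 50-tree separated stands (≈150k
points); the full pipeline takes a few seconds per stand on one core,
and the complete suite under a minute.  Larger plots scale roughly
linearly in point count (k-d tree queries and per-level labelling
dominate).

## Known limitations

* Ground model: grid-minimum + TIN; not robust on cliffs, buildings or
  very steep terrain.
* CBH is a point-distribution proxy, not the field "first living
  branch"; on sparse lower crowns it is biased toward the first dense
  layer.
* Crown delineation clips overlapping crowns at watershed boundaries,
  biasing LCR low in closed canopies.
* The beta family needs shape exponents above 1; profiles that stay
  wide at the very base (b₁ + b₂·LCR ≤ 1) sit on the bound.
* DBH is never estimated from the cloud; reference-model covariates
  must come from field tables.
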