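# crownlidar

Crown-profile modelling of plantation conifers from UAV-LiDAR point
clouds: individual-tree crown delineation, crown-metric extraction,
width-percentile profile points, nonlinear crown-profile equations and
crown volumes — with a seeded synthetic-stand simulator so the whole
pipeline is testable without field data.

## The problem

The crown profile — the outer crown radius *OR* as a function of depth
below the tree tip — controls light interception, growth and biomass,
but measuring it traditionally requires felling trees and measuring
branches.  A UAV-borne laser scanner flying above a stand returns a
dense point cloud (hundreds of points/m²) from which crown shape can be
recovered non-destructively.  This package implements that chain for
dense, even-aged conifer plantations (≈2400–3200 stems/ha):

1. **Preprocess** — remove air/low/isolated noise returns, classify
   ground with a grid-minimum + TIN surface, normalize heights above
   ground, and rasterize a pit-filled canopy height model (CHM).
2. **Segment (RHCSA)** — slice the CHM from top to bottom with
   equidistant horizontal planes, tracking the cross-section regions:
   a region that appears with no predecessor is a candidate tree top
   (*marker*); when tracked regions merge, a near-circular union means
   a branch artifact (drop the lower marker) while an irregular union
   means touching trees (marker-controlled watershed split).
3. **Crown metrics** — per tree: tree height TH (highest return),
   crown base height CBH (the height where the 0.5 m-binned vertical
   point-share profile, Gaussian-smoothed, first reaches 1%), crown
   length CL = TH − CBH, and the largest crown radius LCR (mean
   distance of the 2-D convex-hull vertices of the crown projection
   from the apex).
4. **Profile points** — collapse each crown about the vertical axis
   through its apex to (distance, height) pairs, slice into 0.5 m bins
   from the tip down, and take the 90th/95th/99th percentile of the
   distances per bin as the outer-radius estimate, at relative depth
   RDINC = DINC/CL ∈ [0, 1].
5. **Profile models** — fit four no-intercept equations by nonlinear
   least squares, with LCR as a per-tree covariate (x = RDINC,
   L = LCR):

   | family | equation |
   |---|---|
   | parabola | OR = (a₁ + a₂L)·x + b·x² |
   | Mitscherlich | OR = a·(1 − e^(−(b₁+b₂L)·x)) |
   | power | OR = (a₁ + a₂L)·x^(b₁+b₂L) |
   | modified beta | OR = (c₁ + c₂L)·(1−x)^(a−1)·x^(b₁+b₂L−1) / B(a, b₁+b₂L) |

   with R²/RMSE, leave-one-out cross-validation (MPE, MAE, MAE%), and
   upper-crown refits (points above the depth of the largest radius).
6. **Volumes** — crown volume by solid of revolution
   V = π·CL·∫₀¹ OR(x)² dx, compared per tree against the geometric cone
   (radius LCR, height CL) and the 3-D convex hull, with paired
   t-tests.
7. **Validation** — 1:1 matching of detected to reference trees
   (distance < 60% of the average tree spacing, height difference
   < 15% of the tallest tree), detection accuracy DA, and agreement
   statistics (Pearson ρ, RMSE, Bias and relative forms).

The synthetic-stand generator (`crownlidar.generate_stand`) emulates
the target data: jittered 2 m planting grid, heights ≈ 9.7 ± 1.3 m,
crown ratios ≈ 0.55, ~370 returns/m² sampled on and inside a solid of
revolution of a known profile, with return density decaying toward the
crown base (occlusion) — and records full ground truth per point and
per tree.

## Worked example

```python
import crownlidar as cl

cfg = cl.well_separated_config(n_trees=25, spacing=5.0, seed=42)
cloud, truth = cl.generate_stand(cfg)

normalized, chm = cl.preprocess(cloud)
segments = cl.rhcsa_segment(chm)
labeled = cl.extract_crown_points(
    normalized.select(normalized.classification != cl.CLASS_GROUND), segments)
metrics = cl.metrics_table(labeled)

points = cl.build_profile_points(labeled, metrics)
fit = cl.fit_profile(points[points["percentile"] == 95], "beta")
print(f"beta (entire): R2={fit.r2:.3f}  RMSE={fit.rmse:.4f} m  n={fit.n}")

detected = segments.tree_table().rename(
    columns={"apex_x": "x", "apex_y": "y", "apex_height": "TH"})
match = cl.match_trees(detected, truth.trees, cfg.extent[0] * cfg.extent[1])
print(f"detection accuracy: {match.detection_accuracy:.1f}%")
```

prints

```
beta (entire): R2=0.735  RMSE=0.1891 m  n=290
detection accuracy: 100.0%
```

i.e. all 25 simulated crowns are found, and the refitted modified beta
equation explains 74% of the variance in the 290 extracted
95th-percentile crown radii with a residual scatter of 0.19 m.
Per-tree metrics land in a DataFrame (`TH`, `CBH`, `CL`, `LCR`, apex
coordinates), and `cl.volume_of_revolution(lambda x: fit.predict(x, L),
CL)` turns any fitted curve into a crown volume in m³.

The same stages are available as a shell tool:

```bash
crownlidar simulate --seed 42 --out sim/
crownlidar run --config pipeline.yaml          # preprocess ... volumes
crownlidar fit --points profile_points.csv --family beta --cv by_tree
```

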