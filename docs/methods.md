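# Methods

## Overview

`streetgreen` quantifies street-level green-space exposure and its
socioeconomic inequity at the community scale.  The pipeline has five
stages: per-point Green View Index (GVI) from labelled street imagery;
community-level exposure within walking-time buffers; a location-quotient
inequity score; and bivariate global/local Moran's I between rental price
and neighbourhood greenness with permutation inference.  A synthetic-city
generator supplies every input with known ground truth.

All coordinates are planar metres in a projected CRS; no spherical
geometry is used anywhere.  Buffers are therefore exact Euclidean
distances.

## Green View Index

A sample point's GVI is the pooled vegetation fraction over its views:

    GVI = sum_n green_n / sum_n total_n

i.e. a **ratio of sums**, not a mean of per-view ratios.  The two
coincide when views are equal-sized (the usual case for API imagery of a
fixed resolution); the ratio of sums is canonical here because it is
well-defined for unequal view sizes and weighs every pixel equally.  A
dedicated test fixture (one 100-px all-green view plus one 300-px
non-green view → GVI 0.25, not 0.5) pins the convention.

Semantic segmentation is *not* part of this package: the contract is
"label rasters in, GVI out", so any segmenter's output can be ingested
(PNG class raster + JSON palette).  For self-contained runs a rule-based
HSV classifier maps RGB pixels with hue in [0.17, 0.45], saturation
≥ 0.20 and value ≥ 0.10 to a binary green class.  These bounds bracket
vegetation hues (pure green = 1/3) while rejecting achromatic pavement
and sky; they are configurable (`HsvThresholds`).

Vegetation classes default to names {grass, tree, shrub},
case-insensitive.  Quality control is an explicit exclusion-list plus a
minimum-view rule (default 4 of 4 views present); excluded points carry
no GVI and never reach later stages.

## Walking-buffer exposure

Buffer radius is `minutes × walking_speed` with the 15-minute-city
walking speed of 72 m/min, giving 360/720/1080/2160 m for the standard
5/10/15/30-minute buffers.  Each community polygon is buffered outward
(Minkowski sum with a disc; interior retained) and its exposure is the
*unweighted* arithmetic mean GVI of all kept points inside or on the
buffer.  Points exactly on the buffer boundary count as inside — a
deterministic tie rule.  A community×buffer cell with no point is
*missing*, never zero; missing communities are dropped listwise from the
inequity and Moran stages with a logged count.

## Location entropy

    LQ_i = (GVI_i / price_i) / (sum_j GVI_j / sum_j price_j)

computed per buffer distance (the denominator uses that buffer's
community GVIs).  LQ is invariant to a common rescaling of all prices or
all GVIs, and satisfies the exact identity Σ LQ_i·price_i / Σ price = 1
(asserted to 1e-12 on every computation as a self-check).  Summary bins
are half-open and lower-inclusive — [0, 0.2), [0.2, 0.5), …, [5, ∞) —
because the conventional printed labels ("0.2–0.5", "0.5–1.0") overlap
at the edges; lower-inclusive half-open bins are exhaustive and
reproducible.  Percentages are rounded half-up to two decimals.
Aggregate shares for the "very low" (LQ < 0.5) and "high" (LQ > 2)
groups are reported alongside.

## Bivariate Moran's I

Global statistic (z-scores with the sample, n−1, standard deviation):

    I = N · Σ_i Σ_{j≠i} w_ij z_i^P z_j^A / ((N−1) · S0)

Local statistic:

    I_i = z_i^P · Σ_j w_ij z_j^A

The local form includes the focal z_i^P factor — the bare lag alone
cannot produce quadrant classifications or satisfy the local-to-global
identity N·Σ I_i/((N−1)·S0) = I, which holds to 1e-12 and is asserted in
tests.  The lag is still reported per unit.  The (N−1) normaliser is
consistent with the sample-sd standardisation: with row-standardised
weights the A = P case reduces exactly to the textbook univariate
Moran's I (cross-checked against an independent dense implementation).

**Weights.** Queen contiguity over the community polygons (shared edge
or vertex, snap tolerance 1e-6 m), row-standardised — the common default
for irregular lattices; k-nearest-neighbour weights (ties broken by
lower id) are available for sensitivity analysis.  Islands are kept as
zero rows, excluded from N and S0, and logged.

**Inference.** Global: the greenness vector is permuted across units
(999 permutations by default); pseudo p = (1 + #{|I_perm| ≥ |I_obs|}) /
(1 + n_perm), two-sided.  Local: conditional permutation — unit i's own
value is held fixed and its neighbours' values are drawn from the other
n−1 units; a single (n_perm × k_max) index pool is shared across units,
which preserves the per-unit null while keeping the cost at one argsort.
Quadrants are assigned to *all* units from (sign z_i^P, sign lag_i) with
zero classified as "High" (a documented tie-break); the significance
flag subsets them at α = 0.05 with no multiplicity correction by default
(a BH-FDR option exists), matching common LISA mapping practice.

## Synthetic city

The generator emulates the statistical structure of a mid-sized Chinese
downtown study area:

* **Streets:** a square grid with 200 m spacing over a 12 × 12 km extent,
  vertices jittered by 0.15 × spacing for organic irregularity.  Sampling
  every 200 m of arc length yields ≈ 7.5k sample points, the magnitude of
  a real street-view sampling campaign at that interval.
* **Greenery surface:** deterministic trend + kernel-smoothed white
  noise, clipped to [0, 1].  The default is a radial Gaussian bump
  (amplitude 0.25, scale 4 km) over a 0.10 base — a greener old-city
  core decaying toward the periphery — plus smooth noise (sd 0.05,
  length scale 800 m).  This emulates the centre–periphery gradient of
  street greenery; it does not model seasons, occlusion or camera optics.
* **Views:** four label rasters (40 × 40 px by default) per point whose
  pooled green-pixel count is exactly `round(f × 4·H·W)` for planted
  fraction f, so the GVI stage can be verified bit-exactly.
* **Communities:** Voronoi cells of 499 uniform seed points, clipped to
  the extent (mirror-point construction, so the tessellation is exact);
  pairwise interior-disjoint by construction.
* **Prices:** `price_i = α + β·(W·gvi)_i + ε`, ε ~ N(0, σ²), floored at
  1 currency-unit/m² (location entropy divides by price).  Defaults
  α = 30, β = −40, σ = 3 currency-units/m², calibrated once to a
  plausible rental range (≈ 15–35/m²) with a clear but noisy negative
  greenness association; β = 0 gives the exact null, β > 0 the reverse
  pattern.  Prices are planted on the 15-minute-buffer greenness lag.

Everything is deterministic under one master seed; per-stage seeds are
derived from the master seed and the stage name.

What passing tests on this generator do **not** show: real street-view
segmentation accuracy, network-distance (isochrone) accessibility,
seasonal imagery effects, or any property of a specific real city.

## Simulation studies

* **Calibration:** type-I error of the global permutation test under the
  null — independent standard-normal price and greenness on a 10 × 10
  queen lattice, 500 replicates × 999 permutations; the rejection rate at
  α = 0.05 must fall in [0.03, 0.07] (binomial 3-sigma band around 0.05).
* **Recovery:** 200 replicates at the reference scale (499 communities)
  with the default planted β = −40; detection = I < 0 and pseudo p ≤ 0.05.
  Community geometry, point-buffer membership and weights are fixed
  across replicates — they are deterministic study conditions — while
  the greenery noise field and price noise are redrawn each replicate.
  Point greenness enters as the planted surface value directly; the
  imaging round-trip reproduces it exactly up to pixel quantisation
  (≤ 1/6400) and is verified separately, so re-rendering 30k images per
  replicate would add cost without information.  The 15-minute buffer
  (the concept's titular distance) is the reference for this study.

## Numerical conventions and degenerate inputs

* Point dedup at street crossings: exact coordinate equality after
  rounding to 1e-6 m.
* Constant price or greenness vectors raise (Moran undefined), as do
  non-positive prices (named by community) and zero total GVI.
* Missing values are empty CSV fields, never sentinels.
* Pseudo p-values are never zero by construction (the +1 convention).

## Limitations

* Buffers are Euclidean, not network-distance isochrones.
* The HSV classifier is a deliberately simple stand-in; for real imagery
  use a semantic segmenter and ingest its label rasters.
* GVI is a single pooled vegetation fraction; green-space types are not
  subdivided.
* The exposure means are unweighted by street-segment length; communities
  with missing buffers are dropped listwise rather than imputed.
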