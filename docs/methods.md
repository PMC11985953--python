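# Methods

## Model

`hmod` estimates the per-pixel degree of human modification *H* ∈ [0, 1] of
terrestrial land. Each threat *t* contributes *H*<sub>t</sub> =
*F*<sub>t</sub> × *I*<sub>t</sub>, where the footprint *F*<sub>t</sub> is
the fraction of the pixel physically or functionally occupied by the
threat and the intensity *I*<sub>t</sub> is a unitless weight for the
per-unit-area severity of the land use, derived from landscape-development
-intensity coefficients. Threats aggregate with the increasive mean
*H* = 1 − ∏(1 − *H*<sub>t</sub>), whose key properties (bounded by 1,
≥ max, ≥ arithmetic mean, ≤ sum of inputs; permutation-invariant; monotone
in every argument; all-zero layers neutral) are enforced by property tests.

The assumption behind the fuzzy sum is that threat layers are partially
dependent — the same hectare of conversion often appears in several source
datasets — so plain addition would double-count. Two deliberate
exceptions:

- **Road types** (highway, secondary, residential, two-track, rail) occupy
  physically disjoint corridor strips within a pixel, so their *H* values
  are *summed* and capped at 1.
- **Agriculture** (cropland 2.1, plantations 2.2, pasture 2.3) uses the
  pixel-wise *maximum*: the three footprints are built from sources of
  different native resolutions and overlap spatially, and the fuzzy sum
  would overstate modification where they describe the same field.

## Threat registry

The registry (`hmod/data/registry.yaml`) binds each of the 16 threats to
its class code, intensity estimate(s) and availability flags. Intensity
bounds are ±10 % around the best estimate unless an independently
estimated range exists (e.g. railways 0.76 with max 0.84). Two standard
subsets: `current` (all 16 threats) and `timeseries` (12 threats —
tourism/recreation 1.3, mining 3.2, roads/railways 4.1 and solid waste 9.4
have no multi-year sources and are flagged `in_timeseries: false`).
The registry is data-driven so regional studies can supply their own
intensities without code changes.

## Footprint builders and their parameters

**Built-up (1.x).** Source fractions (settlement-structure, impervious
surface, built-up land cover) fuse with the weighted fuzzy sum
*F* = 1 − ∏(1 − *f*<sub>i</sub>·*w*<sub>i</sub>), weights 0.9/0.8/0.8
reflecting classification accuracy. The fused surface is partitioned into
residential / commercial / tourism by land-use polygon overlay (pixel
centers; commercial takes priority over tourism where polygons overlap —
the ordering is a documented choice). Partition conserves mass exactly.

**Cropland (2.1).** Four-source weighted fusion (weights 0.9/0.5/0.3/0.5;
the two-source 0.9/0.5 subset for time-series runs), then two filters:
pixels within 1 km (Euclidean, pixel centers) of an urban-class pixel are
zeroed (urban parks misread as cropland), and primary-source cropland
above the per-region 99th percentile of cropland-pixel elevations is
removed (alpine commission errors). Regions are caller-supplied ids; the
published fixed per-continent cut-offs (2575/2319/2365/3407 m) ship as
optional constants. Cropping-rotation intensity (single/double/triple →
0.39/0.53/0.67) fills nodata with the modal class within a 20 km window
(per-class counts via FFT convolution; ties to the lower class), then
mean-smooths with a 2-pixel circular window. The smoothing radius is
configurable because a "2-pixel ≈ 20 km" window is resolution-dependent.

**Plantations (2.2).** Mask × canopy-cover fraction; intensity 0.30 for
tree crops, 0.06 for planted forest.

**Pasture (2.3).** Livestock density (animal units/km²) is capped at
1 000 au/km² (the grazing/industrial break-point) and square-root
transformed: *f*<sub>gp</sub> = √(min(d, 1000)/1000). The footprint is
the mean of *f*<sub>gp</sub> within each 8-connected patch of each grazing
land-cover class, broadcast to the whole patch ("sharpening"); pixels
crossed by highways are dropped from the average. Sparse-cover pixels
join the footprint only where their density lies within the central 95 %
([2.5, 97.5] % quantiles, pooled over grazed classes — sidedness and
pooling are documented choices) of densities on grazed classes.

**Transportation (4.1).** Lines are rasterized *fractionally*: per-pixel
F = (in-pixel length × corridor width) / pixel area, capped at 1, with
exact segment–grid intersection lengths. For a straight crossing this
reduces to width / pixel-size (40 m highway at 90 m → 4/9). The literal
width-over-pixel-width rule is generalized to length-weighting so
diagonal and partial crossings behave sensibly; the straight-crossing
case reproduces the published worked example. Default widths 40/20/15/5/
20 m and intensities 0.81/0.76/0.66/0.09/0.76 for highway/secondary/
residential/track/rail. Residential roads farther than 5 km from any
settlement pixel are re-typed as two-track (remote mis-attributions).
Per-type *H* values are summed and capped at 1.

**Kernels (3.1 flares/wells, 4.2 powerlines, 6.1 trails).** Linear-decay
cones evaluated at pixel centers: value peak·(1 − d/R), zero beyond R.
Flares/trails: R = 233 m, peak 1 (planar integral πR²/3 ≈ 0.057 km² per
well-head); powerlines: R = 250 m, peak 0.25 (positional uncertainty).
"Kernel width 250 m" is read as the decay radius; a full-width reading
(radius 125 m) is selectable. Overlapping kernels combine by per-pixel
maximum, not sum, so one land transformation is not double-counted.
Center-point evaluation is acceptable because R ≫ pixel size at the
resolutions used.

**Areal threats (3.2, 3.3, 7.2, 9.4).** Polygons contribute exact
per-pixel cover fractions (vectorized box–polygon intersection). Wind
turbines deposit 0.0014 km² into their containing pixel. Reservoir
polygons are buffered by 1 km then masked by open water (shoreline
modification without counting the water body itself); an exclusion list
drops misattributed natural lakes.

**Normalizations (4.2, 9.5).** Nightlights: DMSP digital numbers / 63
(sensor saturation); VIIRS log10(x+1) / 1.05 (global 95th percentile of
the transform). NO₂ column density / 3·10⁻⁴ (99th percentile). All
clipped to [0, 1].

**Forestry (5.3).** F = 1 where forest was lost in or before the mapping
year, stood ≥ 10 m tall in the 2000 baseline, and the loss year differs
from any burn year (fire loss is not harvest; an exact-year match is the
default, ±1 year configurable because detection-year offsets are common).
Loss is cumulative — regrowth is ignored — so the footprint is monotone in
the mapping year. Finer stacks aggregate to the output grid as exact
harvested fractions.

**Accessibility (6.1).** Population density is smoothed with a Gaussian
kernel (radius 2 km; implemented as σ = radius/2 so ~95 % of the weight
falls inside the stated radius, nearest-edge handling so uniform fields
are invariant). Pixels with smoothed density D > 1 get class
⌊ln D⌋; 8-connected patches of equal class carry z = ⌊ln(patch
population)⌋. The cost surface assigns minutes-per-km factors: on-feature
19/48/96/167/169/200 (highway/secondary/residential/track/rail/trail,
minimum rule where features overlap), water 167, and required off-road
land-cover factors (defaults 60 open, 120 forest, 200 wetland). Travel
time is multi-source Dijkstra over the 8-neighbour graph with edge weight
= step distance (km, diagonal ×√2) × mean of the endpoint costs — the
standard symmetric cost-distance convention. One travel-time field per
z-group (sources = all pixels of the group) keeps the computation linear
in the number of groups. Accessible population
P = Σ<sub>z</sub> e^z · 0.5^(T_z/30) halves per 30 minutes traveled; the
printed form of the accumulation ("exp(z) × T") is implemented as the
decay transform, since literal multiplication by minutes would grow with
distance and contradict the stated halving. F_h = min(1, P/12.0) — the
normalizer is taken as given (≈ 90th percentile globally, a town of
~100 000) — then fuzzy-combined with trail cone kernels (peak 1.0 before
the 0.09 intensity; the peak is configurable as the source value is
unstated).

## Derived products

- **Dominant threat**: arg-max over per-class H where any H > 0; all-zero
  pixels are nodata; ties break to the lowest taxonomy code (documented —
  no published tie rule exists).
- **Modification classes**: very low / low / moderate / high / very high
  at breakpoints 0.01 / 0.1 / 0.4 / 0.7. Bins are half-open [lo, hi) with
  the top bin closed at 1; published interval labels overlap at the edges
  without an edge rule, so the half-open reading is a documented choice.
  Area fractions over valid pixels sum to 1 (±1e−9).
- **Zonal summaries**: per-zone mean, population SD (divide by n — the
  convention is unstated upstream), pixel count and area.
- **Temporal change**: annual rate (%) is the *linear* mean annual change
  relative to the start mean, 100·((m_end − m_start)/m_start)/years.
  This formula reproduces the published per-class rates from their printed
  endpoint means exactly at 2-decimal rounding (e.g. 0.0566 → 0.0607 over
  30 years = 0.24 %/yr); a geometric rate does not. Changed-area fraction
  counts pixels with ΔH > 0.01. A zero start mean leaves the rate NaN.
- **Monotone series**: permanent-infrastructure footprints (wells,
  nightlit areas) are constrained to a running per-pixel maximum over
  years.

## Uncertainty and validation

**Intensity Monte Carlo.** Each draw samples every threat's intensity
uniformly between its min and max bound — one scalar per threat per draw
(global perturbation; per-pixel draws are out of scope) — and recombines
the cumulative surface. Outputs are per-pixel mean and SD across n draws
(default 100), accumulated around the first draw so degenerate ranges give
an SD of exactly 0. Deterministic under a seed.

**Confusion-matrix resampling.** Each pixel's land-cover class is redrawn
from the confusion-matrix row of its predicted class, independently per
pixel (spatially unstructured error — a strong assumption, stated as
such), and a caller-supplied summarizer is re-run per realization; results
reduce to per-zone mean and SD. An identity matrix reproduces the input
exactly.

**Reference plots / RMSE.** Weighted RMSE of the surface against point
observations. The synthetic plot generator samples stratified by
modification class and adds clipped Gaussian noise; with truth away from
the [0, 1] bounds the measured RMSE recovers the injected noise SD, and
near the bounds it matches the truncated-noise expectation (both tested).

## Synthetic landscapes

The generator emulates the *structure* of the real inputs: land cover as
Gaussian-smoothed white noise thresholded at class-mixture quantiles
(contiguous patches, exercising the patch logic); settlements as Gaussian
population kernels with log-populations drawn from a configured range,
which also seed built-up fractions, nightlights and NO₂ halos; roads as
wiggly cross-grid polylines per type; wells, turbines and land-use
polygons placed uniformly; forest loss accruing at a configured annual
fraction with a share of loss years coinciding with fires. One seed fixes
everything; identical configs yield bit-identical bundles. Default grid
256 × 256 at 90 m so the full pipeline runs in seconds; tests use 32–48
pixel grids. What the generator does **not** emulate: real geography,
spatial error correlation of specific source products, OSM attribute
noise, or sensor artifacts — so passing tests demonstrate correctness of
the computation, not accuracy against real-world data.

## Numerical choices and limitations

- Nodata (NaN) propagates: any nodata input makes the output pixel
  nodata; nodata is never encoded as 0.
- Fractional aggregation requires evenly nesting grids (enforced), as in
  10/30 m sources aggregated to 90/300 m outputs.
- Fuzzy-sum round-off is clipped into [0, 1]; F/H layers validate their
  range on construction.
- Line rasterization is exact per segment (grid-line parameter splitting);
  conservation of length × width holds to well under 0.5 %.
- Reprojection between coordinate systems, map rendering, and
  planetary-scale tiling are out of scope; grids carry an opaque CRS tag.
- The toolkit reproduces desk-scale mechanisms; published global summary
  statistics depend on the real global source datasets and are not
  reproducible from synthetic inputs.
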