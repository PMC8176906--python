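# Methods

`lcvmap` implements a landscape-conservation-value (LCV) workflow for
volcanic-island terrain: landform classification from a DEM, a landform ×
land-cover landscape typology, expert-survey value aggregation, value
mapping, and a focal-heterogeneity susceptibility analysis. This note
documents the models, the tunable parameters, the numerical choices, and
what the synthetic data do and do not establish.

## Terrain derivatives

All terrain analysis operates on a rectangular, north-up grid of square
cells of edge `b` meters (30 m by default, the resolution at which the
landform scheme was designed to operate).

**Slope** is the central-difference gradient magnitude converted to
degrees (one-sided differences at grid edges), `atan(|∇z|)`.

**Upslope contributing area.** Each cell's specific catchment area is

    AS = (1/b) · ( Σ_i p_i · A_i + A_self )

where the sum runs over all upslope cells `i`, `A_i` is the cell area
(`b²`, constant), and `p_i` is the fraction of cell `i`'s accumulated
drainage that reaches the target cell through the flow partition. Dividing
by the contour width `b` makes `AS` a length (meters); the self-area term
means a cell with no inflow has `AS = b` exactly, which keeps threshold
comparisons well defined everywhere. `AS` proxies the potential flux of
water and material through a cell.

*Flow partition.* Two partition rules are provided. D8 sends all flow to
the steepest-descent neighbor (ties broken by a fixed neighbor order:
NW, N, NE, W, E, SW, S, SE). MFD — the default — splits flow among all
strictly lower 8-neighbors proportionally to the descent slope toward
each, with diagonal center distances `√2·b`. MFD is the default because
the quantity of interest is a potential for material movement, which
disperses on real hillslopes, not a stream network per se.

*Depressions and flats.* Accumulation requires an acyclic flow graph, so
the DEM is first passed through a priority-flood epsilon fill: starting
from the grid boundary (and from cells bordering nodata, which act as
outlets), cells are popped lowest-first and every unvisited neighbor is
raised to at least the popped elevation plus ε = 1e-6 m. This raises every
depression to its spill level and imposes a monotone micro-gradient across
flats in a single pass, so every cell has a strictly descending path to
the boundary. Accumulation then processes cells in descending filled
elevation — a valid topological order because flow only moves to strictly
lower cells.

**Surface curvature** is the mean elevation drop per unit distance to the
8 queen neighbors:

    C_s = (1/n) · Σ_n (Z_self − Z_n) / d_n

with `d_n = b` for cardinal and `√2·b` for diagonal neighbors, and `n` the
number of neighbors that exist and carry data. Positive values are convex
(ridges, summits), negative concave (hollows, footslopes). A constant or
planar surface has `C_s = 0` in its interior; the statistic is exactly
antisymmetric under elevation negation. The 8-neighbor stencil is the
smallest symmetric one; nodata neighbors are simply dropped from the mean.

## Landform classification

Cells are first assigned a hillslope unit of the nine-unit landscape
model (NULM) by a fixed-priority decision cascade over (AS, slope,
curvature):

1. **channel** if `AS ≥ channel_upslope_min`;
2. **fall face** if `slope ≥ 45°`;
3. **summit** if the cell is an 8-neighbor local elevation maximum with
   `C_s ≥ summit_curvature_min` and `slope < flat_slope_max`;
4. **shoulder** if `C_s ≥ shoulder_curvature_min`;
5. **footslope** if `C_s ≤ footslope_curvature_max`;
6. **toeslope** if `slope < flat_slope_max`;
7. **backslope** otherwise.

Channel outranks everything because stream cells occur wherever drainage
concentrates, regardless of what the bare slope attributes would suggest.
The 45° fall-face bound and the 5° flat-slope bound are fixed literature
values; the remaining cutoffs default to quantiles of the grid's own
derivative fields, resolved at classification time:

| parameter | default | meaning |
|---|---|---|
| `summit_curvature_min` | 95th pct of `C_s` | sharpest convexities |
| `shoulder_curvature_min` | 80th pct of `C_s` | upper convex slopes |
| `footslope_curvature_max` | 20th pct of `C_s` | lower concave slopes |
| `fallface_slope_min_deg` | 45° | steep erosional faces |
| `flat_slope_max_deg` | 5° | flat land / gentle summits |
| `channel_upslope_min` | 99th pct of `AS` | drainage concentration |

Quantile defaults make every unit attainable on any terrain with relief,
and transfer across domain sizes. The channel default is a quantile for
the same reason: a fixed multiple of the median catchment area does not
transfer between a continental DEM and a few-thousand-cell island —
dispersive MFD routing on a small radial island tops out at an `AS` of
roughly nine times the median, so any large fixed multiple would silence
the unit entirely, while the 99th percentile keeps the channel share near
the ~1–2 % that volcanic-island stream networks occupy. All six cutoffs
are plain configuration (`NulmThresholds`) for users with calibrated
values.

The nine-unit provenance layer is retained; for mapping, units merge into
five final classes: backslope, fall face and footslope (the "mild slope"
of the six-class intermediate scheme) → **Slope**; toeslope (and the
never-firing interfluve) → **Flat land**; summit → **Summit**; shoulder →
**Shoulder**; channel → **Channel**. The footslope merge target is
configurable (`Flat land` is the alternative reading); Slope is the
default because footslopes are sloping, depositional surfaces.

## Landscape typology

The 5 landform classes × 7 land-cover classes (Ministry-style large
classes: Developed, Agriculture, Forest, Grassland, Wetland, Barren land,
Open water) cross into at most 35 landscape types. The pair code is
`landform·10 + landcover`, human-decodable without a lookup table. Inputs
must share footprint, cell size and origin — there is no implicit
resampling; an explicit nearest-neighbor helper is provided. Nodata in
either layer is nodata in the overlay. Area tabulation reports cells,
km², and proportions over the unmasked cells (summing to 100 % by
construction).

## Expert-survey aggregation

Each expert rates every land-cover class and landform class on a 1–5
Likert scale (1 very low conservation value, 3 standard, 5 very high) and
states, via pairwise comparison, the relative importance of one variable
over the other. Importance multiplies the ratings: ×1.75 "Very
Important", ×1.5 "Important", ×1.25 "Merely Important" and "Somewhat
Important", ×1.0 "Same". The two 1.25 weights reflect the only published
evidence for the "Somewhat Important" factor; the map is configurable.

An expert's score for a landscape type is the **product** of their
weighted land-cover and landform scores (a rank-1 7×5 matrix). The panel
matrix is the cell-wise mean across experts, then a single min-max rescale
onto [1, 10]:

    v ↦ 1 + 9·(v − min)/(max − min)

Min-max is the unique affine map placing the least valued type exactly at
1 and the most valued exactly at 10, matching the published endpoint
values; ties at either extreme are preserved. Rescaling after averaging
(rather than per expert) is the default order; per-expert rescaling before
the mean is available as a sensitivity variant (`rescale_each=True`).
Because the rescale is affine-invariant, uniform multiplicative weights
cancel; only the *relative* importance answers move the result.

A published 7×5 reference matrix produced by a 13-expert panel under this
scheme ships with the package
(`src/lcvmap/data/reference_lcv_matrix.csv`, loaded by
`load_reference_matrix()`): minimum 1.00 at Barren land × Flat land,
maximum 10.00 tied at Wetland × Summit and Open water × Summit. Whether
that panel rated the 35 types directly or through the unit-product
procedure is ambiguous in the source; both paths are implemented
(`aggregate_survey` for the product path, `LCVMatrix.from_csv` for any
directly elicited table) and neither is asserted as the original
procedure.

## Value mapping, zonal summaries, susceptibility

`apply_lcv_matrix` assigns each cell its type's matrix value (range
[1, 10] by construction). Zonal statistics use a cell-center-in-polygon
membership test (reproducible, no partial-cell weighting) and report mean
and SD per designated area plus a whole-site row. `focal_sd` computes a
moving-window SD (default 3×3 — the smallest window consistent with "a
cell and its surrounding cells"; any odd size is accepted), truncating the
window at grid edges, excluding nodata cells, and masking cells whose
window holds fewer than two valid values. Both zonal and focal statistics
use the **population** SD (divide by n), the common raster-GIS focal
convention; sample SD is a `ddof=1` switch away.

The susceptibility mask flags cells in the top band of focal SD: the
threshold is the linear-interpolation percentile (default 80th) of the
unmasked focal-SD values, and cells with `SD ≥ threshold` — ties included
— are flagged. Raising the percentile never grows the mask. High focal SD
marks places where high- and low-value landscape types sit side by side,
the configuration most exposed to spillover from development.

## Synthetic island generator

The generator emulates the study system — a shield-volcano island — well
enough to exercise every stage with known structure:

* **Relief**: a radially symmetric cosine-profile cone (400 m peak over a
  ~0.9 km radius on the default 64×64 grid of 30 m cells) dropping to sea
  level, sea cells at exactly 0.
* **Channels** (4 by default): angular-Gaussian grooves carved
  multiplicatively along random azimuths, so each bed still descends
  monotonically to the coast and drainage concentrates into it.
* **Oreums** (5 by default): secondary cones placed on the mid flanks
  with rejection-sampled separation, each sitting on a level pedestal at
  the local surface height (`z = max(surface, pedestal + cone)`) with its
  apex snapped to a cell center — so every oreum top is a symmetric
  strict local maximum with a gentle summit and steep convex flanks, as
  small volcanic cones read in a 30 m DEM.
* **Land cover** tracks elevation in seven bands (developed shoreline,
  agricultural lowland, grassland, forest belt, high barren slopes,
  summit wetland, crater open water) split at the septiles of the
  above-sea-level elevations, plus a seeded speckle (5 % by default) for
  within-band patchiness. The sea-level fringe falls into the developed
  coastal band.
* **Zones**: disjoint discs placed by seeded rejection sampling, standing
  in for designated protected areas.
* **Expert panel**: 13 experts by default; each rating is a latent class
  score plus Gaussian noise (SD 0.3 Likert units), rounded half-up and
  clamped to {1..5}. The default latent scores are the first-survey mean
  ratings of the published panel, so the simulated panel's latent ordering
  matches the published one. Each expert draws one pairwise importance
  category for land cover relative to landform.

Every generator is a pure function of its parameters and a single integer
seed; no global random state is touched, and identical calls are
bit-identical.

**What the synthetic data do not show.** The island is smooth and
noise-free by default: no measurement error, no terracing artifacts, no
hydrologically realistic drainage density, no spatially autocorrelated
land-cover patches, and the land-cover/elevation coupling is perfectly
monotone. Passing tests therefore demonstrate the correctness of the
computations and the coherence of the pipeline, not that the default
thresholds are well calibrated for any real DEM. Region-specific results
(area proportions, zone means, the focal-SD threshold value) depend on
the input data and are not reproduced here.

## Numerical choices and degenerate inputs

* Fill epsilon 1e-6 m; all distances in meters, row-major north-up grids,
  cell-center coordinates.
* D8 ties: first neighbor in the fixed scan order. MFD fractions sum to 1
  for any cell with a lower neighbor, 0 for pits and masked cells.
* Min-max rescale of a constant matrix raises a degenerate-range error
  rather than inventing a value.
* A constant focal-SD field makes the percentile threshold equal that
  constant and flags every unmasked cell (the degenerate but consistent
  reading of "top band, ties included").
* Grids smaller than 3×3, all-nodata inputs, even focal windows,
  percentiles outside (0, 100), non-increasing land-cover breaks, and
  unmapped NULM codes all raise typed errors naming the offending value.
* Problem sizes used throughout the tests and analysis scripts — 64×64
  grids, 6×6/8×8 oracle grids, 13–200-expert panels, 20 replicate seeds —
  are the package's reference study conditions; they keep every check
  exact or tightly seeded while exercising each code path.

## Known limitations

* The ninth unit of the nine-unit model has no decision rule here (the
  source scheme enumerates eight); the provenance layer stores whichever
  configured units fire.
* GeoTIFF support covers single-band north-up grids with pixel-scale/
  tiepoint georeferencing — no CRS metadata, tiling, overviews or
  compression.
* The flow router is for terrain attribution, not hydrology: no runoff,
  no watershed delineation, no channel geometry.
* Zonal membership by cell center makes zone areas quantized to whole
  cells; sub-cell polygons can cover zero cells (flagged, not errored).
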