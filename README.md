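# lcvmap

Landscape conservation value (LCV) mapping from terrain and land cover.

Conventional land-use planning regulates resources sector by sector and
leaves the surrounding landscape out of the decision. `lcvmap` implements
an integrative alternative for landscape ecologists, conservation
planners and GIS analysts: classify terrain into landform classes, cross
them with land cover into *landscape types*, attach an expert-elicited
conservation value to every type, and locate the cells where high- and
low-value landscapes collide — the places most susceptible to degradation
when development arrives.

## The method

1. **Landform.** From a DEM of cell size `b`, compute slope, surface
   curvature `C_s = (1/n) Σ_n (Z_self − Z_n)/d_n` (positive = convex),
   and the specific catchment area
   `AS = (1/b)(Σ_i p_i A_i + A_self)` with flow fractions `p_i` from
   multiple-flow-direction (or D8) routing. A fixed-priority cascade
   assigns each cell a hillslope unit of the nine-unit landscape model
   (channel ≻ fall face ≻ summit ≻ shoulder ≻ footslope ≻ toeslope ≻
   backslope), merged to five classes: Flat land, Slope, Shoulder,
   Channel, Summit.
2. **Typology.** Landform × land cover (7 Ministry-style classes) gives
   up to 35 landscape types per cell.
3. **Valuation.** Each expert rates every class on a 1–5 Likert scale;
   pairwise importance multiplies the ratings (×1.75 / ×1.5 / ×1.25 /
   ×1.0); a type's score is the product of its weighted land-cover and
   landform scores; the panel mean is min-max rescaled to
   `v ↦ 1 + 9(v − min)/(max − min)` so values span exactly [1, 10].
   A published 13-expert reference matrix ships with the package.
4. **Mapping.** Cells take their type's matrix value; designated areas
   get mean/SD summaries against the whole site; the 3×3 focal standard
   deviation of the value grid is thresholded at its 80th percentile to
   flag the top-20 % heterogeneity cells as susceptible.

A seeded synthetic volcanic island (cone, secondary "oreum" cones,
incised radial channels, elevation-banded land cover, simulated expert
panel) makes the whole workflow runnable and testable with no external
data. See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
synthetic island (seed 7), writing tables and grids under `results/`:

```sh
python analysis/01_simulate_island.py
python analysis/02_classify_landforms.py
python analysis/03_landscape_typology.py
python analysis/04_expert_survey.py
python analysis/05_conservation_map.py
```

`02_classify_landforms.py` resolves the terrain cutoffs from the island's
own derivative fields and reports every landform class:

```
resolved thresholds: summit curvature >= 0.3017, shoulder >= 0.0188,
footslope <= -0.0187, channel AS >= 1777 m
 landform  cells  share_pct
Flat land   1397  34.106445
    Slope   1988  48.535156
 Shoulder    664  16.210938
  Channel     41   1.000977
   Summit      6   0.146484
```

The six summit cells are the central apex plus the five oreum tops; the
channel strip (~1 %) follows the carved drainage lines. The overlay then
yields 30 of the 35 possible landscape types, and the simulated
13-expert panel reproduces the published value structure:

```
normalized panel matrix spans [1.00, 10.00]
minimum cell: Barren land x Flat land = 1.00
rank agreement with the published reference matrix: Spearman rho = 0.980
```

Finally `05_conservation_map.py` maps the values and flags heterogeneous
cells:

```
      zone  area_km2  mean_lcv       sd  cells
    zone_1    0.0702  4.687380 1.418588     78
    zone_2    0.0720  4.865170 2.494752     80
    zone_3    0.0675  1.726307 0.932450     75
whole site    3.6864  3.359259 2.347397   4096
focal-SD threshold at the 80th percentile: 1.348; 820 cells (20.0%)
flagged susceptible
```

Zones straddling the value gradient (zone_2) show the largest internal
SD; the susceptibility mask traces the boundaries where cheap and
precious landscape types meet.

The same pipeline is scriptable as one command (`lcvmap run --config
config.yaml`) or stage by stage (`lcvmap simulate|terrain|typology|
survey|lcv|susceptibility`); every run writes a JSON manifest with
per-output SHA-256 checksums, and identical configs reproduce identical
checksums.

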