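#!/usr/bin/env python
"""Simulate the study inputs: a volcanic island and its expert panel.

Writes the four inputs every later stage consumes — elevation, land cover,
designated-area polygons, and the expert rating table — under
results/island/, and prints what the island looks like.
"""

from pathlib import Path

import numpy as np

from lcvmap.grids import write_geotiff
from lcvmap.synth import (
    IslandParams,
    SurveySimParams,
    gen_dem,
    gen_landcover,
    gen_survey,
    gen_zones,
)
from lcvmap.zones import write_geojson

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "island"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = IslandParams(seed=SEED)
    dem = gen_dem(params)
    landcover = gen_landcover(dem, seed=SEED + 1)
    zones = gen_zones(dem, seed=SEED + 2)
    ratings = gen_survey(SurveySimParams(seed=SEED + 3))

    write_geotiff(OUT / "dem.tif", dem)
    write_geotiff(OUT / "landcover.tif", landcover)
    write_geojson(OUT / "zones.geojson", zones)
    ratings.to_csv(OUT / "survey.csv", index=False)

    rows, cols = dem.shape
    print(f"island grid: {rows}x{cols} cells at {dem.cell_size:.0f} m "
          f"({rows * cols * dem.cell_area / 1e6:.2f} km^2 footprint)")
    print(f"elevation: 0 - {dem.values.max():.0f} m "
          f"(peak parameter {params.peak_height:.0f} m, "
          f"{params.n_oreums} oreums, {params.channel_count} channels)")
    share = {landcover.legend[c]: (landcover.values == c).mean()
             for c in sorted(landcover.legend)}
    print("land cover shares:",
          ", ".join(f"{k} {100 * v:.1f}%" for k, v in share.items()))
    print(f"zones: {len(zones)} discs; panel: "
          f"{ratings.expert_id.nunique()} experts x "
          f"{ratings.item.nunique()} items")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
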