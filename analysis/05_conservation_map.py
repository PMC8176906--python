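#!/usr/bin/env python
"""Map conservation values, summarize zones, and flag susceptible cells.

Assigns each cell its landscape type's value from the panel matrix,
compares designated-area means against the whole island, and computes the
3x3 focal standard deviation whose top-20% band marks cells where high-
and low-value landscape types sit side by side. Outputs under
results/conservation/.
"""

import json
from pathlib import Path

from lcvmap.grids import read_geotiff, write_geotiff
from lcvmap.lcv import apply_lcv_matrix, focal_sd, susceptibility_mask, zonal_lcv_stats
from lcvmap.survey import LCVMatrix
from lcvmap.zones import read_geojson

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "conservation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    types = read_geotiff(ROOT / "typology" / "types.tif")
    matrix = LCVMatrix.from_csv(ROOT / "survey" / "panel_matrix.csv")
    zones = read_geojson(ROOT / "island" / "zones.geojson")

    lcv = apply_lcv_matrix(types, matrix)
    stats = zonal_lcv_stats(lcv, zones)
    sd = focal_sd(lcv, window=3)
    result = susceptibility_mask(sd, percentile=80.0)

    write_geotiff(OUT / "lcv.tif", lcv)
    write_geotiff(OUT / "focal_sd.tif", sd)
    write_geotiff(OUT / "susceptibility.tif", result.mask_raster())
    stats.to_csv(OUT / "zonal_stats.csv", index=False, float_format="%.6f")
    (OUT / "susceptibility.json").write_text(json.dumps(
        {"percentile": result.percentile, "threshold": round(result.threshold, 6),
         "susceptible_cells": int(result.mask.sum()),
         "susceptible_share_pct": round(
             100.0 * result.mask.sum() / (~lcv.nodata_mask).sum(), 2)},
        indent=1))

    print(f"conservation value grid spans "
          f"[{lcv.valid_values().min():.2f}, {lcv.valid_values().max():.2f}]")
    print("zonal summary (mean value per designated area vs whole site):")
    print(stats.to_string(index=False))
    print(f"focal-SD threshold at the 80th percentile: {result.threshold:.3f}; "
          f"{result.mask.sum()} cells "
          f"({100.0 * result.mask.sum() / (~lcv.nodata_mask).sum():.1f}%) "
          f"flagged susceptible")
    print(f"outputs written to {OUT}")


if __name__ == "__main__":
    main()
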