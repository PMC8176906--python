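#!/usr/bin/env python
"""Derive landforms from the island DEM with the nine-unit model.

Computes slope, specific catchment area and surface curvature, classifies
each cell into a hillslope unit, merges to the five final landform
classes, and writes the grids plus a class-share table under
results/landforms/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lcvmap.grids import read_geotiff, write_geotiff
from lcvmap.legends import LANDFORM_LEGEND, NULM_LEGEND
from lcvmap.terrain import (
    NulmThresholds,
    classify_nulm,
    compute_derivatives,
    remap_landform,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "landforms"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dem = read_geotiff(ROOT / "island" / "dem.tif")
    derivs = compute_derivatives(dem, method="mfd")
    thresholds = NulmThresholds().resolve(derivs)
    nulm = classify_nulm(derivs, thresholds)
    landform = remap_landform(nulm)

    write_geotiff(OUT / "slope.tif", derivs.slope_deg)
    write_geotiff(OUT / "upslope_area.tif", derivs.upslope_area)
    write_geotiff(OUT / "curvature.tif", derivs.curvature)
    write_geotiff(OUT / "nulm.tif", nulm)
    write_geotiff(OUT / "landform.tif", landform.classes)

    n = (~landform.classes.nodata_mask).sum()
    shares = pd.DataFrame(
        [
            {
                "landform": name,
                "cells": int((landform.classes.values == code).sum()),
                "share_pct": 100.0 * (landform.classes.values == code).sum() / n,
            }
            for code, name in LANDFORM_LEGEND.items()
        ]
    )
    shares.to_csv(OUT / "landform_shares.csv", index=False, float_format="%.4f")

    print(f"slope: 0 - {derivs.slope_deg.values.max():.1f} deg; "
          f"catchment area: {derivs.upslope_area.values.min():.0f} - "
          f"{derivs.upslope_area.values.max():.0f} m")
    print("resolved thresholds: "
          f"summit curvature >= {thresholds.summit_curvature_min:.4f}, "
          f"shoulder >= {thresholds.shoulder_curvature_min:.4f}, "
          f"footslope <= {thresholds.footslope_curvature_max:.4f}, "
          f"channel AS >= {thresholds.channel_upslope_min:.0f} m")
    units = {NULM_LEGEND[int(c)]: int((nulm.values == c).sum())
             for c in np.unique(nulm.values[~nulm.nodata_mask])}
    print("hillslope units:", units)
    print(shares.to_string(index=False))
    print(f"all five final classes present: "
          f"{set(np.unique(landform.classes.valid_values())) == {1, 2, 3, 4, 5}}")


if __name__ == "__main__":
    main()
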