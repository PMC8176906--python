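"""Conservation-value mapping, zonal summaries and susceptibility analysis.

The type grid is turned into a value grid by matrix lookup; designated
areas get mean/SD summaries against the whole-site mean; and a moving-
window (focal) standard deviation of the value grid locates cells where
high- and low-value landscape types sit side by side — the top percentile
band (default 20 %) of focal SD is flagged as the susceptibility mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import convolve2d

from .errors import EmptyInputError, LegendError, ParameterError
from .grids import LandscapeTypeGrid, LCVGrid, Raster
from .legends import LANDCOVER_LEGEND, LANDFORM_LEGEND, decode_type
from .survey import LCVMatrix
from .zones import ZoneSet, contains_cell_centers

log = logging.getLogger(__name__)


def apply_lcv_matrix(types: LandscapeTypeGrid, matrix: LCVMatrix) -> LCVGrid:
    """Assign each cell the matrix value of its (landform, land-cover) type."""
    if not matrix.normalized:
        raise ParameterError("matrix must be normalized to the 1-10 scale")
    out = np.zeros(types.shape, dtype=np.float64)
    lut: dict[int, float] = {}
    for code in np.unique(types.values[~types.nodata_mask]).tolist():
        lf, lc = decode_type(int(code))
        if lf not in LANDFORM_LEGEND or lc not in LANDCOVER_LEGEND:
            raise LegendError(f"type code {code} does not decode to known classes")
        lut[int(code)] = matrix.value(LANDCOVER_LEGEND[lc], LANDFORM_LEGEND[lf])
    for code, value in lut.items():
        out[types.values == code] = value
    out[types.nodata_mask] = 0.0
    return types.like(out, nodata_mask=types.nodata_mask.copy())


def _population_sd(values: np.ndarray, ddof: int = 0) -> float:
    return float(np.std(values, ddof=ddof))


def zonal_lcv_stats(lcv: LCVGrid, zones: ZoneSet, ddof: int = 0) -> pd.DataFrame:
    """Mean and SD of the value grid per zone, plus a whole-site row.

    A cell belongs to a zone when its center falls inside the polygon.
    Zones covering no cell get a flagged row with NaN stats. ``ddof=0``
    (population SD) matches the focal-statistics convention; pass 1 for the
    sample SD.
    """
    rows = []
    cell_km2 = lcv.cell_area / 1e6
    for zone in zones:
        inside = contains_cell_centers(zone, lcv) & ~lcv.nodata_mask
        n = int(inside.sum())
        if n == 0:
            log.warning("zone %r covers no grid cells", zone.name)
            rows.append({"zone": zone.name, "area_km2": 0.0,
                         "mean_lcv": np.nan, "sd": np.nan, "cells": 0})
            continue
        vals = lcv.values[inside]
        rows.append({
            "zone": zone.name,
            "area_km2": n * cell_km2,
            "mean_lcv": float(vals.mean()),
            "sd": _population_sd(vals, ddof),
            "cells": n,
        })
    site = lcv.valid_values()
    if site.size == 0:
        raise EmptyInputError("value grid is all nodata")
    rows.append({
        "zone": "whole site",
        "area_km2": site.size * cell_km2,
        "mean_lcv": float(site.mean()),
        "sd": _population_sd(site, ddof),
        "cells": int(site.size),
    })
    return pd.DataFrame(rows, columns=["zone", "area_km2", "mean_lcv", "sd", "cells"])


def focal_sd(lcv: LCVGrid, window: int = 3, ddof: int = 0) -> Raster:
    """Moving-window standard deviation of the value grid.

    The window is ``window x window`` (odd, >= 3) centered on each cell and
    truncated at grid edges; nodata cells are excluded from the window
    statistics and a cell whose window holds fewer than 2 valid cells is
    nodata in the output. Population SD by default.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    valid = (~lcv.nodata_mask).astype(np.float64)
    vals = np.where(lcv.nodata_mask, 0.0, lcv.values.astype(np.float64))
    kernel = np.ones((window, window))
    n = convolve2d(valid, kernel, mode="same", boundary="fill")
    s1 = convolve2d(vals, kernel, mode="same", boundary="fill")
    s2 = convolve2d(vals**2, kernel, mode="same", boundary="fill")
    out_mask = lcv.nodata_mask | (n < 2)
    denom = np.maximum(n - ddof, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / np.maximum(n, 1.0)
        var = np.maximum(s2 / np.maximum(n, 1.0) - mean**2, 0.0) * (
            np.maximum(n, 1.0) / denom
        )
        sd = np.sqrt(var)
    sd[out_mask] = 0.0
    return lcv.like(sd, nodata_mask=out_mask)


@dataclass
class SusceptibilityResult:
    """Focal-SD field, the percentile threshold used, and the boolean mask."""

    focal_sd: Raster
    percentile: float
    threshold: float
    mask: np.ndarray

    def mask_raster(self) -> Raster:
        # coded 1/2 (not susceptible / susceptible); 0 stays the nodata code
        return self.focal_sd.like(
            self.mask.astype(np.int64) + 1,
            legend={1: "not susceptible", 2: "susceptible"},
            nodata_mask=self.focal_sd.nodata_mask.copy(),
        )


def susceptibility_mask(sd: Raster, percentile: float = 80.0) -> SusceptibilityResult:
    """Flag the top (100 - percentile) % focal-SD cells as susceptible.

    The threshold is the linear-interpolation percentile of the unmasked
    focal-SD values; cells at or above it (ties included) form the mask.
    """
    if not 0.0 < percentile < 100.0:
        raise ParameterError(f"percentile must lie in (0, 100), got {percentile}")
    vals = sd.valid_values()
    if vals.size == 0:
        raise EmptyInputError("focal-SD field is all nodata")
    threshold = float(np.percentile(vals, percentile))
    mask = (~sd.nodata_mask) & (sd.values >= threshold)
    log.info("susceptibility threshold at percentile %.1f: %.4f (%d cells flagged)",
             percentile, threshold, int(mask.sum()))
    return SusceptibilityResult(
        focal_sd=sd, percentile=percentile, threshold=threshold, mask=mask
    )
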