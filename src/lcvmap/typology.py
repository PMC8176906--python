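"""Landscape typology: landform x land-cover overlay and area tabulation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyInputError
from .grids import LandcoverGrid, LandformGrid, LandscapeTypeGrid, Raster
from .legends import (
    LANDCOVER_LEGEND,
    LANDFORM_LEGEND,
    decode_type,
    type_code,
    type_legend,
)


def overlay_types(landform: LandformGrid | Raster,
                  landcover: LandcoverGrid) -> LandscapeTypeGrid:
    """Thematic overlay of the two categorical layers into pair-coded types.

    The two grids must already share footprint, cell size and origin (use
    :func:`resample_nearest` first if they do not); nodata in either input
    is nodata in the output.
    """
    lf = landform.classes if isinstance(landform, LandformGrid) else landform
    if not lf.aligned_with(landcover):
        raise AlignmentError(
            f"landform {lf.shape}@{lf.origin} and landcover "
            f"{landcover.shape}@{landcover.origin} are not aligned"
        )
    mask = lf.nodata_mask | landcover.nodata_mask
    codes = lf.values * 10 + landcover.values
    codes = np.where(mask, 0, codes).astype(np.int64)
    return lf.like(codes, legend=type_legend(), nodata_mask=mask)


def tabulate_type_areas(types: LandscapeTypeGrid) -> pd.DataFrame:
    """Area and proportion of every occurring landscape type.

    Returns one row per type sorted by descending area, with columns
    ``landform, landcover, cells, area_km2, proportion_pct``; proportions
    are over the unmasked cells and sum to 100.
    """
    valid = types.values[~types.nodata_mask]
    if valid.size == 0:
        raise EmptyInputError("cannot tabulate an all-nodata type grid")
    codes, counts = np.unique(valid, return_counts=True)
    cell_km2 = types.cell_area / 1e6
    rows = []
    for code, count in zip(codes.tolist(), counts.tolist()):
        lf, lc = decode_type(int(code))
        rows.append(
            {
                "landform": LANDFORM_LEGEND[lf],
                "landcover": LANDCOVER_LEGEND[lc],
                "cells": count,
                "area_km2": count * cell_km2,
                "proportion_pct": 100.0 * count / valid.size,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["area_km2", "landform", "landcover"], ascending=[False, True, True]
    )
    return table.reset_index(drop=True)


def resample_nearest(src: Raster, template: Raster) -> Raster:
    """Nearest-neighbor resampling of ``src`` onto ``template``'s grid."""
    xs, ys = template.cell_centers()
    x0, y0 = src.origin
    cols = np.clip(((xs - x0) / src.cell_size).astype(int), 0, src.shape[1] - 1)
    rows = np.clip(((y0 - ys) / src.cell_size).astype(int), 0, src.shape[0] - 1)
    values = src.values[rows, cols]
    mask = src.nodata_mask[rows, cols]
    return template.like(values, legend=src.legend, nodata_mask=mask)


__all__ = [
    "overlay_types",
    "tabulate_type_areas",
    "resample_nearest",
    "type_code",
]
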