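"""Georeferenced raster container and GeoTIFF round-trip.

A :class:`Raster` is a rectangular, north-up, row-major grid of cell-center
values with a square cell size in meters, an origin at the top-left corner,
and an explicit nodata mask. Continuous grids (elevation, conservation
value, focal SD) are float; categorical grids (land cover, landform,
landscape type) are integer-coded and carry a ``{code: name}`` legend.

Files are single-band GeoTIFFs written through :mod:`tifffile` with the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA);
categorical grids get a JSON legend sidecar next to the .tif.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, InputError, LegendError

log = logging.getLogger(__name__)

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

FLOAT_NODATA = -9999.0
INT_NODATA = 0


@dataclass
class Raster:
    """A single-band georeferenced grid.

    Parameters
    ----------
    values
        2-D array of cell values (row 0 = northernmost row).
    cell_size
        Square cell edge length in meters (> 0). This is also the contour
        width ``b`` used when converting accumulated drainage area to a
        specific catchment area.
    origin
        (x, y) map coordinates of the outer corner of cell (0, 0).
    nodata_mask
        Boolean array, ``True`` where the cell carries no data.
    legend
        Optional ``{code: class name}`` mapping for categorical grids.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None
    legend: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise InputError(f"raster values must be 2-D, got {self.values.ndim}-D")
        if not self.cell_size > 0:
            raise InputError(f"cell_size must be > 0, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise InputError("nodata_mask shape differs from values shape")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area(self) -> float:
        """Cell area in m²."""
        return self.cell_size**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell center, each shaped like the grid."""
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    # -- convenience ------------------------------------------------------

    def masked(self) -> np.ndarray:
        """Values with nodata cells as NaN (float grids only)."""
        out = self.values.astype(float).copy()
        out[self.nodata_mask] = np.nan
        return out

    def valid_values(self) -> np.ndarray:
        """1-D array of the unmasked cell values."""
        return self.values[~self.nodata_mask]

    def like(self, values: np.ndarray, legend: dict[int, str] | None = None,
             nodata_mask: np.ndarray | None = None) -> "Raster":
        """A new raster on the same footprint with different values."""
        return Raster(
            values=values,
            cell_size=self.cell_size,
            origin=self.origin,
            nodata_mask=self.nodata_mask.copy() if nodata_mask is None else nodata_mask,
            legend=legend,
        )

    def copy(self) -> "Raster":
        return replace(
            self,
            values=self.values.copy(),
            nodata_mask=self.nodata_mask.copy(),
            legend=None if self.legend is None else dict(self.legend),
        )


# Semantic aliases used throughout the pipeline.
ElevationGrid = Raster
LandcoverGrid = Raster
LandscapeTypeGrid = Raster
LCVGrid = Raster


@dataclass
class LandformGrid:
    """Final five-class landform grid plus its nine-unit-model provenance."""

    classes: Raster
    nulm: Raster

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape


# -- GeoTIFF I/O ----------------------------------------------------------


def write_geotiff(path: str | Path, raster: Raster) -> Path:
    """Write a raster as a single-band GeoTIFF.

    Float grids go out as float32 with nodata -9999; integer (categorical)
    grids as uint8 with nodata 0. A legend, when present, is validated
    against the grid values and written to ``<path>.legend.json``.
    """
    path = Path(path)
    values = raster.values
    if np.issubdtype(values.dtype, np.floating):
        out = values.astype(np.float32).copy()
        nodata: float | int = FLOAT_NODATA
        out[raster.nodata_mask] = nodata
    else:
        out = values.astype(np.uint8).copy()
        nodata = INT_NODATA
        out[raster.nodata_mask] = nodata
        if raster.legend is not None:
            present = set(np.unique(values[~raster.nodata_mask]).tolist())
            missing = present - set(raster.legend)
            if missing:
                raise LegendError(
                    f"grid values {sorted(missing)} have no legend entry"
                )
    x0, y0 = raster.origin
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (raster.cell_size, raster.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y0), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, out, extratags=extratags)
    if raster.legend is not None:
        legend_path = path.with_suffix(path.suffix + ".legend.json")
        legend_path.write_text(
            json.dumps({str(k): v for k, v in sorted(raster.legend.items())}, indent=1)
        )
    return path


def read_geotiff(path: str | Path) -> Raster:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`.

    A missing pixel-scale/tiepoint pair is a :class:`FormatError`; a missing
    nodata tag leaves every cell unmasked and logs a warning. A legend
    sidecar, when present, is loaded and validated against the values.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise FormatError(f"{path}: missing GeoTIFF georeferencing tags")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
    if values.ndim != 2:
        raise FormatError(f"{path}: expected a single-band grid")
    cell_size = float(scale[0])
    # tiepoint maps raster (i, j, k) -> model (x, y, z); we write (0,0) -> origin
    origin = (float(tie[3]) - float(tie[0]) * cell_size,
              float(tie[4]) + float(tie[1]) * cell_size)
    if nodata_tag is None:
        msg = f"{path}: no nodata tag, treating all cells as data"
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
        mask = np.zeros(values.shape, dtype=bool)
    else:
        nodata = float(str(nodata_tag.value))
        mask = values == values.dtype.type(nodata)
    legend = None
    legend_path = path.with_suffix(path.suffix + ".legend.json")
    if legend_path.exists():
        legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
        present = set(np.unique(values[~mask]).tolist())
        missing = present - set(legend)
        if missing:
            raise LegendError(f"{path}: values {sorted(missing)} absent from legend")
    if np.issubdtype(values.dtype, np.floating):
        values = values.astype(np.float64)
    else:
        values = values.astype(np.int64)
    return Raster(values=values, cell_size=cell_size, origin=origin,
                  nodata_mask=mask, legend=legend)
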