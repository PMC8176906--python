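"""DEM terrain analysis and nine-unit landform classification.

The landform layer is derived from three per-cell terrain attributes:

* **slope** (degrees), from central differences;
* **upslope contributing area** ``AS = (1/b) * (sum_i p_i A_i + A_self)``,
  the drainage area routed from upslope (plus the cell's own area) divided
  by the contour width ``b`` taken equal to the cell size — a specific
  catchment area in meters, a proxy for the potential flux of water and
  material through the cell;
* **surface curvature** ``C_s = mean_n (Z_self - Z_n) / d_n`` over the 8
  queen neighbors with center-to-center distances ``d_n`` (cardinal ``b``,
  diagonal ``sqrt(2) b``); positive is convex, negative concave.

Flow is partitioned to lower neighbors either by steepest descent (D8) or
by slope-proportional multiple flow directions (MFD, the default). Before
routing, depressions are removed with a priority-flood epsilon fill, which
raises every pit to its spill level and leaves a tiny monotone gradient
across flats so the flow graph is acyclic and complete.

Cells are then classified into hillslope units of the nine-unit landscape
model (NULM) by a fixed-priority decision cascade and re-mapped to the five
final landform classes (flat land, slope, shoulder, channel, summit).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, InputError, ParameterError
from .grids import ElevationGrid, LandformGrid, Raster
from .legends import LANDFORM_CODES, LANDFORM_LEGEND, NULM_CODES, NULM_LEGEND

# Queen-neighborhood offsets (row, col) and center-to-center distances in
# cell units; the order is fixed and shared by every routine below.
NEIGHBOR_OFFSETS: list[tuple[int, int]] = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]
NEIGHBOR_DISTANCES: np.ndarray = np.array(
    [np.sqrt(2), 1.0, np.sqrt(2), 1.0, 1.0, np.sqrt(2), 1.0, np.sqrt(2)]
)


@dataclass
class FlowField:
    """Per-cell outflow fractions to the 8 neighbors.

    ``fractions[k, r, c]`` is the share of cell (r, c)'s accumulated flow
    sent to the neighbor at ``NEIGHBOR_OFFSETS[k]``. Fractions sum to 1 for
    every cell with at least one strictly lower neighbor and to 0 for pits
    and masked cells. ``elevation`` is the depression-filled surface the
    fractions were derived from (used for topological ordering).
    """

    fractions: np.ndarray
    elevation: np.ndarray
    cell_size: float
    nodata_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    def outflow_sum(self) -> np.ndarray:
        return self.fractions.sum(axis=0)


@dataclass
class TerrainDerivatives:
    """The per-cell attribute stack the NULM cascade consumes."""

    upslope_area: Raster
    curvature: Raster
    slope_deg: Raster
    is_local_max: np.ndarray
    cell_size: float

    @property
    def cell_area(self) -> float:
        return self.cell_size**2


def _require_3x3(dem: ElevationGrid) -> None:
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise InputError(f"grid {dem.shape} too small; need at least 3x3")


def compute_slope(dem: ElevationGrid) -> Raster:
    """Slope in degrees from central differences (one-sided at edges)."""
    _require_3x3(dem)
    z = dem.masked()
    gy, gx = np.gradient(z, dem.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    mask = dem.nodata_mask | ~np.isfinite(slope)
    slope = np.where(mask, 0.0, slope)
    return dem.like(slope, nodata_mask=mask)


def fill_depressions(dem: ElevationGrid, eps: float = 1e-6) -> ElevationGrid:
    """Priority-flood epsilon fill.

    Raises every interior depression to its spill elevation plus a tiny
    increment per cell, so that every unmasked cell has a strictly
    descending 8-connected path to the grid boundary (or to a nodata
    region, which is treated as an outlet).
    """
    rows, cols = dem.shape
    z = dem.values.astype(np.float64).copy()
    mask = dem.nodata_mask
    filled = np.full_like(z, np.inf)
    visited = np.zeros_like(mask)
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    for r in range(rows):
        for c in range(cols):
            if mask[r, c]:
                continue
            on_edge = r in (0, rows - 1) or c in (0, cols - 1)
            next_to_nodata = any(
                0 <= r + dr < rows and 0 <= c + dc < cols and mask[r + dr, c + dc]
                for dr, dc in NEIGHBOR_OFFSETS
            )
            if on_edge or next_to_nodata:
                filled[r, c] = z[r, c]
                heapq.heappush(heap, (z[r, c], counter, r, c))
                counter += 1
                visited[r, c] = True
    while heap:
        zv, _, r, c = heapq.heappop(heap)
        for dr, dc in NEIGHBOR_OFFSETS:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < rows and 0 <= nc < cols):
                continue
            if mask[nr, nc] or visited[nr, nc]:
                continue
            filled[nr, nc] = max(z[nr, nc], zv + eps)
            heapq.heappush(heap, (filled[nr, nc], counter, nr, nc))
            counter += 1
            visited[nr, nc] = True
    filled[mask] = z[mask]
    return dem.like(filled)


def flow_partition(dem: ElevationGrid, method: str = "mfd",
                   fill: bool = True) -> FlowField:
    """Partition each cell's outflow among its strictly lower neighbors.

    ``method="d8"`` sends everything to the steepest-descent neighbor
    (first in the fixed neighbor order on ties); ``method="mfd"`` splits
    among all lower neighbors proportionally to the descent slope toward
    each. Cells with no lower neighbor (pits after filling, interior
    minima when ``fill=False``) have zero outflow.
    """
    method = method.lower()
    if method not in ("d8", "mfd"):
        raise ParameterError(f"unknown flow method {method!r}")
    if not np.all(np.isfinite(dem.values[~dem.nodata_mask])):
        raise InputError("DEM must be finite on unmasked cells")
    routed = fill_depressions(dem) if fill else dem
    z = routed.masked()
    rows, cols = z.shape
    drops = np.full((8, rows, cols), np.nan)
    for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        shifted = np.full_like(z, np.nan)
        rs = slice(max(dr, 0), rows + min(dr, 0))
        cs = slice(max(dc, 0), cols + min(dc, 0))
        rs_src = slice(max(-dr, 0), rows + min(-dr, 0))
        cs_src = slice(max(-dc, 0), cols + min(-dc, 0))
        shifted[rs_src, cs_src] = z[rs, cs]
        drops[k] = (z - shifted) / (NEIGHBOR_DISTANCES[k] * dem.cell_size)
    lower = np.nan_to_num(drops, nan=0.0)
    lower[lower < 0] = 0.0
    fractions = np.zeros_like(lower)
    if method == "mfd":
        total = lower.sum(axis=0)
        has_down = total > 0
        fractions[:, has_down] = lower[:, has_down] / total[has_down]
    else:
        with np.errstate(invalid="ignore"):
            best = np.argmax(lower, axis=0)
        has_down = lower.max(axis=0) > 0
        rr, cc = np.nonzero(has_down)
        fractions[best[rr, cc], rr, cc] = 1.0
    fractions[:, dem.nodata_mask] = 0.0
    return FlowField(
        fractions=fractions,
        elevation=routed.values.copy(),
        cell_size=dem.cell_size,
        nodata_mask=dem.nodata_mask.copy(),
    )


def upslope_contributing_area(dem: ElevationGrid, flow: FlowField) -> Raster:
    """Specific catchment area ``AS`` (meters) by topological accumulation.

    Every cell starts with its own area ``A_self``; cells are processed in
    descending order of the routed elevation (a topological order, since
    flow only goes to strictly lower cells) and each passes its accumulated
    area downstream by the outflow fractions. The per-cell result is the
    accumulated area divided by the contour width ``b`` = cell size, so the
    floor value for a no-inflow cell is ``A/b = b``.
    """
    if flow.shape != dem.shape:
        raise InputError("flow field shape differs from DEM shape")
    rows, cols = dem.shape
    mask = dem.nodata_mask
    acc = np.where(mask, 0.0, dem.cell_area).astype(np.float64)
    z = flow.elevation
    order = np.argsort(-z[~mask].ravel(), kind="stable")
    rr, cc = np.nonzero(~mask)
    rr, cc = rr[order], cc[order]
    frac = flow.fractions
    for r, c in zip(rr.tolist(), cc.tolist()):
        a = acc[r, c]
        if a == 0.0:
            continue
        for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
            f = frac[k, r, c]
            if f > 0.0:
                acc[r + dr, c + dc] += f * a
    out = np.where(mask, 0.0, acc / dem.cell_size)
    return dem.like(out)


def surface_curvature(dem: ElevationGrid) -> Raster:
    """Mean neighbor elevation drop per unit distance (positive = convex).

    For each cell, ``(Z_self - Z_n) / d_n`` averaged over whichever of the
    8 neighbors exist and are unmasked; a cell with no unmasked neighbor
    becomes nodata.
    """
    _require_3x3(dem)
    z = dem.masked()
    rows, cols = z.shape
    total = np.zeros_like(z)
    count = np.zeros_like(z)
    for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        shifted = np.full_like(z, np.nan)
        rs = slice(max(dr, 0), rows + min(dr, 0))
        cs = slice(max(dc, 0), cols + min(dc, 0))
        rs_src = slice(max(-dr, 0), rows + min(-dr, 0))
        cs_src = slice(max(-dc, 0), cols + min(-dc, 0))
        shifted[rs_src, cs_src] = z[rs, cs]
        diff = (z - shifted) / (NEIGHBOR_DISTANCES[k] * dem.cell_size)
        ok = np.isfinite(diff)
        total[ok] += diff[ok]
        count[ok] += 1
    mask = dem.nodata_mask | (count == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        curv = np.where(mask, 0.0, total / np.maximum(count, 1))
    return dem.like(curv, nodata_mask=mask)


def local_maxima(dem: ElevationGrid, strict: bool = False) -> np.ndarray:
    """Boolean grid of 8-neighbor local maxima of the elevation field."""
    z = dem.masked()
    rows, cols = z.shape
    out = ~dem.nodata_mask.copy()
    for dr, dc in NEIGHBOR_OFFSETS:
        shifted = np.full_like(z, -np.inf)
        rs = slice(max(dr, 0), rows + min(dr, 0))
        cs = slice(max(dc, 0), cols + min(dc, 0))
        rs_src = slice(max(-dr, 0), rows + min(-dr, 0))
        cs_src = slice(max(-dc, 0), cols + min(-dc, 0))
        shifted[rs_src, cs_src] = z[rs, cs]
        shifted = np.nan_to_num(shifted, nan=-np.inf)
        out &= (z > shifted) if strict else (z >= shifted)
    return out


def compute_derivatives(dem: ElevationGrid, method: str = "mfd") -> TerrainDerivatives:
    """Slope, specific catchment area, curvature and local-max flags in one call."""
    flow = flow_partition(dem, method=method)
    return TerrainDerivatives(
        upslope_area=upslope_contributing_area(dem, flow),
        curvature=surface_curvature(dem),
        slope_deg=compute_slope(dem),
        is_local_max=local_maxima(dem),
        cell_size=dem.cell_size,
    )


@dataclass
class NulmThresholds:
    """Cutoffs of the NULM decision cascade.

    Only the 45° fall-face bound is a fixed literature value; the curvature
    and catchment-area cutoffs default to quantiles of the grid's own
    derivative fields (resolved by :meth:`resolve`), which guarantees every
    unit can fire on any terrain with relief.
    """

    summit_curvature_min: float | None = None   # default: 95th pct of curvature
    shoulder_curvature_min: float | None = None  # default: 80th pct
    footslope_curvature_max: float | None = None  # default: 20th pct
    fallface_slope_min_deg: float = 45.0
    flat_slope_max_deg: float = 5.0
    channel_upslope_min: float | None = None    # default: 99th pct of AS

    def __post_init__(self) -> None:
        if not 0 < self.fallface_slope_min_deg < 90:
            raise ParameterError("fallface_slope_min_deg must lie in (0, 90)")
        if self.channel_upslope_min is not None and self.channel_upslope_min <= 0:
            raise ParameterError("channel_upslope_min must be > 0")

    def resolve(self, derivs: TerrainDerivatives) -> "NulmThresholds":
        """Fill unset cutoffs from quantiles of the derivative fields."""
        curv = derivs.curvature.valid_values()
        upa = derivs.upslope_area.valid_values()
        return replace(
            self,
            summit_curvature_min=(
                self.summit_curvature_min
                if self.summit_curvature_min is not None
                else float(np.percentile(curv, 95))
            ),
            shoulder_curvature_min=(
                self.shoulder_curvature_min
                if self.shoulder_curvature_min is not None
                else float(np.percentile(curv, 80))
            ),
            footslope_curvature_max=(
                self.footslope_curvature_max
                if self.footslope_curvature_max is not None
                else float(np.percentile(curv, 20))
            ),
            channel_upslope_min=(
                self.channel_upslope_min
                if self.channel_upslope_min is not None
                else float(np.percentile(upa, 99))
            ),
        )


def classify_nulm(derivs: TerrainDerivatives,
                  thresholds: NulmThresholds | None = None) -> Raster:
    """Classify each cell into a nine-unit-model hillslope unit.

    Fixed priority cascade: channel (catchment area above the channel
    threshold) > fall face (slope >= 45°) > summit (convex local maximum
    with gentle slope) > shoulder (convex) > footslope (concave) > toeslope
    (gentle) > backslope (the remainder). Channel outranks everything
    because stream cells occur regardless of what unit the bare slope
    attributes would suggest.
    """
    for name in ("upslope_area", "curvature", "slope_deg"):
        if getattr(derivs, name, None) is None:
            raise InputError(f"missing derivative field {name!r}")
    th = (thresholds or NulmThresholds()).resolve(derivs)
    upa = derivs.upslope_area.values
    curv = derivs.curvature.values
    slope = derivs.slope_deg.values
    mask = derivs.upslope_area.nodata_mask
    out = np.zeros(upa.shape, dtype=np.int64)
    undecided = ~mask
    for code, cond in (
        (NULM_CODES["channel"], upa >= th.channel_upslope_min),
        (NULM_CODES["fall face"], slope >= th.fallface_slope_min_deg),
        (NULM_CODES["summit"], (curv >= th.summit_curvature_min)
         & (slope < th.flat_slope_max_deg) & derivs.is_local_max),
        (NULM_CODES["shoulder"], curv >= th.shoulder_curvature_min),
        (NULM_CODES["footslope"], curv <= th.footslope_curvature_max),
        (NULM_CODES["toeslope"], slope < th.flat_slope_max_deg),
    ):
        hit = undecided & cond
        out[hit] = code
        undecided &= ~hit
    out[undecided] = NULM_CODES["backslope"]
    return derivs.upslope_area.like(out, legend=dict(NULM_LEGEND),
                                    nodata_mask=mask.copy())


# Default merge of the NULM units into the five final landform classes:
# backslope, fall face and footslope (the "mild slope" of the six-class
# intermediate scheme) all map to Slope; toeslope (and the never-firing
# interfluve) to Flat land.
DEFAULT_LANDFORM_REMAP: dict[str, str] = {
    "interfluve": "Flat land",
    "summit": "Summit",
    "shoulder": "Shoulder",
    "fall face": "Slope",
    "backslope": "Slope",
    "footslope": "Slope",
    "toeslope": "Flat land",
    "channel": "Channel",
}


def remap_landform(nulm: Raster,
                   mapping: dict[str, str] | None = None) -> LandformGrid:
    """Merge the nine-unit classification into the five final classes."""
    mapping = dict(DEFAULT_LANDFORM_REMAP if mapping is None else mapping)
    present = set(np.unique(nulm.values[~nulm.nodata_mask]).tolist())
    lut = np.zeros(max(NULM_LEGEND) + 1, dtype=np.int64)
    for code, unit in NULM_LEGEND.items():
        if unit not in mapping:
            if code in present:
                raise ConfigurationError(f"NULM unit {unit!r} has no landform mapping")
            continue
        target = mapping[unit]
        if target not in LANDFORM_CODES:
            raise ConfigurationError(
                f"unknown landform class {target!r} for NULM unit {unit!r}"
            )
        lut[code] = LANDFORM_CODES[target]
    final = lut[nulm.values]
    final[nulm.nodata_mask] = 0
    classes = nulm.like(final, legend=dict(LANDFORM_LEGEND),
                        nodata_mask=nulm.nodata_mask.copy())
    return LandformGrid(classes=classes, nulm=nulm)
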