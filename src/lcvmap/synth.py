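"""Synthetic volcanic-island data generators.

The study system is a volcanic island: one dominant shield cone, scattered
secondary cones ("oreums"), radial stream channels incised into the flanks,
and land cover that tracks elevation (developed coast, farmed lowlands,
forested mid-slopes, open and wet classes near the top — the summit crater
of such islands often holds a lake or wetland). The generators here emulate
that structure on a small grid with fully seeded randomness, so every
downstream stage — landform classification, typology, value mapping,
susceptibility — can be exercised and tested without any external dataset.

Every generator is deterministic per seed: identical parameters and seed
give bit-identical output, and no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .errors import GenerationError, ParameterError
from .grids import ElevationGrid, LandcoverGrid, Raster
from .legends import (
    LANDCOVER_CODES,
    LANDCOVER_LEGEND,
    LANDCOVER_MATRIX_ORDER,
    LANDFORM_MATRIX_ORDER,
)
from .zones import Zone, ZoneSet

# Elevation-band land-cover sequence, coast to summit: developed shoreline,
# agricultural lowland, grassland, forest belt, high barren slopes, summit
# wetland, crater open water.
ELEVATION_BAND_CLASSES: list[str] = [
    "Developed",
    "Agriculture",
    "Grassland",
    "Forest",
    "Barren land",
    "Wetland",
    "Open water",
]

IMPORTANCE_CATEGORIES: list[str] = [
    "Very Important",
    "Important",
    "Merely Important",
    "Somewhat Important",
    "Same",
]

# First-survey mean conservation ratings, used as the default latent truth
# the simulated expert panel perturbs.
DEFAULT_LANDCOVER_LATENTS: dict[str, float] = {
    "Barren land": 2.46,
    "Developed": 2.69,
    "Agriculture": 3.23,
    "Grassland": 3.84,
    "Forest": 4.15,
    "Open water": 4.46,
    "Wetland": 4.53,
}
DEFAULT_LANDFORM_LATENTS: dict[str, float] = {
    "Flat land": 3.46,
    "Slope": 3.69,
    "Shoulder": 4.08,
    "Channel": 4.46,
    "Summit": 5.00,
}


@dataclass
class IslandParams:
    """Parameters of the synthetic island DEM.

    Defaults describe a ~1.9 km island on a 64x64 grid of 30 m cells with a
    400 m central cone, five oreums and four incised radial channels.
    """

    grid_shape: tuple[int, int] = (64, 64)
    cell_size: float = 30.0
    peak_height: float = 400.0
    n_oreums: int = 5
    oreum_height_range: tuple[float, float] = (40.0, 90.0)
    channel_count: int = 4
    channel_depth_frac: float = 0.35
    channel_angular_sd: float = 0.055
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 16 or cols < 16:
            raise ParameterError(f"grid_shape must be >= 16x16, got {self.grid_shape}")
        if self.cell_size <= 0:
            raise ParameterError("cell_size must be > 0")
        if self.peak_height < 0 or self.noise_sd < 0:
            raise ParameterError("heights and noise_sd must be >= 0")
        if self.n_oreums < 0 or self.channel_count < 0:
            raise ParameterError("counts must be >= 0")
        lo, hi = self.oreum_height_range
        if lo > hi or lo < 0:
            raise ParameterError(f"bad oreum_height_range {self.oreum_height_range}")
        if not 0 <= self.channel_depth_frac < 1:
            raise ParameterError("channel_depth_frac must lie in [0, 1)")


@dataclass
class SurveySimParams:
    """Parameters of the simulated expert panel.

    13 respondents by default, matching a small expert board; latent scores
    are on the 1-5 Likert scale and the per-rating noise SD is in Likert
    units.
    """

    n_experts: int = 13
    latent_landcover_scores: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LANDCOVER_LATENTS)
    )
    latent_landform_scores: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LANDFORM_LATENTS)
    )
    rating_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 2:
            raise ParameterError("n_experts must be >= 2")
        if self.rating_noise_sd < 0:
            raise ParameterError("rating_noise_sd must be >= 0")
        for name, scores in (
            ("landcover", self.latent_landcover_scores),
            ("landform", self.latent_landform_scores),
        ):
            for item, v in scores.items():
                if not 1.0 <= v <= 5.0:
                    raise ParameterError(
                        f"latent {name} score for {item!r} outside [1, 5]: {v}"
                    )
        if set(self.latent_landcover_scores) != set(LANDCOVER_MATRIX_ORDER):
            raise ParameterError("latent_landcover_scores must cover the 7 classes")
        if set(self.latent_landform_scores) != set(LANDFORM_MATRIX_ORDER):
            raise ParameterError("latent_landform_scores must cover the 5 classes")


def gen_dem(params: IslandParams) -> ElevationGrid:
    """Generate the island elevation grid.

    The base is a radially symmetric cosine-profile cone of ``peak_height``
    dropping to sea level at radius R (95 % of the half-extent). Channels
    are carved multiplicatively along random azimuths — an angular Gaussian
    groove whose depth scales with local relief, so each channel bed still
    descends monotonically to the coast. Oreums are Gaussian bumps placed
    on the flanks. Seeded Gaussian noise is added last and the surface is
    clipped at sea level, so the minimum elevation is exactly 0.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = params.grid_shape
    b = params.cell_size
    yy, xx = np.mgrid[0:rows, 0:cols]
    # cell-center coordinates with the apex at the grid center
    cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0
    dx = (xx - cx) * b
    dy = (yy - cy) * b
    r = np.hypot(dx, dy)
    radius = 0.95 * (min(rows, cols) - 1) / 2.0 * b
    base = np.where(
        r <= radius,
        params.peak_height * 0.5 * (1.0 + np.cos(np.pi * np.minimum(r / radius, 1.0))),
        0.0,
    )

    # channels: multiplicative grooves along random azimuths
    theta = np.arctan2(dy, dx)
    carve = np.ones_like(base)
    azimuths = rng.uniform(-np.pi, np.pi, size=params.channel_count)
    for az in azimuths:
        delta = np.angle(np.exp(1j * (theta - az)))
        carve *= 1.0 - params.channel_depth_frac * np.exp(
            -0.5 * (delta / params.channel_angular_sd) ** 2
        )
    z = base * carve

    # oreums: secondary cones on the mid flanks. Each sits on a level
    # pedestal at the local surface height (z = max(surface, pedestal +
    # cone)), with its center snapped to a cell center, so every oreum top
    # is a symmetric strict local maximum with a gentle summit and steep
    # convex flanks — the way the small volcanic cones read in a 30 m DEM.
    # Centers are rejection-sampled to stay well separated.
    heights = rng.uniform(*params.oreum_height_range, size=params.n_oreums)
    sigma = 1.5 * b
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < params.n_oreums:
        if tries > 200 * max(params.n_oreums, 1):
            raise GenerationError(
                f"could not place {params.n_oreums} separated oreums"
            )
        tries += 1
        ang = rng.uniform(-np.pi, np.pi)
        rad = rng.uniform(0.45, 0.80) * radius
        # snap to the cell-center lattice so each cone top is one cell
        ox = (np.round(rad * np.cos(ang) / b + cx) - cx) * b
        oy = (np.round(rad * np.sin(ang) / b + cy) - cy) * b
        if all(np.hypot(ox - px, oy - py) > 8.0 * sigma for px, py in centers):
            centers.append((float(ox), float(oy)))
    for h, (ox, oy) in zip(heights, centers):
        d2 = (dx - ox) ** 2 + (dy - oy) ** 2
        center_cell = np.unravel_index(np.argmin(d2), d2.shape)
        pedestal = z[center_cell]
        bump = pedestal + h * np.exp(-0.5 * d2 / sigma**2)
        z = np.where(d2 <= (4.0 * sigma) ** 2, np.maximum(z, bump), z)

    if params.noise_sd > 0:
        z = z + rng.normal(0.0, params.noise_sd, size=z.shape)
    z = np.maximum(z, 0.0)
    return Raster(values=z.astype(np.float64), cell_size=b)


def gen_landcover(
    dem: ElevationGrid,
    class_breaks: np.ndarray | None = None,
    seed: int = 0,
    speckle_rate: float = 0.05,
) -> LandcoverGrid:
    """Assign the seven land-cover classes by elevation band.

    ``class_breaks`` are the six interior elevation thresholds separating
    the seven bands; by default the six interior septile quantiles of the
    unmasked elevations. A seeded speckle replaces a fraction of cells with
    a uniformly random class, giving patchiness within bands.
    """
    z = dem.values
    if not np.all(np.isfinite(z[~dem.nodata_mask])):
        raise ParameterError("DEM must be finite on unmasked cells")
    if class_breaks is None:
        qs = np.arange(1, 7) / 7.0
        zz = z[~dem.nodata_mask]
        # septiles over the above-sea-level cells, so a wide sea fringe of
        # identical minima cannot collapse the breaks
        above = zz[zz > zz.min()]
        class_breaks = np.quantile(above if above.size else zz, qs)
    class_breaks = np.asarray(class_breaks, dtype=float)
    if class_breaks.shape != (6,) or not np.all(np.diff(class_breaks) > 0):
        raise ParameterError("class_breaks must be 6 strictly increasing values")
    band = np.digitize(z, class_breaks)  # 0..6
    codes = np.array([LANDCOVER_CODES[name] for name in ELEVATION_BAND_CLASSES])
    cover = codes[band]
    if speckle_rate > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(cover.shape) < speckle_rate
        cover = np.where(flip, rng.integers(1, 8, size=cover.shape), cover)
    cover = cover.astype(np.int64)
    cover[dem.nodata_mask] = 0
    return dem.like(cover, legend=dict(LANDCOVER_LEGEND))


def gen_zones(
    dem: ElevationGrid,
    n_zones: int = 3,
    seed: int = 0,
    radius_cells: float = 5.0,
    max_tries: int = 2000,
) -> ZoneSet:
    """Place ``n_zones`` disjoint circular designated areas on the island.

    Disc centers are drawn uniformly (seeded) inside the grid footprint,
    rejecting overlaps; failing to place all discs raises a generation
    error.
    """
    if n_zones < 1:
        raise ParameterError("n_zones must be >= 1")
    rng = np.random.default_rng(seed)
    rows, cols = dem.shape
    x0, y0 = dem.origin
    radius = radius_cells * dem.cell_size
    xmin, xmax = x0 + radius, x0 + cols * dem.cell_size - radius
    ymin, ymax = y0 - rows * dem.cell_size + radius, y0 - radius
    if xmin >= xmax or ymin >= ymax:
        raise GenerationError("zone radius too large for the grid footprint")
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_zones:
        if tries >= max_tries:
            raise GenerationError(
                f"could not place {n_zones} disjoint zones after {max_tries} tries"
            )
        tries += 1
        cx = rng.uniform(xmin, xmax)
        cy = rng.uniform(ymin, ymax)
        if all(np.hypot(cx - px, cy - py) > 2.2 * radius for px, py in centers):
            centers.append((cx, cy))
    zones = [
        Zone(name=f"zone_{i + 1}", geometry=Point(cx, cy).buffer(radius, quad_segs=64))
        for i, (cx, cy) in enumerate(centers)
    ]
    return ZoneSet(zones)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def gen_survey(params: SurveySimParams) -> pd.DataFrame:
    """Simulate the expert panel's Likert ratings.

    Each expert rates each of the 12 items (7 land-cover + 5 landform
    classes): the latent score plus Gaussian noise, rounded half-up and
    clamped to the 1-5 Likert grid. Each expert also draws one pairwise
    importance category for land cover relative to landform (applied to the
    land-cover rows; landform rows carry "Same").

    Returns a tidy table with columns ``expert_id, item, rating, importance``.
    """
    rng = np.random.default_rng(params.seed)
    records = []
    for e in range(1, params.n_experts + 1):
        importance = IMPORTANCE_CATEGORIES[rng.integers(0, len(IMPORTANCE_CATEGORIES))]
        for item in LANDCOVER_MATRIX_ORDER:
            latent = params.latent_landcover_scores[item]
            noisy = latent + rng.normal(0.0, params.rating_noise_sd)
            rating = int(np.clip(_round_half_up(np.array(noisy)), 1, 5))
            records.append((f"expert_{e:02d}", item, rating, importance))
        for item in LANDFORM_MATRIX_ORDER:
            latent = params.latent_landform_scores[item]
            noisy = latent + rng.normal(0.0, params.rating_noise_sd)
            rating = int(np.clip(_round_half_up(np.array(noisy)), 1, 5))
            records.append((f"expert_{e:02d}", item, rating, "Same"))
    return pd.DataFrame(records, columns=["expert_id", "item", "rating", "importance"])
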