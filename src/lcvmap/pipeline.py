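"""End-to-end pipeline: terrain -> typology -> survey -> value map -> mask.

A run is driven by a :class:`PipelineConfig` (usually loaded from YAML),
writes every stage product into the output directory, and finishes with a
JSON :class:`RunManifest` carrying the config snapshot, derived thresholds
and a SHA-256 checksum per output — re-running with the same config and
inputs reproduces the checksums bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError, LcvmapError, ParameterError
from .grids import Raster, read_geotiff, write_geotiff
from .lcv import apply_lcv_matrix, focal_sd, susceptibility_mask, zonal_lcv_stats
from .survey import LCVMatrix, aggregate_survey, load_reference_matrix
from .synth import IslandParams, gen_dem, gen_landcover, gen_survey, gen_zones, SurveySimParams
from .terrain import NulmThresholds, compute_derivatives, classify_nulm, remap_landform
from .typology import overlay_types, tabulate_type_areas
from .zones import ZoneSet, read_geojson, write_geojson

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; paths may be None when a stage is simulated."""

    out_dir: Path
    dem: Path | None = None
    landcover: Path | None = None
    zones: Path | None = None
    survey: Path | None = None
    matrix: Path | None = None
    nulm: dict = field(default_factory=dict)
    flow_method: str = "mfd"
    focal_window: int = 3
    percentile: float = 80.0
    sd_ddof: int = 0
    seed: int = 0
    simulate: bool = False
    island: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not 0 < self.percentile < 100:
            raise ParameterError(f"percentile must lie in (0, 100): {self.percentile}")
        for name in ("dem", "landcover", "zones", "survey", "matrix"):
            p = getattr(self, name)
            if p is not None:
                setattr(self, name, Path(p))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in doc:
            raise ConfigurationError("config must set out_dir")
        return cls(**doc)


@dataclass
class RunManifest:
    """What a run produced: config snapshot, software version, checksums."""

    config: dict
    version: str
    checksums: dict[str, str]
    derived: dict

    def write(self, path: Path) -> Path:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    log.info("stage %s", name)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full workflow and return the manifest (also written).

    Stage order: inputs (or simulation) -> terrain derivatives and landform
    classification -> typology -> value matrix (from survey responses, a
    matrix file, or the packaged reference) -> value map and zonal stats ->
    focal SD and susceptibility mask.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    derived: dict = {}

    try:
        # -- inputs ------------------------------------------------------
        _stage("inputs")
        if config.simulate or config.dem is None:
            params = IslandParams(**{"seed": config.seed, **config.island})
            dem = gen_dem(params)
            landcover = gen_landcover(dem, seed=config.seed + 1)
            zones = gen_zones(dem, seed=config.seed + 2)
            outputs["dem"] = write_geotiff(out / "dem.tif", dem)
            outputs["landcover"] = write_geotiff(out / "landcover.tif", landcover)
            outputs["zones"] = write_geojson(out / "zones.geojson", zones)
        else:
            dem = read_geotiff(config.dem)
            if config.landcover is None:
                raise ConfigurationError("landcover path required when dem is given")
            landcover = read_geotiff(config.landcover)
            zones = read_geojson(config.zones) if config.zones else ZoneSet([])

        # -- terrain -----------------------------------------------------
        _stage("terrain")
        derivs = compute_derivatives(dem, method=config.flow_method)
        thresholds = NulmThresholds(**config.nulm).resolve(derivs)
        nulm = classify_nulm(derivs, thresholds)
        landform = remap_landform(nulm)
        derived["nulm_thresholds"] = dataclasses.asdict(thresholds)
        outputs["nulm"] = write_geotiff(out / "nulm.tif", nulm)
        outputs["landform"] = write_geotiff(out / "landform.tif", landform.classes)
        outputs["slope"] = write_geotiff(out / "slope.tif", derivs.slope_deg)
        outputs["upslope_area"] = write_geotiff(out / "upslope_area.tif",
                                                derivs.upslope_area)
        outputs["curvature"] = write_geotiff(out / "curvature.tif", derivs.curvature)

        # -- typology ----------------------------------------------------
        _stage("typology")
        types = overlay_types(landform, landcover)
        areas = tabulate_type_areas(types)
        outputs["types"] = write_geotiff(out / "types.tif", types)
        areas.to_csv(out / "type_areas.csv", index=False, float_format="%.6f")
        outputs["type_areas"] = out / "type_areas.csv"
        derived["n_types"] = int(len(areas))

        # -- value matrix ------------------------------------------------
        _stage("survey")
        if config.matrix is not None:
            matrix = LCVMatrix.from_csv(config.matrix, normalized=True)
        elif config.survey is not None:
            import pandas as pd

            matrix = aggregate_survey(pd.read_csv(config.survey))
        elif config.simulate or config.dem is None:
            ratings = gen_survey(SurveySimParams(seed=config.seed + 3))
            ratings.to_csv(out / "survey.csv", index=False)
            outputs["survey"] = out / "survey.csv"
            matrix = aggregate_survey(ratings)
        else:
            matrix = load_reference_matrix()
        outputs["lcv_matrix"] = matrix.to_csv(out / "lcv_matrix.csv")

        # -- value map ---------------------------------------------------
        _stage("lcv")
        lcv = apply_lcv_matrix(types, matrix)
        outputs["lcv"] = write_geotiff(out / "lcv.tif", lcv)
        stats = zonal_lcv_stats(lcv, zones, ddof=config.sd_ddof)
        stats.to_csv(out / "zonal_stats.csv", index=False, float_format="%.6f")
        outputs["zonal_stats"] = out / "zonal_stats.csv"

        # -- susceptibility ----------------------------------------------
        _stage("susceptibility")
        sd = focal_sd(lcv, window=config.focal_window, ddof=config.sd_ddof)
        result = susceptibility_mask(sd, percentile=config.percentile)
        outputs["focal_sd"] = write_geotiff(out / "focal_sd.tif", sd)
        outputs["susceptibility"] = write_geotiff(out / "susceptibility.tif",
                                                  result.mask_raster())
        derived["susceptibility_percentile"] = result.percentile
        derived["susceptibility_threshold"] = result.threshold
        derived["susceptible_cells"] = int(result.mask.sum())
    except LcvmapError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise LcvmapError(f"pipeline failed: {exc}") from exc

    manifest = RunManifest(
        config={k: str(v) if isinstance(v, Path) else v
                for k, v in dataclasses.asdict(config).items()},
        version=__version__,
        checksums={name: _sha256(path) for name, path in sorted(outputs.items())},
        derived=derived,
    )
    manifest.write(out / "manifest.json")
    return manifest
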