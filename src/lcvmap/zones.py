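"""Labeled polygon zones (designated areas) and their GeoJSON round-trip."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import FormatError, InputError


@dataclass
class Zone:
    """One designated area: a name and a valid polygonal geometry."""

    name: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.geometry.is_empty:
            raise InputError(f"zone {self.name!r}: empty geometry")
        if not self.geometry.is_valid:
            raise InputError(f"zone {self.name!r}: invalid geometry")


@dataclass
class ZoneSet:
    """An ordered collection of labeled zones in the grid's coordinate system."""

    zones: list[Zone]

    def __iter__(self):
        return iter(self.zones)

    def __len__(self) -> int:
        return len(self.zones)

    @property
    def names(self) -> list[str]:
        return [z.name for z in self.zones]


def write_geojson(path: str | Path, zones: ZoneSet) -> Path:
    """Write zones as a GeoJSON FeatureCollection with a ``name`` property."""
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "properties": {"name": z.name},
            "geometry": mapping(z.geometry),
        }
        for z in zones
    ]
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
    return path


def read_geojson(path: str | Path) -> ZoneSet:
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    zones = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = shape(feat["geometry"])
        name = (feat.get("properties") or {}).get("name", f"zone_{i}")
        zones.append(Zone(name=name, geometry=geom))
    return ZoneSet(zones)


def contains_cell_centers(zone: Zone, raster) -> np.ndarray:
    """Boolean grid: True where a cell center lies inside the zone polygon."""
    xs, ys = raster.cell_centers()
    return shapely.contains_xy(zone.geometry, xs, ys)
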