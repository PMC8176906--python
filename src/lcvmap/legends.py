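"""Class legends shared across the pipeline.

Land cover follows the Korean Ministry of Environment large-class scheme
(seven classes); landform is the five-class scheme obtained by simplifying
the nine-unit landscape model (NULM). Grid codes are small positive
integers; 0 is reserved for nodata in categorical rasters.
"""

from __future__ import annotations

# Land cover, Ministry large-class codes.
LANDCOVER_LEGEND: dict[int, str] = {
    1: "Developed",
    2: "Agriculture",
    3: "Forest",
    4: "Grassland",
    5: "Wetland",
    6: "Barren land",
    7: "Open water",
}
LANDCOVER_CODES: dict[str, int] = {v: k for k, v in LANDCOVER_LEGEND.items()}

# Final five landform classes.
LANDFORM_LEGEND: dict[int, str] = {
    1: "Flat land",
    2: "Slope",
    3: "Shoulder",
    4: "Channel",
    5: "Summit",
}
LANDFORM_CODES: dict[str, int] = {v: k for k, v in LANDFORM_LEGEND.items()}

# Hillslope units of the nine-unit landscape model that the classifier can
# emit (the provenance layer behind the five final classes).
NULM_LEGEND: dict[int, str] = {
    1: "interfluve",
    2: "summit",
    3: "shoulder",
    4: "fall face",
    5: "backslope",
    6: "footslope",
    7: "toeslope",
    8: "channel",
}
NULM_CODES: dict[str, int] = {v: k for k, v in NULM_LEGEND.items()}

# Value-matrix axis orders (conservation-value matrix convention: land-cover
# rows from least to most natural, landform columns from flat to summit).
LANDCOVER_MATRIX_ORDER: list[str] = [
    "Barren land",
    "Developed",
    "Agriculture",
    "Grassland",
    "Forest",
    "Open water",
    "Wetland",
]
LANDFORM_MATRIX_ORDER: list[str] = [
    "Flat land",
    "Slope",
    "Shoulder",
    "Channel",
    "Summit",
]


def type_code(landform_code: int, landcover_code: int) -> int:
    """Pair code for a (landform, land cover) landscape type.

    ``code = landform * 10 + landcover`` — human-decodable and stable
    without a lookup file.
    """
    return landform_code * 10 + landcover_code


def decode_type(code: int) -> tuple[int, int]:
    """Inverse of :func:`type_code`."""
    return code // 10, code % 10


def type_legend() -> dict[int, str]:
    """Legend over all 35 possible landscape-type pair codes."""
    return {
        type_code(lf, lc): f"{LANDFORM_LEGEND[lf]} x {LANDCOVER_LEGEND[lc]}"
        for lf in LANDFORM_LEGEND
        for lc in LANDCOVER_LEGEND
    }
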