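#!/usr/bin/env python
"""Cross landform with land cover into landscape types and tabulate areas.

The overlay pairs the 5 landform and 7 land-cover classes cell by cell
(35 possible types) and the table reports each occurring type's area and
share, written to results/typology/.
"""

from pathlib import Path

from lcvmap.grids import read_geotiff, write_geotiff
from lcvmap.typology import overlay_types, tabulate_type_areas

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "typology"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    landform = read_geotiff(ROOT / "landforms" / "landform.tif")
    landcover = read_geotiff(ROOT / "island" / "landcover.tif")
    types = overlay_types(landform, landcover)
    table = tabulate_type_areas(types)

    write_geotiff(OUT / "types.tif", types)
    table.to_csv(OUT / "type_areas.csv", index=False, float_format="%.6f")

    print(f"{len(table)} of 35 possible landscape types occur on the island")
    print("largest types:")
    print(table.head(6).to_string(index=False))
    print(f"proportions sum to {table.proportion_pct.sum():.6f}%")
    print(f"table written to {OUT / 'type_areas.csv'}")


if __name__ == "__main__":
    main()
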