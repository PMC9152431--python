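#!/usr/bin/env python
"""Overlay diversity results with protected areas and the footprint raster.

For each reserve: does it coincide spatially with any occupied grid cell, how
many species have records inside it, and what is its mean human-footprint
index.  Prints the top reserves by species count — the conservation-gap view.
"""

from pathlib import Path

import pandas as pd

from endegrid.gap_analysis import gap_report, read_protected_areas
from endegrid.grid_metrics import GridSpec, presence_from_triplets
from endegrid.rasters import read_ascii_grid

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = pd.read_csv(BASE / "cleaning" / "cleaned.csv")
    matrix = presence_from_triplets(BASE / "metrics" / "presence.csv")
    areas = read_protected_areas(BASE / "inputs" / "protected_areas.geojson")
    raster = read_ascii_grid(BASE / "inputs" / "footprint.asc")

    table = gap_report(areas, matrix, GridSpec(cell_size=1.0), records, raster)
    out = BASE / "gaps"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "gap_table.csv", index=False, float_format="%.12g")

    n_coincide = int(table["coincides_with_grid"].sum())
    print(f"{n_coincide}/{len(table)} protected areas coincide with occupied cells")
    for country, group in table.groupby("country"):
        print(f"  {country}: {int(group['coincides_with_grid'].sum())}/{len(group)}; "
              f"mean footprint {group['mean_footprint'].mean():.1f}")
    print("top reserves by species count:")
    print(
        table.head(5)[["name", "country", "n_species", "mean_footprint"]]
        .to_string(index=False)
    )


if __name__ == "__main__":
    main()
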