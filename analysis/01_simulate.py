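#!/usr/bin/env python
"""Generate the synthetic study landscape: occurrences, reserves, footprint.

Emulates a subcontinental two-country study area with a heavy-tailed
range-size distribution, spatially cohesive ranges, one planted cluster of
narrow endemics (a known center of endemism to recover later), rectangular
protected areas, and a blobby 0–100 impact raster.  Writes everything under
results/inputs/ in the same text formats the pipeline reads.
"""

from pathlib import Path

from endegrid.gap_analysis import write_protected_areas
from endegrid.rasters import write_ascii_grid
from endegrid.synthetic import (
    SyntheticConfig,
    generate_footprint_raster,
    generate_occurrences,
    generate_protected_areas,
)

SEED = 20260928
EXTENT = (-76.0, -56.0, -53.0, -21.0)
PLANTED_CELL = (107, 65)  # a coastal-desert-like cell seeded with 6 endemics

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SyntheticConfig(
        n_species=300,
        range_size=("logseries", 0.95),
        records_per_species=("poisson", 12.0),
        spatial_model="cohesive",
        planted_centers=[(PLANTED_CELL, 6)],
        extent=EXTENT,
        countries=("Westland", "Eastland"),
        seed=SEED,
    )
    records, truth = generate_occurrences(config)
    records.to_csv(OUT / "occurrences.csv", index=False)
    truth.to_csv(OUT / "ground_truth.csv", index=False)

    areas = generate_protected_areas(EXTENT, 30, seed=SEED + 1)
    write_protected_areas(areas, OUT / "protected_areas.geojson")
    raster = generate_footprint_raster(EXTENT, 0.25, ("blobs", 10, 60.0), seed=SEED + 2)
    write_ascii_grid(raster, OUT / "footprint.asc")

    print(f"{len(records)} records of {truth['species'].nunique()} species")
    print(f"{len(areas)} protected areas; raster {raster.n_rows}×{raster.n_cols} @0.25°")
    print(f"planted center: 6 single-cell endemics at cell {PLANTED_CELL}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
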