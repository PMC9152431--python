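#!/usr/bin/env python
"""Grid the cleaned records and map SR, WE and CWE on the 1° graticule.

Builds the presence matrix, reports raw and 5–95% percentile-trimmed score
extrema, and exports the per-cell score table plus GeoJSON cell polygons.
"""

from pathlib import Path

import pandas as pd

from endegrid.grid_metrics import (
    GridSpec,
    build_presence_matrix,
    diversity_scores,
    percentile_trim,
    presence_to_triplets,
    scores_to_geojson,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = pd.read_csv(BASE / "cleaning" / "cleaned.csv")
    grid = GridSpec(cell_size=1.0)
    matrix = build_presence_matrix(records, grid)
    out = BASE / "metrics"
    out.mkdir(parents=True, exist_ok=True)
    presence_to_triplets(matrix, out / "presence.csv")

    scores = diversity_scores(matrix)
    scores.to_csv(out / "scores.csv", index=False, float_format="%.12g")
    scores_to_geojson(scores, grid, out / "cells.geojson")

    print(f"{matrix.n_cells} occupied 1° cells × {matrix.n_species} species")
    for name in ("SR", "WE", "CWE"):
        values = scores[name]
        trim = percentile_trim(values, 5, 95)
        print(
            f"{name}: range {values.min():.4g}–{values.max():.4g}; "
            f"5–95% trimmed max {trim.trimmed_max:.4g} "
            f"({int(trim.retained.sum())}/{len(values)} cells retained)"
        )
    print(f"WE sums to {scores['WE'].sum():.6f} (= number of species)")


if __name__ == "__main__":
    main()
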