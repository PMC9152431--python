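"""Degree-grid presence matrices and range-weighted endemism metrics.

Occurrences are binned onto a graticule-aligned grid (default 1° × 1°,
anchored at −180, −90) with half-open cells ``[edge, edge + size)``.  From the
binary cells × species incidence matrix three per-cell scores are computed:

* **SR** — species richness, the number of species recorded in the cell;
* **WE** — weighted endemism, ``Σ_s 1/r_s`` over species present, where the
  range ``r_s`` is the number of occupied cells of species *s* over the whole
  analysis extent.  High where many narrow-ranged species co-occur;
* **CWE** — corrected weighted endemism, ``WE / SR``, which removes the raw
  richness signal; with a single-cell window it lies in ``(0, 1]`` and equals
  1 only where every species is confined to that cell.

A square neighborhood window of configurable half-width generalizes WE to
``Σ_s (cells of s in window) / r_s`` and CWE to that sum over the window
richness; the default window is the focal cell alone, the classic definition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "PresenceMatrix",
    "PercentileTrim",
    "OutOfExtentError",
    "EmptyMatrixError",
    "assign_cell",
    "build_presence_matrix",
    "species_richness",
    "weighted_endemism",
    "corrected_weighted_endemism",
    "diversity_scores",
    "percentile_trim",
    "presence_to_triplets",
    "presence_from_triplets",
    "scores_to_geojson",
]


class OutOfExtentError(ValueError):
    """A point falls outside the grid's declared extent."""


class EmptyMatrixError(ValueError):
    """No records to grid: a presence matrix would have no rows."""


@dataclass(frozen=True)
class GridSpec:
    """Graticule grid definition.

    Cells are indexed by integer ``(cell_x, cell_y)`` counted from the anchor
    ``(origin_lon, origin_lat)``; membership is half-open in both axes, so a
    point exactly on a shared edge belongs to the cell whose lower edge it
    touches.  ``extent`` is an optional ``(lon_min, lat_min, lon_max, lat_max)``
    bounding box; points outside it raise :class:`OutOfExtentError`.
    """

    cell_size: float = 1.0
    origin_lon: float = -180.0
    origin_lat: float = -90.0
    extent: tuple[float, float, float, float] | None = None

    def __post_init__(self):
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.extent is not None:
            x0, y0, x1, y1 = self.extent
            if not (x1 > x0 and y1 > y0):
                raise ValueError("extent must be non-degenerate")

    def cell_index(self, lon, lat):
        """Vectorized point → (cell_x, cell_y) assignment (no extent check)."""
        ix = np.floor((np.asarray(lon, float) - self.origin_lon) / self.cell_size)
        iy = np.floor((np.asarray(lat, float) - self.origin_lat) / self.cell_size)
        return ix.astype(np.int64), iy.astype(np.int64)

    def cell_bounds(self, cell_x: int, cell_y: int) -> tuple[float, float, float, float]:
        """(west, south, east, north) of a cell."""
        w = self.origin_lon + cell_x * self.cell_size
        s = self.origin_lat + cell_y * self.cell_size
        return (w, s, w + self.cell_size, s + self.cell_size)

    def contains(self, lon: float, lat: float) -> bool:
        if self.extent is None:
            return True
        x0, y0, x1, y1 = self.extent
        return x0 <= lon <= x1 and y0 <= lat <= y1


def assign_cell(longitude: float, latitude: float, grid: GridSpec) -> tuple[int, int]:
    """Assign one point to its grid cell.

    Deterministic half-open binning: ``floor((coord − origin)/cell_size)``.

    Raises
    ------
    OutOfExtentError
        If the grid declares an extent and the point lies outside it.
    """
    if not (math.isfinite(longitude) and math.isfinite(latitude)):
        raise OutOfExtentError(f"non-finite coordinate ({longitude}, {latitude})")
    if not grid.contains(longitude, latitude):
        raise OutOfExtentError(
            f"point ({longitude}, {latitude}) outside extent {grid.extent}"
        )
    ix, iy = grid.cell_index(longitude, latitude)
    return int(ix), int(iy)


@dataclass
class PresenceMatrix:
    """Binary cells × species incidence with its marginals.

    Rows are occupied cells (lexicographically ordered ``(cell_x, cell_y)``),
    columns are species (lexicographic).  Every row and column has at least one
    presence; ``row_sums`` is per-cell richness SR and ``col_sums`` the
    per-species range r_s.
    """

    cells: np.ndarray  # (n_cells, 2) int64, lexicographically sorted
    species: np.ndarray  # (n_species,) str, sorted
    incidence: np.ndarray  # (n_cells, n_species) uint8 in {0, 1}

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=np.int64)
        self.species = np.asarray(self.species, dtype=object)
        self.incidence = np.asarray(self.incidence, dtype=np.uint8)
        if self.incidence.shape != (len(self.cells), len(self.species)):
            raise ValueError("incidence shape does not match cells × species")
        if not np.isin(self.incidence, (0, 1)).all():
            raise ValueError("incidence must be binary")
        if (self.incidence.sum(axis=1) == 0).any():
            raise ValueError("empty cell row: drop unoccupied cells")
        if (self.incidence.sum(axis=0) == 0).any():
            raise ValueError("empty species column: drop unrecorded species")

    @property
    def n_cells(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_species(self) -> int:
        return self.incidence.shape[1]

    @property
    def row_sums(self) -> np.ndarray:
        """Per-cell richness SR_c."""
        return self.incidence.sum(axis=1, dtype=np.int64)

    @property
    def col_sums(self) -> np.ndarray:
        """Per-species range r_s (occupied cells over the whole extent)."""
        return self.incidence.sum(axis=0, dtype=np.int64)

    def with_incidence(self, incidence: np.ndarray) -> "PresenceMatrix":
        return PresenceMatrix(self.cells.copy(), self.species.copy(), incidence)


def build_presence_matrix(records: pd.DataFrame, grid: GridSpec) -> PresenceMatrix:
    """Grid cleaned occurrence records into a presence matrix.

    A species is present in a cell iff at least one record falls in it.  Cell
    and species orderings are lexicographic, so the matrix is independent of
    record order.

    Raises
    ------
    EmptyMatrixError
        If ``records`` is empty.
    """
    if len(records) == 0:
        raise EmptyMatrixError("empty matrix: no records to grid")
    ix, iy = grid.cell_index(records["longitude"].to_numpy(), records["latitude"].to_numpy())
    if grid.extent is not None:
        x0, y0, x1, y1 = grid.extent
        lon = records["longitude"].to_numpy()
        lat = records["latitude"].to_numpy()
        outside = (lon < x0) | (lon > x1) | (lat < y0) | (lat > y1)
        if outside.any():
            raise OutOfExtentError(f"{int(outside.sum())} record(s) outside extent")

    frame = pd.DataFrame(
        {"cell_x": ix, "cell_y": iy, "species": records["species"].to_numpy()}
    ).drop_duplicates()
    species = np.array(sorted(frame["species"].unique()), dtype=object)
    cells_df = frame[["cell_x", "cell_y"]].drop_duplicates().sort_values(
        ["cell_x", "cell_y"], kind="mergesort"
    )
    cells = cells_df.to_numpy(dtype=np.int64)

    cell_pos = {tuple(c): i for i, c in enumerate(cells)}
    sp_pos = {s: j for j, s in enumerate(species)}
    incidence = np.zeros((len(cells), len(species)), dtype=np.uint8)
    for cx, cy, sp in frame.itertuples(index=False):
        incidence[cell_pos[(cx, cy)], sp_pos[sp]] = 1
    return PresenceMatrix(cells, species, incidence)


def _window_rows(matrix: PresenceMatrix, half_width: int) -> list[np.ndarray]:
    """Row indices of occupied cells within Chebyshev distance ``half_width``."""
    if half_width == 0:
        return [np.array([i]) for i in range(matrix.n_cells)]
    pos = {tuple(c): i for i, c in enumerate(matrix.cells)}
    out = []
    for cx, cy in matrix.cells:
        rows = [
            pos[(cx + dx, cy + dy)]
            for dx in range(-half_width, half_width + 1)
            for dy in range(-half_width, half_width + 1)
            if (cx + dx, cy + dy) in pos
        ]
        out.append(np.array(sorted(rows)))
    return out


def species_richness(matrix: PresenceMatrix) -> np.ndarray:
    """Per-cell species richness SR (the incidence row sums)."""
    return matrix.row_sums


def weighted_endemism(matrix: PresenceMatrix, window: int = 0) -> np.ndarray:
    """Per-cell weighted endemism.

    ``window`` is the half-width (in cells) of a square neighborhood; 0 means
    the focal cell alone, in which case WE_c reduces to ``Σ 1/r_s`` over the
    species present in the cell.
    """
    inv_r = 1.0 / matrix.col_sums.astype(float)
    if window == 0:
        return matrix.incidence.astype(float) @ inv_r
    we = np.empty(matrix.n_cells)
    for i, rows in enumerate(_window_rows(matrix, window)):
        counts = matrix.incidence[rows].sum(axis=0)  # cells of s within the window
        we[i] = float((counts * inv_r).sum())
    return we


def corrected_weighted_endemism(matrix: PresenceMatrix, window: int = 0) -> np.ndarray:
    """Per-cell corrected weighted endemism: WE divided by window richness."""
    if window == 0:
        sr = matrix.row_sums.astype(float)
        assert (sr > 0).all()  # empty rows are dropped at construction
        return weighted_endemism(matrix, 0) / sr
    cwe = np.empty(matrix.n_cells)
    inv_r = 1.0 / matrix.col_sums.astype(float)
    for i, rows in enumerate(_window_rows(matrix, window)):
        counts = matrix.incidence[rows].sum(axis=0)
        sr_window = int((counts > 0).sum())
        cwe[i] = float((counts * inv_r).sum()) / sr_window
    return cwe


def diversity_scores(matrix: PresenceMatrix, window: int = 0) -> pd.DataFrame:
    """Per-cell score table: cell_x, cell_y, SR, WE, CWE."""
    return pd.DataFrame(
        {
            "cell_x": matrix.cells[:, 0],
            "cell_y": matrix.cells[:, 1],
            "SR": species_richness(matrix),
            "WE": weighted_endemism(matrix, window),
            "CWE": corrected_weighted_endemism(matrix, window),
        }
    )


@dataclass
class PercentileTrim:
    """Extrema of a score distribution after percentile trimming."""

    trimmed_max: float
    trimmed_min: float
    retained: np.ndarray  # boolean mask over the input cells
    low_cutoff: float
    high_cutoff: float


def percentile_trim(
    scores: Sequence[float], low_pct: float = 5.0, high_pct: float = 95.0
) -> PercentileTrim:
    """Trim a score distribution to its [low_pct, high_pct] percentile band.

    Percentiles use the linear-interpolation empirical definition
    (:func:`numpy.percentile` default).  The trimmed extrema are descriptive
    statistics only; they feed no downstream computation.
    """
    values = np.asarray(scores, dtype=float)
    if values.size == 0:
        raise ValueError("percentile_trim requires at least one score")
    lo = float(np.percentile(values, low_pct))
    hi = float(np.percentile(values, high_pct))
    retained = (values >= lo) & (values <= hi)
    kept = values[retained]
    return PercentileTrim(
        trimmed_max=float(kept.max()),
        trimmed_min=float(kept.min()),
        retained=retained,
        low_cutoff=lo,
        high_cutoff=hi,
    )


# ---------------------------------------------------------------------------
# I/O: sparse triplet CSV and GeoJSON cell polygons


def presence_to_triplets(matrix: PresenceMatrix, path=None) -> pd.DataFrame:
    """Export the presence matrix as a (cell_x, cell_y, species) triplet table."""
    rows, cols = np.nonzero(matrix.incidence)
    df = pd.DataFrame(
        {
            "cell_x": matrix.cells[rows, 0],
            "cell_y": matrix.cells[rows, 1],
            "species": matrix.species[cols],
        }
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df


def presence_from_triplets(source) -> PresenceMatrix:
    """Rebuild a presence matrix from a triplet table (path or DataFrame)."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    species = np.array(sorted(df["species"].unique()), dtype=object)
    cells = (
        df[["cell_x", "cell_y"]]
        .drop_duplicates()
        .sort_values(["cell_x", "cell_y"], kind="mergesort")
        .to_numpy(dtype=np.int64)
    )
    cell_pos = {tuple(c): i for i, c in enumerate(cells)}
    sp_pos = {s: j for j, s in enumerate(species)}
    incidence = np.zeros((len(cells), len(species)), dtype=np.uint8)
    for cx, cy, sp in df[["cell_x", "cell_y", "species"]].itertuples(index=False):
        incidence[cell_pos[(cx, cy)], sp_pos[sp]] = 1
    return PresenceMatrix(cells, species, incidence)


def scores_to_geojson(scores: pd.DataFrame, grid: GridSpec, path=None) -> dict:
    """Render a per-cell score table as a GeoJSON FeatureCollection of squares."""
    features = []
    prop_cols = [c for c in scores.columns if c not in ("cell_x", "cell_y")]
    for row in scores.itertuples(index=False):
        w, s, e, n = grid.cell_bounds(int(row.cell_x), int(row.cell_y))
        props = {c: getattr(row, c) for c in prop_cols}
        props = {
            k: (bool(v) if isinstance(v, np.bool_) else float(v) if isinstance(v, (np.floating,)) else int(v) if isinstance(v, (np.integer,)) else v)
            for k, v in props.items()
        }
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[w, s], [e, s], [e, n], [w, n], [w, s]]],
                },
                "properties": {"cell_x": int(row.cell_x), "cell_y": int(row.cell_y), **props},
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(collection, fh)
    return collection
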