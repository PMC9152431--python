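"""Conservation gap analysis: protected areas vs. diversity surfaces and impact.

Three independent overlays, combined into one table per protected area:

* *spatial coincidence* — does the area's polygon intersect the square of at
  least one occupied grid cell (boundary touch counts);
* *species count* — distinct species with at least one cleaned occurrence
  point inside (or on the boundary of) the polygon;
* *mean footprint* — unweighted arithmetic mean of the impact raster over the
  pixels whose center falls inside the polygon, ignoring nodata; undefined
  (NaN) when no pixel center falls inside.

All geometries are WGS84 longitude/latitude, matching the graticule grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid_metrics import GridSpec, PresenceMatrix
from .rasters import ImpactRaster

__all__ = [
    "ProtectedArea",
    "read_protected_areas",
    "write_protected_areas",
    "overlap_with_cells",
    "species_per_area",
    "footprint_zonal_mean",
    "gap_report",
]


@dataclass
class ProtectedArea:
    """One protected area: identifier, name, country, WGS84 (multi)polygon."""

    id: str
    name: str
    country: str
    geometry: BaseGeometry
    notes: dict = field(default_factory=dict)


def _repair(area: ProtectedArea) -> ProtectedArea | None:
    """Zero-width-buffer repair; None (with a note) if the geometry stays invalid."""
    geom = area.geometry
    if geom is None or geom.is_empty:
        area.notes["excluded"] = "empty geometry"
        return None
    if not geom.is_valid:
        geom = geom.buffer(0)
        if not geom.is_valid or geom.is_empty:
            area.notes["excluded"] = "invalid geometry after repair"
            return None
        area.geometry = geom
        area.notes["repaired"] = True
    return area


def read_protected_areas(path) -> list[ProtectedArea]:
    """Load protected areas from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        collection = json.load(fh)
    areas = []
    for i, feat in enumerate(collection.get("features", [])):
        props = feat.get("properties") or {}
        areas.append(
            ProtectedArea(
                id=str(props.get("id", f"PA{i:04d}")),
                name=str(props.get("name", f"area {i}")),
                country=str(props.get("country", "")),
                geometry=shape(feat["geometry"]),
            )
        )
    return areas


def write_protected_areas(areas: list[ProtectedArea], path) -> None:
    collection = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(a.geometry),
                "properties": {"id": a.id, "name": a.name, "country": a.country},
            }
            for a in areas
        ],
    }
    with open(path, "w") as fh:
        json.dump(collection, fh)


def overlap_with_cells(
    areas: list[ProtectedArea], matrix: PresenceMatrix, grid: GridSpec
) -> tuple[pd.Series, int]:
    """Flag each area that intersects at least one occupied grid cell.

    Returns the per-area boolean series (indexed by area id) and the number of
    coinciding areas.  Invalid geometries are repaired with a zero-width
    buffer; unrepairable ones are excluded and flagged in ``area.notes``.
    """
    cell_boxes = [box(*grid.cell_bounds(cx, cy)) for cx, cy in matrix.cells]
    tree = shapely.STRtree(cell_boxes)
    flags = {}
    for area in areas:
        repaired = _repair(area)
        if repaired is None:
            flags[area.id] = False
            continue
        hits = tree.query(repaired.geometry, predicate="intersects")
        flags[area.id] = bool(len(hits))
    series = pd.Series(flags, name="coincides_with_grid", dtype=bool)
    return series, int(series.sum())


def species_per_area(areas: list[ProtectedArea], records: pd.DataFrame) -> pd.Series:
    """Distinct species with a record inside each area (boundary-inclusive)."""
    lon = records["longitude"].to_numpy(dtype=float)
    lat = records["latitude"].to_numpy(dtype=float)
    species = records["species"].to_numpy()
    counts = {}
    for area in areas:
        repaired = _repair(area)
        if repaired is None:
            counts[area.id] = 0
            continue
        geom = repaired.geometry
        shapely.prepare(geom)
        inside = shapely.intersects_xy(geom, lon, lat)  # True on the boundary too
        counts[area.id] = int(pd.unique(species[inside]).size)
    return pd.Series(counts, name="n_species", dtype=int)


def footprint_zonal_mean(area: ProtectedArea, raster: ImpactRaster) -> float:
    """Mean impact over pixels whose center lies inside the area.

    Nodata pixels are ignored; returns NaN (undefined) when no valid pixel
    center falls inside — never 0.
    """
    repaired = _repair(area)
    if repaired is None:
        return float("nan")
    geom = repaired.geometry
    minx, miny, maxx, maxy = geom.bounds
    res = raster.resolution
    # candidate pixel window from the geometry envelope
    col0 = max(int(np.floor((minx - raster.west) / res)) - 1, 0)
    col1 = min(int(np.ceil((maxx - raster.west) / res)) + 1, raster.n_cols)
    row0 = max(int(np.floor((raster.north - maxy) / res)) - 1, 0)
    row1 = min(int(np.ceil((raster.north - miny) / res)) + 1, raster.n_rows)
    if col0 >= col1 or row0 >= row1:
        return float("nan")
    xs = raster.west + (np.arange(col0, col1) + 0.5) * res
    ys = raster.north - (np.arange(row0, row1) + 0.5) * res
    gx, gy = np.meshgrid(xs, ys)
    shapely.prepare(geom)
    inside = shapely.intersects_xy(geom, gx.ravel(), gy.ravel())
    window = raster.values[row0:row1, col0:col1].ravel()
    vals = window[inside & (window != raster.nodata)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def gap_report(
    areas: list[ProtectedArea],
    matrix: PresenceMatrix | None,
    grid: GridSpec | None,
    records: pd.DataFrame,
    raster: ImpactRaster | None = None,
) -> pd.DataFrame:
    """Combine the three overlays into one table, sorted by species count.

    Columns: area_id, name, country, n_species, mean_footprint,
    coincides_with_grid.  Sorted by ``n_species`` descending with ``name`` as
    the tie-breaker.  ``raster=None`` leaves ``mean_footprint`` as NaN;
    ``matrix=None`` leaves ``coincides_with_grid`` false.
    """
    if not areas:
        return pd.DataFrame(
            columns=[
                "area_id",
                "name",
                "country",
                "n_species",
                "mean_footprint",
                "coincides_with_grid",
            ]
        )
    n_species = species_per_area(areas, records)
    if matrix is not None and grid is not None:
        coincides, _ = overlap_with_cells(areas, matrix, grid)
    else:
        coincides = pd.Series(False, index=[a.id for a in areas])
    footprint = {
        a.id: (footprint_zonal_mean(a, raster) if raster is not None else float("nan"))
        for a in areas
    }
    table = pd.DataFrame(
        {
            "area_id": [a.id for a in areas],
            "name": [a.name for a in areas],
            "country": [a.country for a in areas],
            "n_species": [int(n_species[a.id]) for a in areas],
            "mean_footprint": [footprint[a.id] for a in areas],
            "coincides_with_grid": [bool(coincides[a.id]) for a in areas],
        }
    )
    return table.sort_values(
        ["n_species", "name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
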