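"""Synthetic occurrence landscapes, protected areas and impact rasters.

Every pipeline stage can be exercised without external downloads: the
generator emits point occurrence records with known per-species occupancy
(the *ground truth*), rectangular protected areas, and a bounded impact
raster, all reproducible from one seed.

The occupancy model mirrors the structure of real range data: each species
draws a range size (optionally heavy-tailed, log-series), occupies that many
grid cells — scattered uniformly or grown as a spatially cohesive blob by
randomized breadth-first accretion — and emits at least one record per
occupied cell so the gridded presence matrix reproduces the ground truth
exactly.  Narrow-endemic *planted centers* (k species confined to one chosen
cell) provide landscapes with a known endemism signal for power studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import box

from .gap_analysis import ProtectedArea
from .grid_metrics import GridSpec
from .occurrences import FLAG_COLUMNS, RECORD_COLUMNS
from .rasters import ImpactRaster

__all__ = [
    "SyntheticConfig",
    "generate_occurrences",
    "generate_protected_areas",
    "generate_footprint_raster",
]


@dataclass
class SyntheticConfig:
    """Controls for the synthetic occurrence generator.

    ``range_size`` is a distribution spec: ``("fixed", [r1, r2, ...])`` cycles
    the list, ``("uniform", lo, hi)`` draws integers inclusively, and
    ``("logseries", p)`` draws from the log-series with parameter ``p``
    (heavy-tailed, the classic range-size/abundance shape), truncated to the
    number of cells in the extent.  ``records_per_species`` is ``("fixed", n)``
    or ``("poisson", mean)`` and is a floor: at least one record is always
    emitted per occupied cell so the ground truth is recoverable.

    ``planted_centers`` is a list of ``((cell_x, cell_y), n_endemics)`` pairs
    (global cell indices): each planted species occupies exactly that cell.
    """

    n_species: int = 60
    records_per_species: tuple = ("poisson", 8.0)
    range_size: tuple = ("logseries", 0.9)
    spatial_model: str = "scattered"  # "scattered" | "cohesive"
    planted_centers: list = field(default_factory=list)
    extent: tuple[float, float, float, float] = (-75.0, -40.0, -60.0, -25.0)
    cell_size: float = 1.0
    n_genera: int | None = None
    countries: tuple[str, str] | None = ("Westland", "Eastland")
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 0:
            raise ValueError("n_species must be >= 0")
        if self.spatial_model not in ("scattered", "cohesive"):
            raise ValueError("spatial_model must be 'scattered' or 'cohesive'")
        if self.planted_centers:
            grid = self.grid()
            for (cx, cy), n in self.planted_centers:
                if n < 0:
                    raise ValueError("planted endemic count must be >= 0")
                w, s, e, nth = grid.cell_bounds(cx, cy)
                x0, y0, x1, y1 = self.extent
                if not (x0 <= w and e <= x1 and y0 <= s and nth <= y1):
                    raise ValueError(f"planted cell ({cx}, {cy}) outside extent")

    def grid(self) -> GridSpec:
        return GridSpec(cell_size=self.cell_size, extent=self.extent)

    def extent_cells(self) -> np.ndarray:
        """Global (cell_x, cell_y) indices of every cell in the extent."""
        g = self.grid()
        x0, y0, x1, y1 = self.extent
        ix0, iy0 = g.cell_index(x0, y0)
        # upper edge belongs to the next cell; stay strictly inside the extent
        nx = int(round((x1 - x0) / self.cell_size))
        ny = int(round((y1 - y0) / self.cell_size))
        xs, ys = np.meshgrid(
            np.arange(ix0, ix0 + nx), np.arange(iy0, iy0 + ny), indexing="ij"
        )
        return np.column_stack([xs.ravel(), ys.ravel()])


def _draw_range_sizes(config: SyntheticConfig, n: int, n_cells: int, rng) -> np.ndarray:
    kind = config.range_size[0]
    if kind == "fixed":
        values = list(config.range_size[1])
        sizes = np.array([values[i % len(values)] for i in range(n)], dtype=int)
        if (sizes > n_cells).any():
            raise ValueError("requested range size exceeds number of cells in extent")
        return sizes
    if kind == "uniform":
        lo, hi = int(config.range_size[1]), int(config.range_size[2])
        if hi > n_cells:
            raise ValueError("requested range size exceeds number of cells in extent")
        return rng.integers(lo, hi + 1, size=n)
    if kind == "logseries":
        p = float(config.range_size[1])
        sizes = stats.logser.rvs(p, size=n, random_state=rng)
        return np.minimum(sizes, n_cells)  # truncate the heavy tail to the extent
    raise ValueError(f"unknown range_size spec: {config.range_size!r}")


def _grow_blob(all_cells: set, start: tuple, size: int, rng) -> list[tuple]:
    """Randomized breadth-first accretion of a contiguous cell blob."""
    blob = [start]
    frontier: list[tuple] = []
    seen = {start}

    def push_neighbors(cell):
        cx, cy = cell
        for nb in ((cx + 1, cy), (cx - 1, cy), (cx, cy + 1), (cx, cy - 1)):
            if nb in all_cells and nb not in seen:
                frontier.append(nb)
                seen.add(nb)

    push_neighbors(start)
    while len(blob) < size and frontier:
        k = rng.integers(len(frontier))
        cell = frontier.pop(int(k))
        blob.append(cell)
        push_neighbors(cell)
    return blob


def generate_occurrences(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate occurrence records plus the ground-truth occupancy table.

    Returns ``(records, ground_truth)``: records in the canonical occurrence
    schema (clean — no flags set), and the ground truth with one row per
    (species, occupied cell) and a ``planted`` marker.  Presence matrices
    built from the records at ``config.cell_size`` equal the ground truth
    exactly, because every occupied cell receives at least one record.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    cells = config.extent_cells()
    n_cells = len(cells)
    if n_cells == 0:
        raise ValueError("extent contains no cells")
    cell_set = {tuple(c) for c in cells}

    n_genera = config.n_genera or max(1, config.n_species // 12)
    names = [
        f"Genus{(i % n_genera):02d} species{i:03d}" for i in range(config.n_species)
    ]

    sizes = _draw_range_sizes(config, config.n_species, n_cells, rng)
    occupancy: list[tuple[str, int, int, bool]] = []
    for name, size in zip(names, sizes):
        size = int(size)
        if config.spatial_model == "scattered":
            chosen = cells[rng.choice(n_cells, size=size, replace=False)]
            chosen = [tuple(c) for c in chosen]
        else:
            start = tuple(cells[int(rng.integers(n_cells))])
            chosen = _grow_blob(cell_set, start, size, rng)
        for cx, cy in chosen:
            occupancy.append((name, cx, cy, False))

    for k, ((cx, cy), n_endemics) in enumerate(config.planted_centers):
        for j in range(n_endemics):
            occupancy.append((f"Endemic{k:02d} planted{j:03d}", cx, cy, True))

    truth = pd.DataFrame(occupancy, columns=["species", "cell_x", "cell_y", "planted"])

    # per-species record budget; floor of one record per occupied cell
    rows = []
    for species, group in truth.groupby("species", sort=True):
        occ = group[["cell_x", "cell_y"]].to_numpy()
        kind, param = config.records_per_species
        if kind == "fixed":
            budget = int(param)
        elif kind == "poisson":
            budget = int(rng.poisson(float(param)))
        else:
            raise ValueError(f"unknown records_per_species spec: {config.records_per_species!r}")
        extra = max(budget - len(occ), 0)
        targets = list(range(len(occ))) + list(rng.integers(len(occ), size=extra))
        for t in targets:
            cx, cy = int(occ[t, 0]), int(occ[t, 1])
            w, s, e, n = grid.cell_bounds(cx, cy)
            u, v = rng.random(2)
            rows.append((species, w + u * (e - w), s + v * (n - s)))

    records = pd.DataFrame(rows, columns=["species", "longitude", "latitude"])
    records["genus"] = records["species"].str.split().str[0]
    if config.countries is not None:
        x0, _, x1, _ = config.extent
        mid = 0.5 * (x0 + x1)
        west, east = config.countries
        records["country"] = np.where(records["longitude"] < mid, west, east)
    else:
        records["country"] = ""
    for flag in FLAG_COLUMNS:
        records[flag] = False
    records = records[list(RECORD_COLUMNS)].sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    return records, truth


def generate_protected_areas(
    extent: tuple[float, float, float, float],
    n_areas: int,
    size_range: tuple[float, float] = (0.5, 3.0),
    seed: int = 0,
    countries: tuple[str, str] | None = ("Westland", "Eastland"),
) -> list[ProtectedArea]:
    """Random non-degenerate rectangles within the extent, reproducible by seed."""
    if n_areas < 0:
        raise ValueError("n_areas must be >= 0")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = extent
    lo, hi = size_range
    if not (0 < lo <= hi):
        raise ValueError("size_range must be positive and ordered")
    areas = []
    for i in range(n_areas):
        w = min(float(rng.uniform(lo, hi)), (x1 - x0) * 0.9)
        h = min(float(rng.uniform(lo, hi)), (y1 - y0) * 0.9)
        px = float(rng.uniform(x0, x1 - w))
        py = float(rng.uniform(y0, y1 - h))
        geom = box(px, py, px + w, py + h)
        if countries is not None:
            country = countries[0] if geom.centroid.x < 0.5 * (x0 + x1) else countries[1]
        else:
            country = ""
        areas.append(
            ProtectedArea(id=f"PA{i:04d}", name=f"Reserve {i:04d}", country=country, geometry=geom)
        )
    return areas


def generate_footprint_raster(
    extent: tuple[float, float, float, float],
    resolution: float,
    model: tuple = ("constant", 20.0),
    seed: int = 0,
) -> ImpactRaster:
    """Impact raster on the 0–100 scale over the extent.

    Models: ``("constant", v)``; ``("gradient", axis, lo, hi)`` monotone along
    ``axis`` ("x" or "y", increasing eastward / northward); ``("blobs", n,
    amplitude)`` — a low background plus ``n`` random Gaussian bumps, clipped
    to [0, 100].
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    x0, y0, x1, y1 = extent
    n_cols = max(int(round((x1 - x0) / resolution)), 1)
    n_rows = max(int(round((y1 - y0) / resolution)), 1)
    rng = np.random.default_rng(seed)

    kind = model[0]
    if kind == "constant":
        values = np.full((n_rows, n_cols), float(model[1]))
    elif kind == "gradient":
        axis, lo, hi = model[1], float(model[2]), float(model[3])
        ramp = np.linspace(lo, hi, n_cols if axis == "x" else n_rows)
        if axis == "x":
            values = np.tile(ramp, (n_rows, 1))
        else:
            values = np.tile(ramp[::-1, None], (1, n_cols))  # row 0 is north
    elif kind == "blobs":
        n_blobs, amplitude = int(model[1]), float(model[2])
        xs = x0 + (np.arange(n_cols) + 0.5) * resolution
        ys = y1 - (np.arange(n_rows) + 0.5) * resolution
        gx, gy = np.meshgrid(xs, ys)
        values = np.full((n_rows, n_cols), 5.0)
        for _ in range(n_blobs):
            cx = rng.uniform(x0, x1)
            cy = rng.uniform(y0, y1)
            sigma = rng.uniform(0.02, 0.08) * max(x1 - x0, y1 - y0)
            values += amplitude * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sigma**2))
    else:
        raise ValueError(f"unknown raster model: {model!r}")

    return ImpactRaster(
        values=np.clip(values, 0.0, 100.0),
        west=x0,
        north=y1,
        resolution=resolution,
    )
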