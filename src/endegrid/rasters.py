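"""Minimal georeferenced single-band raster for human-footprint overlays.

The human-footprint index is a 0–100 composite of human influence (population
density, land transformation, accessibility, infrastructure).  Here it is held
as a north-up numpy grid with a simple origin/resolution georeferencing in
WGS84 and read/written as ESRI ASCII grid (``.asc``) — a plain-text format any
GIS ingests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImpactRaster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class ImpactRaster:
    """Single-band impact raster, row 0 at the northern edge.

    ``west``/``north`` are the outer corner of the top-left pixel; pixel
    centers are at ``west + (col + 0.5) * resolution`` and
    ``north - (row + 0.5) * resolution``.  Non-nodata values must lie in
    [0, 100].
    """

    values: np.ndarray  # (n_rows, n_cols) float
    west: float
    north: float
    resolution: float
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        data = self.values[self.values != self.nodata]
        if data.size and (data.min() < 0 or data.max() > 100):
            raise ValueError("impact values must lie in [0, 100]")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.resolution

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.resolution

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat arrays of pixel-center x and y coordinates."""
        xs = self.west + (np.arange(self.n_cols) + 0.5) * self.resolution
        ys = self.north - (np.arange(self.n_rows) + 0.5) * self.resolution
        gx, gy = np.meshgrid(xs, ys)
        return gx.ravel(), gy.ravel()

    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) pixels."""
        return self.values != self.nodata


def write_ascii_grid(raster: ImpactRaster, path) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    header = (
        f"NCOLS {raster.n_cols}\n"
        f"NROWS {raster.n_rows}\n"
        f"XLLCORNER {raster.west!r}\n"
        f"YLLCORNER {raster.south!r}\n"
        f"CELLSIZE {raster.resolution!r}\n"
        f"NODATA_VALUE {raster.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt="%.6g")


def read_ascii_grid(path) -> ImpactRaster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().upper()
            if key in {"NCOLS", "NROWS", "XLLCORNER", "YLLCORNER", "CELLSIZE", "NODATA_VALUE"}:
                header[key] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    n_rows = int(header["NROWS"])
    res = header["CELLSIZE"]
    if values.shape != (n_rows, int(header["NCOLS"])):
        raise ValueError("ASCII grid data does not match its header dimensions")
    return ImpactRaster(
        values=values,
        west=header["XLLCORNER"],
        north=header["YLLCORNER"] + n_rows * res,
        resolution=res,
        nodata=header.get("NODATA_VALUE", -9999.0),
    )
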