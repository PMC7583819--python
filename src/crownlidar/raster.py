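"""Gridded rasters (canopy height model, segment labels) on a regular grid.

The grid follows the usual raster convention: continuous (x, y) maps to
cell ``col = floor((x - x_min)/res)``, ``row = floor((y - y_min)/res)``;
cells are half-open.  Row 0 is the *southern* edge (y = y_min); values
are stored with NaN for no-data in memory and written as -9999 in the
ESRI ASCII grid text format.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NODATA = -9999.0


@dataclass
class CHMRaster:
    """Canopy height model: per-cell maximum normalized height (m)."""

    values: np.ndarray  # (nrows, ncols), float, NaN = no-data
    resolution: float
    origin: tuple  # (x_min, y_min)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("CHM values must be a 2-D grid")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def cell_of(self, x, y) -> tuple:
        """Map continuous coordinates to (row, col) cell indices."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.resolution).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.resolution).astype(int)
        return row, col

    def center_of(self, row, col) -> tuple:
        """Cell-center coordinates of (row, col)."""
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.resolution
        y = self.origin[1] + (np.asarray(row) + 0.5) * self.resolution
        return x, y

    def max(self) -> float:
        if not self.valid.any():
            raise ValueError("CHM has no valid cells")
        return float(np.nanmax(self.values))

    def save(self, path) -> None:
        write_ascii_grid(path, self.values, self.resolution, self.origin)

    @classmethod
    def load(cls, path) -> "CHMRaster":
        values, resolution, origin = read_ascii_grid(path)
        return cls(values, resolution, origin)


def write_ascii_grid(path, values, resolution, origin, nodata=NODATA) -> None:
    """Write a grid in ESRI ASCII format (row 0 stored as northern edge)."""
    out = np.asarray(values, dtype=float)
    nrows, ncols = out.shape
    flipped = np.flipud(out)  # file rows run north to south
    flipped = np.where(np.isfinite(flipped), flipped, nodata)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {origin[0]:.6f}\n"
        f"yllcorner {origin[1]:.6f}\n"
        f"cellsize {resolution:.6f}\n"
        f"NODATA_value {nodata:.1f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, flipped, fmt="%.4f")


def read_ascii_grid(path):
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.flipud(np.atleast_2d(values))
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    origin = (header["xllcorner"], header["yllcorner"])
    return values, header["cellsize"], origin
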