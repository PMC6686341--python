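"""Planar raster grids on a regular square-cell lattice.

All spatial layers in this package (burn year, unburned-island mask,
vegetation type/height class, elevation, cheatgrass cover) live on
axis-aligned grids in a planar CRS with units of meters.  The container
deliberately stays minimal: a 2-D numpy array, a cell size, and the world
coordinate of the upper-left corner.  Row 0 is the northernmost row, so
world y decreases with row index.

Text I/O uses the ESRI ASCII grid format (.asc), which round-trips through
any GIS package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "disc_mask"]


@dataclass
class RasterGrid:
    """A single-band raster on a square-cell planar grid.

    Parameters
    ----------
    data
        2-D array, row 0 = northern edge.
    cell_size
        Cell edge length in meters.
    origin
        (x, y) world coordinate of the grid's upper-left corner.
    nodata
        Value marking cells with no data (default -9999).
    """

    data: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edge."""
        nrows, ncols = self.data.shape
        x0, y0 = self.origin
        return (x0, y0 - nrows * self.cell_size, x0 + ncols * self.cell_size, y0)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of every cell center as (X, Y) meshgrids."""
        nrows, ncols = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing world point (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        nrows, ncols = self.data.shape
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def value_at(self, x: float, y: float):
        row, col = self.index_of(x, y)
        return self.data[row, col]

    def same_grid_as(self, other: "RasterGrid") -> bool:
        """True when shapes, cell sizes and origins coincide exactly."""
        return (
            self.data.shape == other.data.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )

    def copy_with(self, data: np.ndarray) -> "RasterGrid":
        if data.shape != self.data.shape:
            raise ValueError("replacement data must keep the grid shape")
        return RasterGrid(data, self.cell_size, self.origin, self.nodata)

    # -- text I/O ----------------------------------------------------------

    def write_ascii(self, path: str | Path, fmt: str = "%.6g") -> None:
        """Write as an ESRI ASCII grid (plain text)."""
        nrows, ncols = self.data.shape
        x0, y0 = self.origin
        yll = y0 - nrows * self.cell_size
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner {x0:.6f}\n"
            f"yllcorner {yll:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            f"NODATA_value {self.nodata:g}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data, fmt=fmt)


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :meth:`RasterGrid.write_ascii`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"grid body {data.shape} disagrees with header ({nrows}, {ncols})")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return RasterGrid(data, cell, origin, header.get("nodata_value", -9999.0))


def disc_mask(grid: RasterGrid, center: tuple[float, float], radius_m: float) -> np.ndarray:
    """Boolean mask of cells whose center lies inside a circle.

    Membership is by cell center, so the discretized disc area converges to
    pi*r^2 as the radius grows relative to the cell size.

    Raises
    ------
    ValueError
        If the circle extends beyond the raster's outer edge; callers must
        pad synthetic extents so every queried disc is fully covered.
    """
    cx, cy = center
    xmin, ymin, xmax, ymax = grid.extent
    if cx - radius_m < xmin or cx + radius_m > xmax or cy - radius_m < ymin or cy + radius_m > ymax:
        raise ValueError(
            f"disc of radius {radius_m} m at ({cx}, {cy}) extends beyond the raster extent"
        )
    X, Y = grid.cell_centers()
    return (X - cx) ** 2 + (Y - cy) ** 2 <= radius_m**2
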