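"""Planar equal-area grids and single-band raster layers.

The whole pipeline operates on a planar equal-area frame with square
1-km² pixels (an abstraction of the Albers-type grids used for
continental-scale habitat modeling).  Pixel ``(row, col)`` covers the
half-open square

    [origin_x + col*s, origin_x + (col+1)*s) x [origin_y + row*s, origin_y + (row+1)*s)

with ``s`` the cell size in km, so row 0 is the *southern* edge.  Raster
files use the ESRI ASCII grid format (plain text, nodata -9999); in
memory, nodata cells are NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a planar equal-area raster grid."""

    n_rows: int
    n_cols: int
    cell_size_km: float = 1.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_tag: str = "planar-equal-area-km"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    def pixel_of(self, x_km: float, y_km: float) -> tuple[int, int]:
        """Return the (row, col) of the pixel containing a point.

        Uses the half-open convention: a point exactly on a shared edge
        belongs to the pixel whose low (south/west) edge it touches.
        Raises ``ValueError`` for points outside the grid footprint.
        """
        s = self.cell_size_km
        col = math.floor((x_km - self.origin_x) / s)
        row = math.floor((y_km - self.origin_y) / s)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(
                f"point ({x_km}, {y_km}) is outside the grid footprint"
            )
        return (row, col)

    def contains(self, x_km: float, y_km: float) -> bool:
        s = self.cell_size_km
        return (
            self.origin_x <= x_km < self.origin_x + self.n_cols * s
            and self.origin_y <= y_km < self.origin_y + self.n_rows * s
        )

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        s = self.cell_size_km
        return (
            self.origin_x + (col + 0.5) * s,
            self.origin_y + (row + 0.5) * s,
        )


@dataclass
class RasterLayer:
    """One named single-band raster aligned to a :class:`GridSpec`.

    ``values`` is a float array of shape ``grid.shape`` indexed
    ``[row, col]`` with row 0 at the southern edge; nodata is NaN.
    """

    grid: GridSpec
    name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"does not match grid shape {self.grid.shape}"
            )

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterLayer":
        return RasterLayer(self.grid, name or self.name, values, self.units)


def check_aligned(layers) -> GridSpec:
    """Verify all layers share one grid; return it."""
    layers = list(layers)
    if not layers:
        raise ValueError("no layers given")
    grid = layers[0].grid
    for lyr in layers[1:]:
        if lyr.grid != grid:
            raise ValueError(
                f"layer {lyr.name!r} grid {lyr.grid.shape} is not aligned "
                f"with {layers[0].name!r} grid {grid.shape}"
            )
    return grid


def write_ascii_grid(layer: RasterLayer, path) -> None:
    """Write a layer as an ESRI ASCII grid (row 0 written last)."""
    path = Path(path)
    g = layer.grid
    vals = np.where(np.isnan(layer.values), NODATA, layer.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.origin_x!r}\n")
        fh.write(f"yllcorner {g.origin_y!r}\n")
        fh.write(f"cellsize {g.cell_size_km!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        # ESRI ASCII grids list the northernmost row first.
        for row in vals[::-1]:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path, name: str | None = None, units: str = "") -> RasterLayer:
    """Read an ESRI ASCII grid into a :class:`RasterLayer`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {data.shape} does not match header")
    nodata = header.get("nodata_value", NODATA)
    data = data[::-1]  # back to row 0 = south
    data[data == nodata] = np.nan
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size_km=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
    )
    return RasterLayer(grid, name or path.stem, data, units)
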