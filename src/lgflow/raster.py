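"""Georeferenced raster grids and raster algebra.

A :class:`Raster` is a row-major 2-D float grid with a NoData mask, a square
cell size and a lower-left origin, i.e. the minimal georeferencing the ESRI
ASCII grid format carries.  Row 0 is the *top* row of the map, matching the
on-disk order of ASCII grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


class RasterError(ValueError):
    """Invalid raster construction or incompatible raster operands."""


@dataclass
class Raster:
    """A single-band raster. NoData cells are NaN in :attr:`grid`."""

    grid: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise RasterError("raster grid must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise RasterError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean NoData mask (True = NoData)."""
        return np.isnan(self.grid)

    def copy_with(self, grid: np.ndarray, **meta) -> "Raster":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return replace(self, grid=np.asarray(grid, dtype=float), meta=new_meta)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Projected (x, y) of a cell center; row 0 is the top row."""
        nrows = self.grid.shape[0]
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (nrows - row - 0.5) * self.cell_size
        return x, y

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing projected point (x, y)."""
        nrows = self.grid.shape[0]
        col = int((x - self.origin[0]) / self.cell_size)
        row = nrows - 1 - int((y - self.origin[1]) / self.cell_size)
        if not (0 <= row < nrows and 0 <= col < self.grid.shape[1]):
            raise RasterError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def values_equal(self, other: "Raster", atol: float = 1e-9) -> bool:
        if self.shape != other.shape:
            return False
        if not np.array_equal(self.mask, other.mask):
            return False
        a, b = self.grid[~self.mask], other.grid[~other.mask]
        return bool(np.allclose(a, b, atol=atol, rtol=0.0))


def grids_aligned(a: Raster, b: Raster, atol: float = 1e-9) -> bool:
    return (
        a.shape == b.shape
        and abs(a.cell_size - b.cell_size) <= atol
        and abs(a.origin[0] - b.origin[0]) <= atol
        and abs(a.origin[1] - b.origin[1]) <= atol
    )


def focal_mean(raster: Raster, radius: float) -> Raster:
    """Circular moving-window mean of non-masked cells.

    Each output cell is the mean of input cells whose centers lie within
    ``radius`` map units of the focal cell center.  NoData cells do not
    contribute and remain NoData in the output.
    """
    if radius < raster.cell_size:
        raise RasterError("focal radius must be at least one cell")
    r_cells = int(np.floor(radius / raster.cell_size))
    yy, xx = np.mgrid[-r_cells : r_cells + 1, -r_cells : r_cells + 1]
    kernel = ((yy**2 + xx**2) * raster.cell_size**2 <= radius**2).astype(float)

    valid = (~raster.mask).astype(float)
    filled = np.where(raster.mask, 0.0, raster.grid)
    num = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    out[raster.mask] = np.nan
    return raster.copy_with(out, focal_radius=radius)


def resample_bilinear(raster: Raster, target_cell: float) -> Raster:
    """Bilinear resampling onto a coarser grid with the same origin/extent.

    Values are interpolated at the centers of the target cells from the four
    surrounding source cell centers; a target cell becomes NoData if any
    contributing source cell is NoData.  Upsampling is rejected.
    """
    if target_cell < raster.cell_size:
        raise RasterError("target cell size must not be finer than the source")
    nrows, ncols = raster.shape
    height = nrows * raster.cell_size
    width = ncols * raster.cell_size
    t_rows = max(int(round(height / target_cell)), 1)
    t_cols = max(int(round(width / target_cell)), 1)

    # target cell-center coordinates expressed in source pixel index space
    rr = (np.arange(t_rows) + 0.5) * target_cell / raster.cell_size - 0.5
    cc = (np.arange(t_cols) + 0.5) * target_cell / raster.cell_size - 0.5
    ri, ci = np.meshgrid(rr, cc, indexing="ij")
    coords = np.stack([ri.ravel(), ci.ravel()])

    filled = np.where(raster.mask, 0.0, raster.grid)
    vals = ndimage.map_coordinates(filled, coords, order=1, mode="nearest")
    bad = ndimage.map_coordinates(
        raster.mask.astype(float), coords, order=1, mode="nearest"
    )
    out = vals.reshape(t_rows, t_cols)
    out[bad.reshape(t_rows, t_cols) > 0] = np.nan
    return Raster(
        out, cell_size=target_cell, origin=raster.origin, meta=dict(raster.meta)
    )


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (.asc). NODATA_value cells become NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            }:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    if "ncols" not in header or "nrows" not in header:
        raise RasterError(f"{path}: missing ncols/nrows header")
    grid = np.array(rows, dtype=float)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise RasterError(
            f"{path}: grid shape {grid.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        grid[grid == nodata] = np.nan
    return Raster(
        grid,
        cell_size=header.get("cellsize", 1.0),
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )


def write_ascii_grid(raster: Raster, path, nodata: float = -9999.0) -> None:
    nrows, ncols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]!r}\n")
        fh.write(f"yllcorner {raster.origin[1]!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        out = np.where(raster.mask, nodata, raster.grid)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
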