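"""Planar raster containers and grid bookkeeping.

All grids live in a CRS-free planar coordinate system in metres. Arrays are
indexed ``[row, col]`` with row 0 at the *southern* edge, so the cell centre
of ``[r, c]`` is ``origin + (c + 0.5, r + 0.5) * cell_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FineRasterStack", "pixel_grid", "pixel_index"]


@dataclass
class FineRasterStack:
    """Fine-resolution tree cover (% in year 0) and first-loss-year rasters.

    ``lossyear`` is 0 where a cell is never cleared and ``t`` (1-based) for
    the first year in which it is; a cell can be lost at most once.
    """

    treecover2000: np.ndarray  # float %, shape (ny, nx)
    lossyear: np.ndarray  # int, same shape
    cell_size: float  # metres
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) of the SW corner

    def __post_init__(self):
        tc = np.asarray(self.treecover2000, dtype=float)
        ly = np.asarray(self.lossyear)
        if tc.shape != ly.shape:
            raise ValueError("treecover2000 and lossyear grids must be congruent")
        if tc.min() < 0 or tc.max() > 100:
            raise ValueError("tree cover must lie in [0, 100] percent")
        if np.any(ly < 0):
            raise ValueError("lossyear must be >= 0")
        self.treecover2000 = tc
        self.lossyear = ly.astype(np.int32)

    @property
    def shape(self):
        return self.treecover2000.shape

    @property
    def n_years(self) -> int:
        return int(self.lossyear.max())

    def cell_centres(self):
        ny, nx = self.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return x, y


def pixel_grid(width, height, pixel_size=1000.0, origin=(0.0, 0.0)):
    """Table of 1 km^2 (by default) analysis pixels covering the extent.

    Returns (pixel_id array, x centroids, y centroids, n_rows, n_cols) with
    ``pixel_id = row * n_cols + col`` anchored at the raster origin.
    """
    n_cols = int(round(width / pixel_size))
    n_rows = int(round(height / pixel_size))
    if abs(n_cols * pixel_size - width) > 1e-6 or abs(n_rows * pixel_size - height) > 1e-6:
        raise ValueError("extent is not divisible by the pixel size")
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    x = origin[0] + (cols + 0.5) * pixel_size
    y = origin[1] + (rows + 0.5) * pixel_size
    return np.arange(n_rows * n_cols), x, y, n_rows, n_cols


def pixel_index(pixel_id, n_cols):
    """(row, col) of a pixel id on the analysis lattice."""
    pixel_id = np.asarray(pixel_id)
    return pixel_id // n_cols, pixel_id % n_cols
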