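"""Regular-grid geometry shared by the simulator, kriging and raster I/O.

Grids are node-registered with a lower-left origin: node (row 0, col 0)
sits at (xmin, ymin) and values are stored row-major with row 0 at the
bottom (y increasing with row index).  All coordinates are planar
projected meters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridGeometry"]


@dataclass(frozen=True)
class GridGeometry:
    xmin: float
    ymin: float
    cell: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be > 0")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_nodes(self) -> int:
        return self.nrows * self.ncols

    @property
    def xmax(self) -> float:
        return self.xmin + (self.ncols - 1) * self.cell

    @property
    def ymax(self) -> float:
        return self.ymin + (self.nrows - 1) * self.cell

    def node_coords(self) -> np.ndarray:
        """(n_nodes, 2) array of node coordinates, row-major, bottom row first."""
        xs = self.xmin + np.arange(self.ncols) * self.cell
        ys = self.ymin + np.arange(self.nrows) * self.cell
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def nearest_node(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the nearest grid node(s); clipped to the grid."""
        col = np.clip(np.rint((np.asarray(x) - self.xmin) / self.cell).astype(int), 0, self.ncols - 1)
        row = np.clip(np.rint((np.asarray(y) - self.ymin) / self.cell).astype(int), 0, self.nrows - 1)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        half = self.cell / 2.0
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= self.xmin - half) & (x <= self.xmax + half)
            & (y >= self.ymin - half) & (y <= self.ymax + half)
        )
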