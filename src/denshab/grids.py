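"""Planar raster domain shared by every gridded quantity in the pipeline.

All coordinates are planar kilometres; rasters are row-major numpy arrays
with row 0 at the *southern* edge (y increasing with row index), so that
``values[i, j]`` sits at cell centre ``(x_min + (j+0.5)h, y_min + (i+0.5)h)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon, box


class InvalidConfigurationError(ValueError):
    """Raised when a grid or simulation parameter is not usable."""


@dataclass(frozen=True)
class GridSpec:
    """Regular square-cell grid over a rectangular study area.

    Parameters
    ----------
    x_min, y_min : float
        South-west corner (km).
    cell_size : float
        Cell edge length (km); cells are square.
    n_rows, n_cols : int
        Grid shape; the extent is derived from these and ``cell_size``.
    """

    x_min: float
    y_min: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise InvalidConfigurationError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidConfigurationError("grid must contain at least one cell")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size ** 2

    @property
    def extent_polygon(self) -> Polygon:
        return box(self.x_min, self.y_min, self.x_max, self.y_max)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` arrays of cell-centre coordinates, shape (n_rows, n_cols)."""
        x = self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size
        y = self.y_min + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (clipped to the grid)."""
        col = np.clip(((np.asarray(x) - self.x_min) // self.cell_size).astype(int), 0, self.n_cols - 1)
        row = np.clip(((np.asarray(y) - self.y_min) // self.cell_size).astype(int), 0, self.n_rows - 1)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.x_min) & (x < self.x_max) & (y >= self.y_min) & (y < self.y_max)

    def rasterize(self, geometry) -> np.ndarray:
        """Binary mask of cells whose centres fall inside ``geometry``."""
        X, Y = self.cell_centers()
        if geometry is None or geometry.is_empty:
            return np.zeros(self.shape, dtype=bool)
        shapely.prepare(geometry)
        mask = shapely.contains_xy(geometry, X.ravel(), Y.ravel())
        return mask.reshape(self.shape)

    def cells_to_polygon(self, mask: np.ndarray):
        """Union of the square cells where ``mask`` is True (may be multi-part).

        Contiguous runs of cells within each row are merged into rectangles
        before the union, which keeps the geometry count (and the union
        cost) proportional to the boundary rather than the area.
        """
        if not mask.any():
            return Polygon()
        h = self.cell_size
        rects = []
        for r in np.nonzero(mask.any(axis=1))[0]:
            row = mask[r]
            edges = np.flatnonzero(np.diff(np.concatenate(([0], row.view(np.int8), [0]))))
            for start, stop in edges.reshape(-1, 2):
                rects.append(box(self.x_min + start * h, self.y_min + r * h,
                                 self.x_min + stop * h, self.y_min + (r + 1) * h))
        return shapely.unary_union(rects)


def write_ascii_grid(path, grid: GridSpec, values: np.ndarray) -> None:
    """Write a raster as an ESRI ASCII grid (plain text, readable anywhere)."""
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError("raster shape does not match grid")
    header = (
        f"ncols {grid.n_cols}\nnrows {grid.n_rows}\n"
        f"xllcorner {grid.x_min}\nyllcorner {grid.y_min}\n"
        f"cellsize {grid.cell_size}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grids store the top row first
        np.savetxt(fh, values[::-1], fmt="%.6g")


def read_ascii_grid(path) -> tuple[GridSpec, np.ndarray]:
    with open(path) as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        values = np.loadtxt(fh)
    grid = GridSpec(
        x_min=head["xllcorner"], y_min=head["yllcorner"],
        cell_size=head["cellsize"],
        n_rows=int(head["nrows"]), n_cols=int(head["ncols"]),
    )
    return grid, np.atleast_2d(values)[::-1]
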