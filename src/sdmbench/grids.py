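"""Regular lattice geometry shared by every surface in the package.

All rasters are stored as 2D numpy arrays of shape ``(n_rows, n_cols)``
with row 0 at the *bottom* of the landscape (the grid origin is the
lower-left corner) and coordinates measured at cell centres, in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "write_esri_ascii", "read_esri_ascii"]


@dataclass(frozen=True)
class GridSpec:
    """A regular planar grid of square cells.

    Parameters
    ----------
    n_cols, n_rows:
        Number of cells along x and y. Must both be at least 8 so that
        spatial structure (gradients, regions, meshes) is resolvable.
    cell_size:
        Cell edge length in degrees (default 1.0, one-degree cells).
    origin:
        (x, y) of the lower-left corner of the grid in degrees.
    """

    n_cols: int
    n_rows: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_cols < 8 or self.n_rows < 8:
            raise ValueError("grid must be at least 8x8 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid footprint."""
        x0, y0 = self.origin
        return (x0, x0 + self.width, y0, y0 + self.height)

    @property
    def area(self) -> float:
        """Total grid area in squared coordinate units."""
        return self.width * self.height

    def x_centers(self) -> np.ndarray:
        x0 = self.origin[0]
        return x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        y0 = self.origin[1]
        return y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Two (n_rows, n_cols) arrays of cell-centre x and y coordinates."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (n, 2) falling inside the grid footprint."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        xmin, xmax, ymin, ymax = self.extent
        return (
            (pts[:, 0] >= xmin)
            & (pts[:, 0] < xmax)
            & (pts[:, 1] >= ymin)
            & (pts[:, 1] < ymax)
        )

    def point_to_cell(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map points (n, 2) to (row, col) indices of the containing cells."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if not np.all(self.contains(pts)):
            raise ValueError("point outside grid footprint")
        x0, y0 = self.origin
        cols = np.floor((pts[:, 0] - x0) / self.cell_size).astype(np.int64)
        rows = np.floor((pts[:, 1] - y0) / self.cell_size).astype(np.int64)
        cols = np.clip(cols, 0, self.n_cols - 1)
        rows = np.clip(rows, 0, self.n_rows - 1)
        return rows, cols

    def cell_to_center(
        self, rows: np.ndarray, cols: np.ndarray
    ) -> np.ndarray:
        """Cell (row, col) indices to an (n, 2) array of centre coordinates."""
        x0, y0 = self.origin
        xs = x0 + (np.asarray(cols) + 0.5) * self.cell_size
        ys = y0 + (np.asarray(rows) + 0.5) * self.cell_size
        return np.column_stack([xs, ys])

    def random_cell_centers(
        self, n: int, rng: np.random.Generator, replace: bool = True
    ) -> np.ndarray:
        """Draw n cells uniformly and return their centre coordinates."""
        idx = rng.choice(self.n_cells, size=n, replace=replace)
        rows, cols = np.divmod(idx, self.n_cols)
        return self.cell_to_center(rows, cols)


def write_esri_ascii(path, grid: GridSpec, values: np.ndarray, nodata=-9999.0) -> None:
    """Write a single surface as an ESRI ASCII grid (plain-text raster)."""
    arr = np.asarray(values, dtype=float)
    if arr.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("surface shape does not match grid")
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.10g}\n")
        fh.write(f"yllcorner {grid.origin[1]:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        # ESRI ASCII stores the top row first
        for row in arr[::-1]:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_esri_ascii(path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid back into a (GridSpec, surface) pair."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    grid = GridSpec(
        n_cols=int(header["ncols"]),
        n_rows=int(header["nrows"]),
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
    arr = np.array(rows, dtype=float)[::-1]
    if arr.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("raster body does not match header dimensions")
    return grid, arr


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True
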