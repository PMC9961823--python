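"""Grid geometry shared by every raster layer in a run.

Convention (fixed once, used everywhere): row 0 is the northern edge of the
raster; the cell center of ``(row, col)`` sits at

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y - (row + 0.5) * cell_size

with ``origin`` the north-west corner in projected map units (meters).
All distances are Euclidean distances between cell centers, in meters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridGeometry"]


@dataclass(frozen=True)
class GridGeometry:
    """Shape, resolution and placement of a raster grid."""

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.n_rows}x{self.n_cols}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size * self.cell_size

    @property
    def area_km2(self) -> float:
        """Total landscape area A_L in km^2."""
        return self.n_cells * self.cell_area_m2 * 1e-6

    def cell_centers(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Map (row, col) index arrays to an (n, 2) array of (x, y) centers."""
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        x = self.origin[0] + (cols + 0.5) * self.cell_size
        y = self.origin[1] - (rows + 0.5) * self.cell_size
        return np.column_stack([x, y])

    def validate_layer(self, arr: np.ndarray, name: str = "layer") -> None:
        if arr.shape != self.shape:
            raise ValueError(f"{name} shape {arr.shape} does not match grid {self.shape}")
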