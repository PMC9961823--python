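"""Plain-text raster I/O (ESRI ASCII grid).

Rasters are exchanged as ESRI ASCII grids (``.asc``): a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
rows from north to south. The format is text-only, self-describing and
readable by every mainstream GIS.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import GridGeometry

__all__ = ["write_ascii_grid", "read_ascii_grid"]

_NODATA = -9999


def write_ascii_grid(
    path: str | Path,
    arr: np.ndarray,
    geometry: GridGeometry,
    fmt: str = "%.6f",
) -> Path:
    """Write a single-band raster as an ESRI ASCII grid."""
    path = Path(path)
    geometry.validate_layer(arr, path.name)
    xll = geometry.origin[0]
    yll = geometry.origin[1] - geometry.n_rows * geometry.cell_size
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {xll:.6f}\n"
        f"yllcorner {yll:.6f}\n"
        f"cellsize {geometry.cell_size:.6f}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.asarray(arr), fmt=fmt)
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    """Read an ESRI ASCII grid back into ``(array, GridGeometry)``."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        arr = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    arr = np.atleast_2d(arr).reshape(n_rows, n_cols)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
    return arr, GridGeometry(n_rows=n_rows, n_cols=n_cols, cell_size=cell, origin=origin)
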