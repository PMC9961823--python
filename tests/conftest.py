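from __future__ import annotations

import numpy as np
import pytest

from econet.connectivity import Patch, PatchGraph
from econet.geometry import GridGeometry


@pytest.fixture
def geom():
    """Factory for grid geometries (default 30 m cells, origin (0, 0))."""

    def make(n_rows: int, n_cols: int, cell_size: float = 30.0, origin=(0.0, 0.0)):
        return GridGeometry(n_rows=n_rows, n_cols=n_cols, cell_size=cell_size, origin=origin)

    return make


def make_toy_patch(pid: int, area_km2: float, n_cells: int = 1) -> Patch:
    """Patch with dummy cell coordinates; only id and area matter to the indices."""
    rows = np.arange(n_cells)
    cols = np.full(n_cells, pid)
    return Patch(
        id=pid,
        rows=rows,
        cols=cols,
        area_km2=area_km2,
        boundary_rows=rows,
        boundary_cols=cols,
    )


def make_toy_graph(
    areas,
    dist,
    AL: float,
    threshold: float = 5000.0,
    p_threshold: float = 0.5,
) -> PatchGraph:
    """PatchGraph straight from an area vector and a distance matrix."""
    patches = tuple(make_toy_patch(k, a) for k, a in enumerate(areas))
    return PatchGraph(
        patches=patches,
        AL_km2=AL,
        dist_m=np.asarray(dist, dtype=float),
        threshold_m=threshold,
        p_threshold=p_threshold,
    )


def random_toy_graph(rng: np.random.Generator, n_max: int = 7) -> PatchGraph:
    """Random small patch graph for oracle-equivalence sweeps."""
    n = int(rng.integers(2, n_max + 1))
    areas = rng.uniform(0.5, 5.0, size=n)
    d = rng.uniform(500.0, 12000.0, size=(n, n))
    d = np.triu(d, k=1)
    d = d + d.T
    AL = float(areas.sum() * rng.uniform(1.2, 3.0))
    return make_toy_graph(areas, d, AL)


def patch_from_cells(pid: int, cells, geometry: GridGeometry) -> Patch:
    """Patch from explicit (row, col) cells; every cell counts as boundary."""
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    return Patch(
        id=pid,
        rows=rows,
        cols=cols,
        area_km2=rows.size * geometry.cell_area_m2 * 1e-6,
        boundary_rows=rows,
        boundary_cols=cols,
    )
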