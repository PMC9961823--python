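"""Least-cost corridors between source patches and gravity-model ranking.

Cost distances are exact Dijkstra shortest paths on the 8-connected cell
graph: stepping from cell u to adjacent cell v costs
``cell_size * m * (R_u + R_v) / 2`` with ``m = 1`` for rook moves and
``sqrt(2)`` for diagonal moves. One corridor is traced per unordered
source pair, from the minimizing boundary-cell pair, by predecessor
backtracking.

Corridor importance comes from a gravity score

    G_ij = L_max^2 * ln(S_i) * ln(S_j) / (L_ij^2 * P_i * P_j)

with S the patch area in hectares (must exceed 1 ha so the logarithm is
positive), P the mean resistance over the patch's cells (configurable to
the sum), L_ij the corridor's cumulative cost and L_max the largest
corridor cost among all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .connectivity import Patch
from .resistance import ResistanceSurface

__all__ = [
    "CostDistanceMap",
    "Corridor",
    "GravityMatrix",
    "cost_distance",
    "least_cost_corridors",
    "gravity_matrix",
    "rank_corridors",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class CostDistanceMap:
    cost: np.ndarray  # accumulated cost per cell
    predecessor: np.ndarray  # flat index of the previous cell; -9999 at sources

    def backtrack(self, row: int, col: int) -> list[tuple[int, int]]:
        """Path from a source cell to ``(row, col)`` as (row, col) tuples."""
        n_cols = self.cost.shape[1]
        node = row * n_cols + col
        rev = []
        while node >= 0:
            rev.append((node // n_cols, node % n_cols))
            node = int(self.predecessor[node // n_cols, node % n_cols])
        return rev[::-1]


@dataclass(frozen=True)
class Corridor:
    i: int  # source patch id
    j: int
    path: tuple[tuple[int, int], ...]
    cost: float
    gravity: float | None = None
    rank: int | None = None
    important: bool = False


@dataclass(frozen=True)
class GravityMatrix:
    ids: tuple[int, ...]
    G: np.ndarray  # symmetric, zero diagonal
    S_ha: np.ndarray
    P: np.ndarray
    L: np.ndarray
    L_max: float


def _grid_graph(resistance: ResistanceSurface):
    """Sparse symmetric cost graph over the 8-connected cells."""
    r = resistance.values
    if not np.all(r > 0):
        raise ValueError("resistance must be positive everywhere")
    n_rows, n_cols = r.shape
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    cell = resistance.geometry.cell_size
    rows, cols, data = [], [], []
    # rightward, downward, and both diagonal neighbors; symmetry added once
    for dr, dc, m in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, _SQRT2), (1, -1, _SQRT2)):
        src_r = slice(0, n_rows - dr)
        src_c = slice(max(0, -dc), n_cols - max(0, dc))
        dst_r = slice(dr, n_rows)
        dst_c = slice(max(0, dc), n_cols - max(0, -dc))
        u = idx[src_r, src_c].ravel()
        v = idx[dst_r, dst_c].ravel()
        w = cell * m * 0.5 * (r[src_r, src_c].ravel() + r[dst_r, dst_c].ravel())
        rows.append(u)
        cols.append(v)
        data.append(w)
    u = np.concatenate(rows)
    v = np.concatenate(cols)
    w = np.concatenate(data)
    n = n_rows * n_cols
    return coo_matrix((np.concatenate([w, w]), (np.concatenate([u, v]), np.concatenate([v, u]))), shape=(n, n)).tocsr()


def cost_distance(
    resistance: ResistanceSurface,
    source_cells: list[tuple[int, int]] | np.ndarray,
) -> CostDistanceMap:
    """Minimum accumulated cost from the source cell set to every cell."""
    source_cells = np.atleast_2d(np.asarray(source_cells, dtype=int))
    if source_cells.size == 0:
        raise ValueError("source cell set is empty")
    graph = _grid_graph(resistance)
    shape = resistance.values.shape
    flat = source_cells[:, 0] * shape[1] + source_cells[:, 1]
    cost, pred, _ = dijkstra(graph, directed=False, indices=flat, min_only=True, return_predecessors=True)
    return CostDistanceMap(cost=cost.reshape(shape), predecessor=pred.reshape(shape))


def least_cost_corridors(resistance: ResistanceSurface, sources: list[Patch]) -> list[Corridor]:
    """One least-cost corridor per unordered pair of source patches."""
    if len(sources) < 2:
        raise ValueError("need at least two source patches")
    shape = resistance.values.shape
    corridors: list[Corridor] = []
    maps: dict[int, CostDistanceMap] = {}
    for a, patch_a in enumerate(sources[:-1]):
        cells = np.column_stack([patch_a.boundary_rows, patch_a.boundary_cols])
        cdm = cost_distance(resistance, cells)
        for patch_b in sources[a + 1 :]:
            costs_b = cdm.cost[patch_b.boundary_rows, patch_b.boundary_cols]
            k = int(np.argmin(costs_b))
            end = (int(patch_b.boundary_rows[k]), int(patch_b.boundary_cols[k]))
            path = cdm.backtrack(*end)
            corridors.append(
                Corridor(i=patch_a.id, j=patch_b.id, path=tuple(path), cost=float(costs_b[k]))
            )
    return corridors


def gravity_matrix(
    sources: list[Patch],
    corridors: list[Corridor],
    resistance: ResistanceSurface,
    patch_resistance: str = "mean",
) -> GravityMatrix:
    """Pairwise interaction strengths from corridor costs and patch masses."""
    ids = tuple(p.id for p in sources)
    pos = {pid: k for k, pid in enumerate(ids)}
    n = len(sources)
    S = np.array([p.n_cells * resistance.geometry.cell_area_m2 * 1e-4 for p in sources])
    if np.any(S <= 1.0):
        bad = [ids[k] for k in np.nonzero(S <= 1.0)[0]]
        raise ValueError(
            f"patch area must exceed 1 ha for ln(S) to be positive; offending patches: {bad} "
            "(use a larger cell size or merge patches)"
        )
    if patch_resistance == "mean":
        P = np.array([resistance.values[p.rows, p.cols].mean() for p in sources])
    elif patch_resistance == "sum":
        P = np.array([resistance.values[p.rows, p.cols].sum() for p in sources])
    else:
        raise ValueError(f"patch_resistance must be 'mean' or 'sum', got {patch_resistance!r}")

    L = np.zeros((n, n))
    for c in corridors:
        a, b = pos[c.i], pos[c.j]
        if c.cost <= 0:
            raise ValueError(f"corridor ({c.i}, {c.j}) has non-positive cost; sources overlap")
        L[a, b] = L[b, a] = c.cost
    L_max = float(L.max())
    G = np.zeros((n, n))
    lnS = np.log(S)
    for a in range(n):
        for b in range(a + 1, n):
            if L[a, b] > 0:
                G[a, b] = G[b, a] = (L_max**2 * lnS[a] * lnS[b]) / (L[a, b] ** 2 * P[a] * P[b])
    return GravityMatrix(ids=ids, G=G, S_ha=S, P=P, L=L, L_max=L_max)


def rank_corridors(
    gravity: GravityMatrix, corridors: list[Corridor], top_k: int = 15
) -> list[Corridor]:
    """Sort corridors by gravity score and flag the ``top_k`` as important.

    Ties break toward the smaller cumulative cost, then (i, j) id order.
    """
    pos = {pid: k for k, pid in enumerate(gravity.ids)}
    keyed = sorted(
        corridors,
        key=lambda c: (-gravity.G[pos[c.i], pos[c.j]], c.cost, c.i, c.j),
    )
    out = []
    for rank, c in enumerate(keyed, start=1):
        out.append(
            replace(
                c,
                gravity=float(gravity.G[pos[c.i], pos[c.j]]),
                rank=rank,
                important=rank <= top_k,
            )
        )
    return out
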