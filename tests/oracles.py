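"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive — exhaustive path enumeration and a
textbook heap Dijkstra — and shares no code with the package under test.
"""

from __future__ import annotations

import heapq
import math

import numpy as np


def _all_simple_paths(adj: np.ndarray, i: int, j: int):
    """Yield every simple path from i to j as a list of node indices."""
    n = adj.shape[0]

    def extend(path, seen):
        last = path[-1]
        if last == j:
            yield list(path)
            return
        for nxt in range(n):
            if adj[last, nxt] and nxt not in seen:
                yield from extend(path + [nxt], seen | {nxt})

    yield from extend([i], {i})


def brute_iic(areas, adj, AL) -> float:
    """IIC by exhaustive simple-path enumeration (min link count per pair)."""
    n = len(areas)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                total += areas[i] * areas[j]
                continue
            hops = [len(p) - 1 for p in _all_simple_paths(adj, i, j)]
            if hops:
                total += areas[i] * areas[j] / (1 + min(hops))
    return total / AL**2


def brute_pc(areas, adj, p_direct, AL) -> float:
    """PC by exhaustive enumeration of max-product path probabilities."""
    n = len(areas)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                total += areas[i] * areas[j]
                continue
            best = 0.0
            for path in _all_simple_paths(adj, i, j):
                prod = 1.0
                for a, b in zip(path[:-1], path[1:]):
                    prod *= p_direct[a, b]
                best = max(best, prod)
            total += areas[i] * areas[j] * best
    return total / AL**2


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Freeman betweenness over unordered pairs, normalized by (N-1)(N-2)/2."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for j in range(n):
        for k in range(j + 1, n):
            paths = list(_all_simple_paths(adj, j, k))
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            geodesics = [p for p in paths if len(p) == shortest]
            for i in range(n):
                if i in (j, k):
                    continue
                through = sum(1 for p in geodesics if i in p)
                bc[i] += through / len(geodesics)
    return bc / ((n - 1) * (n - 2) / 2)


def brute_cost_distance(resistance: np.ndarray, cell_size: float, sources) -> np.ndarray:
    """Textbook heap Dijkstra over the 8-connected cell graph."""
    n_rows, n_cols = resistance.shape
    dist = np.full((n_rows, n_cols), math.inf)
    heap = []
    for r, c in sources:
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                    continue
                m = math.sqrt(2.0) if dr and dc else 1.0
                step = cell_size * m * 0.5 * (resistance[r, c] + resistance[rr, cc])
                nd = d + step
                if nd < dist[rr, cc]:
                    dist[rr, cc] = nd
                    heapq.heappush(heap, (nd, rr, cc))
    return dist


def brute_core_mask(mask: np.ndarray, width: int) -> np.ndarray:
    """Per-cell chessboard-neighborhood check: core iff the full
    (2w+1)^2 window lies inside the raster and contains only foreground."""
    n_rows, n_cols = mask.shape
    core = np.zeros_like(mask)
    for r in range(n_rows):
        for c in range(n_cols):
            if not mask[r, c]:
                continue
            ok = True
            for dr in range(-width, width + 1):
                for dc in range(-width, width + 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < n_rows and 0 <= cc < n_cols) or not mask[rr, cc]:
                        ok = False
                        break
                if not ok:
                    break
            core[r, c] = ok
    return core
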