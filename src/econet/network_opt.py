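"""Stepping-stone selection and network quality indices.

Betweenness centrality is computed on the thresholded, unweighted patch
link graph (the same graph the connectivity indices use) and normalized by
the number of unordered node pairs excluding the focal node,
``(N - 1)(N - 2) / 2``, so the middle node of a 3-node path scores 1.
The highest-scoring non-source patches become stepping stones; corridors
are then rebuilt over sources plus stones, and the network is scored with
the planar-graph form indices

    alpha = (L - V + 1) / (2V - 5)   (closure: independent cycles)
    beta  = L / V                    (links per node)
    gamma = L / (3 (V - 2))          (realized / maximal links)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .connectivity import Patch, PatchGraph
from .corridors import Corridor, gravity_matrix, least_cost_corridors, rank_corridors
from .resistance import ResistanceSurface

__all__ = [
    "BetweennessReport",
    "NetworkQuality",
    "betweenness",
    "select_stepping_stones",
    "planned_network",
    "network_quality",
]


@dataclass(frozen=True)
class BetweennessReport:
    table: pd.DataFrame  # patch_id, bc, area_km2; sorted by bc descending


@dataclass(frozen=True)
class NetworkQuality:
    V: int
    L: int
    alpha: float
    beta: float
    gamma: float


def betweenness(graph: PatchGraph) -> BetweennessReport:
    """Normalized shortest-path betweenness of every patch in the link graph."""
    if graph.n < 3:
        raise ValueError("betweenness normalization needs at least 3 nodes")
    g = nx.Graph()
    g.add_nodes_from(p.id for p in graph.patches)
    ids = [p.id for p in graph.patches]
    for a in range(graph.n):
        for b in range(a + 1, graph.n):
            if graph.adjacency[a, b]:
                g.add_edge(ids[a], ids[b])
    bc = nx.betweenness_centrality(g, normalized=True)
    table = (
        pd.DataFrame(
            {
                "patch_id": ids,
                "bc": [bc[i] for i in ids],
                "area_km2": [p.area_km2 for p in graph.patches],
            }
        )
        .sort_values(by=["bc", "area_km2", "patch_id"], ascending=[False, False, True], kind="stable")
        .reset_index(drop=True)
    )
    return BetweennessReport(table=table)


def select_stepping_stones(
    report: BetweennessReport, sources: list[int], top_n: int = 10
) -> list[int]:
    """Top non-source patches by betweenness (ties: larger area, smaller id)."""
    if top_n == 0:
        return []
    pool = report.table[~report.table["patch_id"].isin(sources)]
    if len(pool) < top_n:
        warnings.warn(
            f"only {len(pool)} non-source patches available for top_n={top_n}; returning all",
            stacklevel=2,
        )
    return [int(i) for i in pool["patch_id"].head(top_n)]


def planned_network(
    resistance: ResistanceSurface,
    sources: list[Patch],
    stones: list[Patch],
    top_k_important: int = 8,
) -> list[Corridor]:
    """All-pairs least-cost corridors over sources plus stepping stones."""
    source_ids = {p.id for p in sources}
    stone_ids = {p.id for p in stones}
    if source_ids & stone_ids:
        raise ValueError(f"sources and stones overlap: {sorted(source_ids & stone_ids)}")
    nodes = list(sources) + list(stones)
    corridors = least_cost_corridors(resistance, nodes)
    gravity = gravity_matrix(nodes, corridors, resistance)
    return rank_corridors(gravity, corridors, top_k=top_k_important)


def network_quality(V: int, L: int) -> NetworkQuality:
    """Closure (alpha), links-per-node (beta) and connectivity-rate (gamma)."""
    if V < 3:
        raise ValueError("network quality indices need at least 3 nodes")
    return NetworkQuality(
        V=V,
        L=L,
        alpha=(L - V + 1) / (2 * V - 5),
        beta=L / V,
        gamma=L / (3 * (V - 2)),
    )
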