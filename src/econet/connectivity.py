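"""Habitat patch graph and graph-theoretic connectivity indices.

Core patches extracted from a morphological class map become nodes of a
graph whose links join patches closer (edge-to-edge, meters) than a
distance threshold. On that graph:

* ``iic`` — integral index of connectivity: area products discounted by
  the number of links on the shortest topological path.
* ``pc`` — probability of connectivity: area products weighted by the
  maximum product of direct link probabilities over any path, with direct
  probabilities from a negative-exponential kernel calibrated so that the
  probability at the threshold distance equals ``p_threshold``.
* ``delta_importance`` — percentage drop of either index when one patch
  (with all its links) is removed; the standard patch-importance measure.

Patches ranked by dPC supply the ecological source set for the corridor
stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import cKDTree

from .geometry import GridGeometry
from .mspa import MSPA_CODES, MSPAMap

__all__ = [
    "Patch",
    "PatchGraph",
    "ConnectivityReport",
    "extract_patches",
    "patch_distances",
    "build_patch_graph",
    "iic",
    "pc",
    "delta_importance",
    "connectivity_report",
    "select_sources",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Patch:
    """One 8-connected component of the source class."""

    id: int
    rows: np.ndarray
    cols: np.ndarray
    area_km2: float
    boundary_rows: np.ndarray
    boundary_cols: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.rows.size


@dataclass(frozen=True)
class PatchGraph:
    """Patches plus pairwise distances, links and direct link probabilities."""

    patches: tuple[Patch, ...]
    AL_km2: float
    dist_m: np.ndarray  # symmetric, zero diagonal
    threshold_m: float
    p_threshold: float
    adjacency: np.ndarray = field(init=False)  # bool, no self-links
    p_direct: np.ndarray = field(init=False)  # exp(-k d) on links, 0 elsewhere

    def __post_init__(self) -> None:
        n = len(self.patches)
        d = np.asarray(self.dist_m, dtype=float)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match patch count")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        total = sum(p.area_km2 for p in self.patches)
        if self.AL_km2 + 1e-9 < total:
            raise ValueError("landscape area AL is smaller than the summed patch areas")
        adj = (d <= self.threshold_m) & ~np.eye(n, dtype=bool)
        k = -np.log(self.p_threshold) / self.threshold_m
        p = np.where(adj, np.exp(-k * d), 0.0)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "p_direct", p)

    @property
    def n(self) -> int:
        return len(self.patches)

    @property
    def areas_km2(self) -> np.ndarray:
        return np.array([p.area_km2 for p in self.patches], dtype=float)

    def drop_patch(self, index: int) -> "PatchGraph":
        """Graph with one patch (and its links) removed; AL unchanged."""
        keep = [i for i in range(self.n) if i != index]
        return PatchGraph(
            patches=tuple(self.patches[i] for i in keep),
            AL_km2=self.AL_km2,
            dist_m=self.dist_m[np.ix_(keep, keep)],
            threshold_m=self.threshold_m,
            p_threshold=self.p_threshold,
        )

    def edge_table(self) -> pd.DataFrame:
        """Link list (i, j, dist_m, p_ij) over the thresholded pairs."""
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.adjacency[i, j]:
                    rows.append(
                        {
                            "i": self.patches[i].id,
                            "j": self.patches[j].id,
                            "dist_m": self.dist_m[i, j],
                            "p_ij": self.p_direct[i, j],
                        }
                    )
        return pd.DataFrame(rows, columns=["i", "j", "dist_m", "p_ij"])


@dataclass(frozen=True)
class ConnectivityReport:
    table: pd.DataFrame  # per patch: id, area_km2, dIIC, dPC
    iic: float
    pc: float
    sources: tuple[int, ...]  # patch ids, ranked


def extract_patches(mspa_map: MSPAMap, source_class: str = "core") -> list[Patch]:
    """One patch per 8-connected component of the chosen morphological class."""
    mask = mspa_map.label == MSPA_CODES[source_class]
    labels, n = ndimage.label(mask, structure=_SQUARE3)
    cell_km2 = mspa_map.geometry.cell_area_m2 * 1e-6
    interior = ndimage.binary_erosion(labels > 0, structure=_SQUARE3, border_value=0)
    patches = []
    for pid in range(1, n + 1):
        comp = labels == pid
        rows, cols = np.nonzero(comp)
        brows, bcols = np.nonzero(comp & ~interior)
        patches.append(
            Patch(
                id=pid,
                rows=rows,
                cols=cols,
                area_km2=rows.size * cell_km2,
                boundary_rows=brows,
                boundary_cols=bcols,
            )
        )
    return patches


def patch_distances(
    patches: list[Patch], geometry: GridGeometry, mode: str = "edge"
) -> np.ndarray:
    """Pairwise minimum edge-to-edge (or centroid) distance in meters."""
    n = len(patches)
    if n == 0:
        raise ValueError("need at least one patch")
    d = np.zeros((n, n), dtype=float)
    if mode == "centroid":
        cents = np.array(
            [geometry.cell_centers(p.rows, p.cols).mean(axis=0) for p in patches]
        )
        diff = cents[:, np.newaxis, :] - cents[np.newaxis, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])
    if mode != "edge":
        raise ValueError(f"unknown distance mode: {mode!r}")
    pts = [geometry.cell_centers(p.boundary_rows, p.boundary_cols) for p in patches]
    trees = [cKDTree(p) for p in pts]
    for i in range(n):
        for j in range(i + 1, n):
            if pts[i].shape[0] <= pts[j].shape[0]:
                dist = trees[j].query(pts[i])[0].min()
            else:
                dist = trees[i].query(pts[j])[0].min()
            d[i, j] = d[j, i] = dist
    return d


def build_patch_graph(
    patches: list[Patch],
    geometry: GridGeometry,
    threshold_m: float = 5000.0,
    p_threshold: float = 0.5,
    distance_mode: str = "edge",
) -> PatchGraph:
    dist = patch_distances(patches, geometry, mode=distance_mode)
    return PatchGraph(
        patches=tuple(patches),
        AL_km2=geometry.area_km2,
        dist_m=dist,
        threshold_m=threshold_m,
        p_threshold=p_threshold,
    )


def _topological_links(graph: PatchGraph) -> np.ndarray:
    """nl_ij: link count on the shortest topological path; inf if unreachable."""
    adj = csr_matrix(graph.adjacency.astype(float))
    return shortest_path(adj, method="D", unweighted=True, directed=False)


def _max_product_probability(graph: PatchGraph) -> np.ndarray:
    """p*_ij: maximum product of direct probabilities over any path."""
    n = graph.n
    ii, jj = np.nonzero(graph.adjacency)
    weights = -np.log(graph.p_direct[ii, jj])
    mat = csr_matrix((weights, (ii, jj)), shape=(n, n))
    cost = shortest_path(mat, method="D", directed=False)
    p_star = np.exp(-cost)
    p_star[~np.isfinite(cost)] = 0.0
    np.fill_diagonal(p_star, 1.0)
    return p_star


def iic(graph: PatchGraph) -> float:
    """Integral index of connectivity in [0, 1]; self-pairs included."""
    if graph.n == 0:
        return 0.0
    a = graph.areas_km2
    nl = _topological_links(graph)
    np.fill_diagonal(nl, 0.0)
    with np.errstate(invalid="ignore"):
        contrib = np.outer(a, a) / (1.0 + nl)
    contrib[~np.isfinite(nl)] = 0.0
    return float(contrib.sum() / graph.AL_km2**2)


def pc(graph: PatchGraph) -> float:
    """Probability of connectivity in [0, 1]; self-pairs included (p*_ii = 1)."""
    if graph.n == 0:
        return 0.0
    a = graph.areas_km2
    p_star = _max_product_probability(graph)
    return float((np.outer(a, a) * p_star).sum() / graph.AL_km2**2)


def delta_importance(graph: PatchGraph, metric: str = "PC") -> np.ndarray:
    """Per-patch importance d_i = 100 (M - M_remove(i)) / M, in percent."""
    fn = {"IIC": iic, "PC": pc}.get(metric.upper())
    if fn is None:
        raise ValueError(f"metric must be 'IIC' or 'PC', got {metric!r}")
    m_full = fn(graph)
    if m_full <= 0:
        raise ValueError(f"global {metric} is zero; patch importance is undefined")
    out = np.empty(graph.n, dtype=float)
    for i in range(graph.n):
        out[i] = 100.0 * (m_full - fn(graph.drop_patch(i))) / m_full
    return out


def connectivity_report(graph: PatchGraph, top_n: int = 10) -> ConnectivityReport:
    """dIIC/dPC table ranked by dPC plus the selected source patches."""
    d_iic = delta_importance(graph, "IIC")
    d_pc = delta_importance(graph, "PC")
    table = pd.DataFrame(
        {
            "patch_id": [p.id for p in graph.patches],
            "area_km2": graph.areas_km2,
            "dIIC": d_iic,
            "dPC": d_pc,
        }
    ).sort_values(by=["dPC", "area_km2", "patch_id"], ascending=[False, False, True], kind="stable")
    table = table.reset_index(drop=True)
    report = ConnectivityReport(
        table=table,
        iic=iic(graph),
        pc=pc(graph),
        sources=tuple(int(i) for i in table["patch_id"].head(top_n)),
    )
    return report


def select_sources(report: ConnectivityReport, top_n: int = 10) -> list[int]:
    """Top patches by dPC (ties: larger area, then smaller id); patch ids."""
    table = report.table
    if len(table) < top_n:
        warnings.warn(
            f"only {len(table)} patches available for top_n={top_n}; returning all",
            stacklevel=2,
        )
    ranked = table.sort_values(
        by=["dPC", "area_km2", "patch_id"], ascending=[False, False, True], kind="stable"
    )
    return [int(i) for i in ranked["patch_id"].head(top_n)]
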