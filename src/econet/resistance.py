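"""Movement-resistance surface: factor reclassification, weights, overlay.

Six factors (elevation, aspect, land-use type, vegetation cover, distance
from main roads, distance from branch roads) are each reclassified to an
ordinal 1–5 resistance score and combined by a weighted sum, so the
resulting surface always lies in [1, 5].

Weights can be supplied directly (the shipped defaults) or derived from a
principal-component analysis of sampled factor scores: standardized
factors are eigendecomposed via their correlation matrix, per-component
linear-combination coefficients are the loadings divided by the square
root of the component's characteristic root (eigenvalue), a composite
coefficient per factor is the variance-share-weighted mean over the
retained components, and weights are the composites normalized to sum
to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import GridGeometry
from .synthetic_landscape import ASPECT_CODES, LAND_CODES

__all__ = [
    "ReclassRule",
    "WeightVector",
    "PCAWeightReport",
    "ResistanceSurface",
    "DEFAULT_RULES",
    "DEFAULT_WEIGHTS",
    "distance_to_roads",
    "reclassify",
    "linear_combination_coefficient",
    "pca_weights",
    "weighted_sum",
]


@dataclass(frozen=True)
class ReclassRule:
    """Reclassification of one factor to scores in {1..5}.

    Continuous rules list ascending break edges (len = len(scores) + 1,
    typically opening with -inf and closing with +inf); membership is
    left-closed/right-open. Categorical rules map category code -> score.
    Infinite factor values (e.g. road distance with no roads) take
    ``score_for_infinity``.
    """

    factor: str
    kind: str  # "continuous" | "categorical"
    edges: tuple[float, ...] | None = None
    scores: tuple[int, ...] | None = None
    mapping: Mapping[int, int] | None = None
    score_for_infinity: int = 1

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if self.edges is None or self.scores is None:
                raise ValueError(f"{self.factor}: continuous rule needs edges and scores")
            if len(self.edges) != len(self.scores) + 1:
                raise ValueError(f"{self.factor}: need len(edges) == len(scores) + 1")
            if list(self.edges) != sorted(self.edges):
                raise ValueError(f"{self.factor}: edges must be ascending")
            vals = self.scores
        elif self.kind == "categorical":
            if self.mapping is None:
                raise ValueError(f"{self.factor}: categorical rule needs a mapping")
            vals = tuple(self.mapping.values())
        else:
            raise ValueError(f"{self.factor}: unknown rule kind {self.kind!r}")
        if any(not 1 <= s <= 5 for s in vals):
            raise ValueError(f"{self.factor}: scores must lie in 1..5")


@dataclass(frozen=True)
class WeightVector:
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class PCAWeightReport:
    factors: tuple[str, ...]
    loadings: np.ndarray  # (n_factors, n_components)
    roots: np.ndarray  # characteristic roots (eigenvalues), descending
    coefficients: np.ndarray  # loadings / sqrt(roots)
    variance_share_pct: np.ndarray
    composite: np.ndarray  # per factor
    weights: WeightVector

    def to_frame(self) -> pd.DataFrame:
        cols = {f"loading_pc{k + 1}": self.loadings[:, k] for k in range(self.loadings.shape[1])}
        cols |= {f"coef_pc{k + 1}": self.coefficients[:, k] for k in range(self.loadings.shape[1])}
        cols["composite"] = self.composite
        cols["weight"] = [self.weights.weights[f] for f in self.factors]
        return pd.DataFrame(cols, index=list(self.factors))


@dataclass(frozen=True)
class ResistanceSurface:
    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.geometry.validate_layer(self.values, "resistance")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("resistance must be finite everywhere")
        if self.values.min() < 1.0 - 1e-9 or self.values.max() > 5.0 + 1e-9:
            raise ValueError("resistance must lie within [1, 5]")


# Default reclassification: scores as printed in the source ruleset, with
# monotone extensions for uncovered ranges (distances past the farthest
# break and elevations below the lowest break score 1; bare land, absent
# from the land-use rule, scores 5 alongside ice and snow).
DEFAULT_RULES: dict[str, ReclassRule] = {
    "elevation": ReclassRule(
        factor="elevation",
        kind="continuous",
        edges=(-np.inf, 3500.0, 4000.0, 4500.0, 5000.0, np.inf),
        scores=(1, 2, 3, 4, 5),
    ),
    "aspect": ReclassRule(
        factor="aspect",
        kind="categorical",
        mapping={
            ASPECT_CODES["S"]: 1,
            ASPECT_CODES["SW"]: 2,
            ASPECT_CODES["SE"]: 2,
            ASPECT_CODES["E"]: 3,
            ASPECT_CODES["W"]: 3,
            ASPECT_CODES["NW"]: 4,
            ASPECT_CODES["NE"]: 4,
            ASPECT_CODES["N"]: 5,
            ASPECT_CODES["flat"]: 1,
        },
    ),
    "landuse": ReclassRule(
        factor="landuse",
        kind="categorical",
        mapping={
            LAND_CODES["cultivated land"]: 1,
            LAND_CODES["shrub"]: 1,
            LAND_CODES["grassland"]: 1,
            LAND_CODES["forest land"]: 1,
            LAND_CODES["water area"]: 2,
            LAND_CODES["wetland"]: 3,
            LAND_CODES["construction land"]: 4,
            LAND_CODES["ice and snow"]: 5,
            LAND_CODES["bare land"]: 5,
        },
    ),
    "vegcover": ReclassRule(
        factor="vegcover",
        kind="continuous",
        edges=(-np.inf, 0.2, 0.4, 0.6, 0.8, np.inf),
        scores=(5, 4, 3, 2, 1),
    ),
    "road_main": ReclassRule(
        factor="road_main",
        kind="continuous",
        edges=(-np.inf, 400.0, 700.0, 1000.0, 1300.0, np.inf),
        scores=(5, 4, 3, 2, 1),
        score_for_infinity=1,
    ),
    "road_branch": ReclassRule(
        factor="road_branch",
        kind="continuous",
        edges=(-np.inf, 100.0, 200.0, 300.0, 400.0, np.inf),
        scores=(5, 4, 3, 2, 1),
        score_for_infinity=1,
    ),
}

#: Default factor weights (sum to 1).
DEFAULT_WEIGHTS = WeightVector(
    weights={
        "elevation": 0.16,
        "aspect": 0.08,
        "landuse": 0.06,
        "vegcover": 0.21,
        "road_main": 0.26,
        "road_branch": 0.23,
    }
)


def distance_to_roads(road: np.ndarray, geometry: GridGeometry) -> np.ndarray:
    """Euclidean distance (m) from each cell center to the nearest road cell.

    Road cells map to 0. With no road cells at all, every distance is
    infinite (the reclassification rules then score the factor 1).
    """
    geometry.validate_layer(road, "road")
    road = road.astype(bool)
    if not road.any():
        return np.full(geometry.shape, np.inf)
    return ndimage.distance_transform_edt(~road, sampling=geometry.cell_size)


def reclassify(values: np.ndarray, rule: ReclassRule) -> np.ndarray:
    """Apply a reclassification rule, returning an integer score raster."""
    values = np.asarray(values)
    if rule.kind == "continuous":
        finite = np.isfinite(values)
        idx = np.digitize(values, rule.edges[1:-1], right=False)
        out = np.asarray(rule.scores, dtype=np.int16)[np.clip(idx, 0, len(rule.scores) - 1)]
        out = np.where(finite, out, rule.score_for_infinity).astype(np.int16)
        return out
    codes = np.unique(values)
    unknown = [int(c) for c in codes if int(c) not in rule.mapping]
    if unknown:
        raise ValueError(f"{rule.factor}: values {unknown} not covered by the rule")
    lut_size = max(rule.mapping) + 1
    lut = np.ones(lut_size, dtype=np.int16)
    for code, score in rule.mapping.items():
        lut[code] = score
    return lut[values.astype(int)]


def linear_combination_coefficient(loading: float | np.ndarray, root: float | np.ndarray) -> float | np.ndarray:
    """Per-component coefficient: loading divided by sqrt(characteristic root)."""
    return loading / np.sqrt(root)


def pca_weights(
    score_rasters: Mapping[str, np.ndarray],
    sample_size: int = 2000,
    seed: int = 0,
    n_components: int = 2,
) -> PCAWeightReport:
    """Derive factor weights from a PCA of sampled factor scores."""
    factors = tuple(score_rasters)
    if len(factors) < 2:
        raise ValueError("need at least two factors")
    flat = np.column_stack([np.asarray(score_rasters[f], dtype=float).ravel() for f in factors])
    n_cells = flat.shape[0]
    if sample_size < len(factors):
        raise ValueError("sample_size must be at least the number of factors")
    rng = np.random.default_rng(seed)
    take = min(sample_size, n_cells)
    sample = flat[rng.choice(n_cells, size=take, replace=False)]
    sd = sample.std(axis=0, ddof=1)
    degenerate = [f for f, s in zip(factors, sd) if s == 0]
    if degenerate:
        raise ValueError(f"constant factor(s) {degenerate}: correlation matrix is degenerate")

    corr = np.corrcoef(sample, rowvar=False)
    roots, vecs = np.linalg.eigh(corr)
    order = np.argsort(roots)[::-1][:n_components]
    roots = roots[order]
    vecs = vecs[:, order]
    # orient each component so its loading sum is non-negative (sign is arbitrary)
    signs = np.where(vecs.sum(axis=0) < 0, -1.0, 1.0)
    vecs = vecs * signs

    loadings = vecs * np.sqrt(roots)
    coefficients = linear_combination_coefficient(loadings, roots)
    variance_share = 100.0 * roots / len(factors)
    composite = (coefficients * variance_share).sum(axis=1) / variance_share.sum()
    # component orientation is arbitrary, so importance is the magnitude of
    # the composite coefficient; normalizing |composite| keeps weights valid
    # (non-negative, summing to 1) even for weakly correlated factors
    weights = np.abs(composite) / np.abs(composite).sum()
    return PCAWeightReport(
        factors=factors,
        loadings=loadings,
        roots=roots,
        coefficients=coefficients,
        variance_share_pct=variance_share,
        composite=composite,
        weights=WeightVector(weights=dict(zip(factors, weights))),
    )


def weighted_sum(
    score_rasters: Mapping[str, np.ndarray],
    weights: WeightVector,
    geometry: GridGeometry,
) -> ResistanceSurface:
    """Comprehensive weighted index sum of the factor scores."""
    if set(score_rasters) != set(weights.weights):
        missing = set(weights.weights) ^ set(score_rasters)
        raise ValueError(f"factors and weights disagree on: {sorted(missing)}")
    out = np.zeros(geometry.shape, dtype=float)
    for name, arr in score_rasters.items():
        geometry.validate_layer(np.asarray(arr), name)
        out += weights.weights[name] * np.asarray(arr, dtype=float)
    return ResistanceSurface(geometry=geometry, values=out)
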