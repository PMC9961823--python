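"""Seeded synthetic raster landscapes for end-to-end testing of the pipeline.

Generates a grassland-dominated categorical land-use raster (nine classes),
a smooth elevation field, a vegetation-cover field positively correlated
with grassland presence, and sparse connected road networks — all on a
shared :class:`~econet.geometry.GridGeometry` and fully determined by one
integer seed.

The land-use layer is produced by thresholding a smoothed Gaussian white
noise field at the quantile that yields the requested grassland share;
blob "nuclei" and an optional east–west smoothness gradient shape the patch
structure (large contiguous patches in the east, fragmented patches in the
west). Background cells are assigned to the remaining eight classes by
rank-slicing a second smoothed field at fixed class proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line

from .geometry import GridGeometry

__all__ = [
    "LAND_CLASSES",
    "LAND_CODES",
    "ASPECT_CLASSES",
    "ASPECT_CODES",
    "LandscapeStack",
    "SimulationConfig",
    "SizingError",
    "simulate_landscape",
    "aspect_from_dem",
]

#: The nine land-use classes, coded 1..9 in the categorical raster.
LAND_CLASSES = (
    "grassland",
    "construction land",
    "cultivated land",
    "shrub",
    "wetland",
    "forest land",
    "ice and snow",
    "water area",
    "bare land",
)
LAND_CODES = {name: code for code, name in enumerate(LAND_CLASSES, start=1)}

#: Fixed class proportions used to fill the non-grassland background.
_BACKGROUND_PROPORTIONS = (
    ("bare land", 0.40),
    ("wetland", 0.15),
    ("water area", 0.12),
    ("forest land", 0.10),
    ("shrub", 0.08),
    ("cultivated land", 0.06),
    ("ice and snow", 0.05),
    ("construction land", 0.04),
)

#: Aspect classes, coded 0..8. ``flat`` marks zero-gradient cells.
ASPECT_CLASSES = ("flat", "N", "NE", "E", "SE", "S", "SW", "W", "NW")
ASPECT_CODES = {name: code for code, name in enumerate(ASPECT_CLASSES)}


class SizingError(ValueError):
    """Raised when the grid is too small to host the requested structure."""


@dataclass(frozen=True)
class LandscapeStack:
    """Aligned single-band raster layers sharing one grid geometry."""

    geometry: GridGeometry
    landuse: np.ndarray  # int codes 1..9, see LAND_CODES
    dem: np.ndarray  # elevation, m
    vegcover: np.ndarray  # fractional cover in [0, 1]
    road_main: np.ndarray  # bool
    road_branch: np.ndarray  # bool

    def __post_init__(self) -> None:
        for name in ("landuse", "dem", "vegcover", "road_main", "road_branch"):
            self.geometry.validate_layer(getattr(self, name), name)
        codes = np.unique(self.landuse)
        if codes.size and (codes.min() < 1 or codes.max() > len(LAND_CLASSES)):
            raise ValueError("landuse contains codes outside the 9 declared classes")
        if self.vegcover.min() < 0 or self.vegcover.max() > 1:
            raise ValueError("vegcover must lie within [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    geometry: GridGeometry = field(default_factory=lambda: GridGeometry(200, 200, 30.0))
    foreground_fraction: float = 0.80
    n_blobs: int = 40
    fragmentation: float = 0.6  # blur scale in cells; larger = smoother
    east_west_gradient: bool = True
    n_roads_main: int = 2
    n_roads_branch: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.foreground_fraction < 1.0:
            raise ValueError("foreground_fraction must lie in (0, 1)")
        if self.n_blobs < 1:
            raise ValueError("n_blobs must be >= 1")
        if self.fragmentation <= 0:
            raise ValueError("fragmentation must be positive")


def _standardize(arr: np.ndarray) -> np.ndarray:
    sd = arr.std()
    return (arr - arr.mean()) / sd if sd > 0 else np.zeros_like(arr)


def _blob_field(rng: np.random.Generator, geometry: GridGeometry, n_blobs: int) -> np.ndarray:
    """Sum of Gaussian bumps at random nuclei, peak-normalized to 1."""
    rows = rng.uniform(0, geometry.n_rows, size=n_blobs)
    cols = rng.uniform(0, geometry.n_cols, size=n_blobs)
    sigma = max(2.0, 0.35 * min(geometry.n_rows, geometry.n_cols) / np.sqrt(n_blobs))
    rr, cc = np.mgrid[0 : geometry.n_rows, 0 : geometry.n_cols]
    out = np.zeros(geometry.shape, dtype=float)
    for r0, c0 in zip(rows, cols):
        out += np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    return out / out.max()


def _draw_polyline_road(
    rng: np.random.Generator,
    shape: tuple[int, int],
    horizontal: bool,
    n_waypoints: int = 4,
) -> np.ndarray:
    """Rasterize a jittered polyline crossing the grid; 8-connected by construction."""
    n_rows, n_cols = shape
    mask = np.zeros(shape, dtype=bool)
    if horizontal:
        cols = np.linspace(0, n_cols - 1, n_waypoints + 2)
        rows = rng.uniform(0.15 * n_rows, 0.85 * n_rows, size=n_waypoints + 2)
    else:
        rows = np.linspace(0, n_rows - 1, n_waypoints + 2)
        cols = rng.uniform(0.15 * n_cols, 0.85 * n_cols, size=n_waypoints + 2)
    rows = np.clip(np.round(rows).astype(int), 0, n_rows - 1)
    cols = np.clip(np.round(cols).astype(int), 0, n_cols - 1)
    for k in range(len(rows) - 1):
        rr, cc = _draw_line(rows[k], cols[k], rows[k + 1], cols[k + 1])
        mask[rr, cc] = True
    return mask


def simulate_landscape(config: SimulationConfig) -> LandscapeStack:
    """Generate a full layer stack from a seeded configuration.

    The grassland share of the output is within a few percentage points of
    ``config.foreground_fraction`` (quantile thresholding is exact up to
    ties). With ``east_west_gradient`` the eastern half holds larger, more
    contiguous grassland patches than the western half.
    """
    geom = config.geometry
    n_fg_target = config.foreground_fraction * geom.n_cells
    if 9 * config.n_blobs > n_fg_target:
        raise SizingError(
            f"grid of {geom.n_cells} cells cannot host {config.n_blobs} blobs "
            f"at foreground fraction {config.foreground_fraction}"
        )
    rng = np.random.default_rng(config.seed)

    rough = _standardize(ndimage.gaussian_filter(rng.standard_normal(geom.shape), max(0.5, 0.5 * config.fragmentation)))
    smooth = _standardize(ndimage.gaussian_filter(rng.standard_normal(geom.shape), 3.0 * config.fragmentation))
    # bumps must dominate the noise when the field is smooth so few nuclei
    # yield few connected blobs
    amplitude = 1.5 + config.fragmentation
    if config.east_west_gradient:
        w = np.linspace(0.0, 1.0, geom.n_cols)[np.newaxis, :]  # 0 = west, 1 = east
        noise = _standardize((1.0 - w) * rough + w * smooth) + 0.8 * w
    else:
        noise = _standardize(ndimage.gaussian_filter(rng.standard_normal(geom.shape), config.fragmentation))
    field_total = noise + amplitude * _blob_field(rng, geom, config.n_blobs)

    thr = np.quantile(field_total, 1.0 - config.foreground_fraction)
    grass = field_total >= thr

    landuse = np.empty(geom.shape, dtype=np.int16)
    landuse[grass] = LAND_CODES["grassland"]
    bg_field = ndimage.gaussian_filter(rng.standard_normal(geom.shape), max(1.0, config.fragmentation))
    bg_idx = np.where(~grass)
    if bg_idx[0].size:
        vals = bg_field[bg_idx]
        order = np.argsort(vals, kind="stable")
        cum = 0.0
        start = 0
        for name, prop in _BACKGROUND_PROPORTIONS:
            cum += prop
            stop = int(round(cum * vals.size))
            sel = order[start:stop]
            landuse[bg_idx[0][sel], bg_idx[1][sel]] = LAND_CODES[name]
            start = stop
        if start < vals.size:  # rounding remainder
            sel = order[start:]
            landuse[bg_idx[0][sel], bg_idx[1][sel]] = LAND_CODES[_BACKGROUND_PROPORTIONS[-1][0]]

    dem_noise = _standardize(ndimage.gaussian_filter(rng.standard_normal(geom.shape), max(geom.n_rows, geom.n_cols) / 10.0))
    west_high = np.linspace(1.0, 0.0, geom.n_cols)[np.newaxis, :]
    dem = 4300.0 + 350.0 * dem_noise + 400.0 * np.broadcast_to(west_high, geom.shape)

    vc_noise = _standardize(ndimage.gaussian_filter(rng.standard_normal(geom.shape), 2.0))
    vegcover = 0.25 + 0.55 * ndimage.gaussian_filter(grass.astype(float), 1.5) + 0.10 * vc_noise
    vegcover = np.clip(vegcover, 0.0, 1.0)

    road_main = np.zeros(geom.shape, dtype=bool)
    for _ in range(config.n_roads_main):
        road_main |= _draw_polyline_road(rng, geom.shape, horizontal=True)
    road_branch = np.zeros(geom.shape, dtype=bool)
    for k in range(config.n_roads_branch):
        road_branch |= _draw_polyline_road(rng, geom.shape, horizontal=bool(k % 2))

    return LandscapeStack(
        geometry=geom,
        landuse=landuse,
        dem=dem,
        vegcover=vegcover,
        road_main=road_main,
        road_branch=road_branch,
    )


def aspect_from_dem(dem: np.ndarray, geometry: GridGeometry) -> np.ndarray:
    """Label each cell with the compass direction of steepest descent.

    Gradients are computed with Horn's 3x3 finite-difference stencil on
    interior cells; border cells inherit the value of the nearest interior
    cell. Cells with zero gradient are labelled ``flat`` (code 0); compass
    codes follow :data:`ASPECT_CODES`.
    """
    geometry.validate_layer(dem, "dem")
    z = np.asarray(dem, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("dem must be finite")
    n_rows, n_cols = z.shape
    if n_rows < 3 or n_cols < 3:
        return np.zeros(z.shape, dtype=np.int16)  # no interior: all flat

    cell = geometry.cell_size
    # Horn's method on the interior; letters follow the usual 3x3 layout
    #   a b c
    #   d e f        (row 0 = north)
    #   g h i
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cell)  # eastward
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * cell)  # northward

    scale = max(1.0, float(np.abs(z).max()))
    tol = 1e-12 * scale / cell
    flat = np.hypot(dzdx, dzdy) <= tol

    # compass bearing of the downslope vector (0 deg = N, 90 deg = E)
    bearing = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    sector = (np.round(bearing / 45.0).astype(int)) % 8  # 0=N .. 7=NW
    interior = np.where(flat, ASPECT_CODES["flat"], sector + 1).astype(np.int16)

    return np.pad(interior, 1, mode="edge")
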