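"""Morphological segmentation of a binary habitat map into seven classes.

A foreground/background raster is partitioned into ``core``, ``islet``,
``perforation``, ``edge``, ``loop``, ``bridge`` and ``branch`` using
mathematical morphology on the 8-neighborhood (chessboard) topology:

* ``core`` — foreground farther than ``edge_width`` (chessboard distance)
  from any background cell or the raster border; equivalently the erosion
  of the foreground by a ``(2w+1)^2`` square.
* ``islet`` — a foreground connected component containing no core.
* ``perforation`` / ``edge`` — the non-core band around core along interior
  background holes / along background connected to the outside world (a
  cell near both is a perforation).
* ``bridge`` / ``loop`` / ``branch`` — connector cells (non-core foreground
  separated from core by the boundary band) grouped into 8-connected
  components and classified by the number of distinct core areas they
  contact and, for a single core area, the number of disjoint contact-cell
  groups on that core.

This follows the published class semantics rather than any particular
toolbox internals; results can differ from reference software on highly
convoluted shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import GridGeometry
from .synthetic_landscape import LAND_CODES

__all__ = [
    "MSPA_CLASSES",
    "MSPA_CODES",
    "BinaryLandscape",
    "MSPAMap",
    "binarize",
    "mspa_classify",
    "mspa_stats",
]

#: Class-code table used in every raster and table this module emits.
MSPA_CLASSES = ("background", "core", "islet", "perforation", "edge", "loop", "bridge", "branch")
MSPA_CODES = {name: code for code, name in enumerate(MSPA_CLASSES)}

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BinaryLandscape:
    geometry: GridGeometry
    mask: np.ndarray  # bool; True = foreground

    def __post_init__(self) -> None:
        self.geometry.validate_layer(self.mask, "mask")
        if self.mask.dtype != bool:
            raise TypeError("mask must be boolean")


@dataclass(frozen=True)
class MSPAMap:
    geometry: GridGeometry
    label: np.ndarray  # int codes, see MSPA_CODES
    edge_width: int
    connectivity: int = 8

    def class_mask(self, name: str) -> np.ndarray:
        return self.label == MSPA_CODES[name]


def binarize(
    landuse: np.ndarray,
    foreground_classes: Iterable[str],
    geometry: GridGeometry,
) -> BinaryLandscape:
    """Set the listed land-use classes as foreground, everything else background."""
    names = list(foreground_classes)
    if not names:
        raise ValueError("foreground_classes must be non-empty")
    unknown = [n for n in names if n not in LAND_CODES]
    if unknown:
        raise ValueError(f"unknown land-use class(es): {unknown}; known: {sorted(LAND_CODES)}")
    codes = [LAND_CODES[n] for n in names]
    mask = np.isin(landuse, codes)
    return BinaryLandscape(geometry=geometry, mask=mask)


def _chessboard_dilate(mask: np.ndarray, width: int) -> np.ndarray:
    """Cells within chessboard distance <= width of ``mask``."""
    if not mask.any():
        return np.zeros_like(mask)
    size = 2 * width + 1
    return ndimage.binary_dilation(mask, structure=np.ones((size, size), dtype=bool))


def _border_band(shape: tuple[int, int], width: int) -> np.ndarray:
    """Cells within chessboard distance <= width of the outside of the raster."""
    band = np.zeros(shape, dtype=bool)
    w = min(width, max(shape))
    band[:w, :] = True
    band[-w:, :] = True
    band[:, :w] = True
    band[:, -w:] = True
    return band


def mspa_classify(binary: BinaryLandscape, edge_width: int = 1, connectivity: int = 8) -> MSPAMap:
    """Partition the foreground into the seven morphological classes.

    Cells outside the raster count as background connected to the outside
    world, so foreground touching the border is never core.
    """
    if edge_width < 1:
        raise ValueError("edge_width must be >= 1")
    if connectivity != 8:
        raise NotImplementedError("only the eight-neighborhood analysis is supported")
    mask = binary.mask
    w = edge_width
    label = np.zeros(mask.shape, dtype=np.int16)
    if not mask.any():
        return MSPAMap(binary.geometry, label, edge_width=w, connectivity=connectivity)

    size = 2 * w + 1
    core = ndimage.binary_erosion(mask, structure=np.ones((size, size), dtype=bool), border_value=0)

    fg_labels, _ = ndimage.label(mask, structure=_SQUARE3)
    core_bearing = np.unique(fg_labels[core])
    islet = mask & ~np.isin(fg_labels, core_bearing)

    # split background into outside-connected components and interior holes
    bg = ~mask
    bg_labels, n_bg = ndimage.label(bg, structure=_SQUARE3)
    border_ids = np.unique(
        np.concatenate([bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]])
    )
    border_ids = border_ids[border_ids > 0]
    outside = np.isin(bg_labels, border_ids)
    holes = bg & ~outside

    near_outside = _chessboard_dilate(outside, w) | _border_band(mask.shape, w)
    near_hole = _chessboard_dilate(holes, w)
    near_core = _chessboard_dilate(core, w)

    boundary = mask & ~core & ~islet
    perforation = boundary & near_hole  # perforation wins ties with edge
    edge = boundary & ~perforation & near_core
    connector = boundary & ~perforation & ~edge

    label[core] = MSPA_CODES["core"]
    label[islet] = MSPA_CODES["islet"]
    label[perforation] = MSPA_CODES["perforation"]
    label[edge] = MSPA_CODES["edge"]

    # connectors sit beyond the boundary band; they reach core through it,
    # so contact is tested at chessboard distance <= edge_width + 1
    core_labels, _ = ndimage.label(core, structure=_SQUARE3)
    conn_labels, n_conn = ndimage.label(connector, structure=_SQUARE3)
    reach_w = w + 1
    struct_reach = np.ones((2 * reach_w + 1, 2 * reach_w + 1), dtype=bool)
    slices = ndimage.find_objects(conn_labels)
    for cid in range(1, n_conn + 1):
        sl_r, sl_c = slices[cid - 1]
        win = (
            slice(max(0, sl_r.start - reach_w), min(mask.shape[0], sl_r.stop + reach_w)),
            slice(max(0, sl_c.start - reach_w), min(mask.shape[1], sl_c.stop + reach_w)),
        )
        comp_win = conn_labels[win] == cid
        reach = ndimage.binary_dilation(comp_win, structure=struct_reach)
        contact = reach & core[win]
        touched = np.unique(core_labels[win][contact])
        touched = touched[touched > 0]
        if touched.size >= 2:
            cls = "bridge"
        elif touched.size == 1:
            _, n_groups = ndimage.label(contact, structure=_SQUARE3)
            cls = "loop" if n_groups >= 2 else "branch"
        else:
            cls = "edge"  # connector in a core-bearing component touching no core
        label[win][comp_win] = MSPA_CODES[cls]

    return MSPAMap(binary.geometry, label, edge_width=w, connectivity=connectivity)


def mspa_stats(mspa_map: MSPAMap) -> pd.DataFrame:
    """Per-class area table: area (km^2), share of foreground and of total (%)."""
    geom = mspa_map.geometry
    cell_km2 = geom.cell_area_m2 * 1e-6
    counts = {name: int(np.count_nonzero(mspa_map.label == code)) for name, code in MSPA_CODES.items()}
    n_fg = sum(c for name, c in counts.items() if name != "background")
    rows = []
    for name in MSPA_CLASSES[1:]:
        n = counts[name]
        rows.append(
            {
                "class": name,
                "cells": n,
                "area_km2": n * cell_km2,
                "share_of_foreground_pct": 100.0 * n / n_fg if n_fg else 0.0,
                "share_of_total_pct": 100.0 * n / geom.n_cells,
            }
        )
    return pd.DataFrame(rows)
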