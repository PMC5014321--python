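"""Local (per-tile) classification of the spatial distribution.

The tile-area distribution analysis is re-run on the subset of tiles whose
centroids fall inside a circle centred on each tile in turn, sweeping a range
of circle diameters. Each centre tile receives the pattern class of its best
acceptable local fit (highest r^2 among diameters passing both the r^2 and
the distance cutoff), with the cluster sizes coarsened to one "clusters"
class and the polar variants to one "polar" class. Tiles failing everywhere
stay "unclassified".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import (
    InsufficientDataError,
    ReferenceGraph,
    compute_density,
    fit_and_score,
    inhomogeneity,
)
from .measure import CorrectionFactor, correct_tile_areas
from .segment import TileSet

__all__ = [
    "LocalClassificationMap",
    "LOCAL_CLASSES",
    "COARSE_CLASS",
    "CLASS_COLORS",
    "select_local_subset",
    "classify_local",
]

#: coarsened class per reference pattern (the per-diameter cluster sizes and
#: the polar variants are merged for display)
COARSE_CLASS = {
    "random": "random",
    "clusters_80": "clusters",
    "clusters_240": "clusters",
    "polar": "polar",
    "polar_clusters": "polar",
}

LOCAL_CLASSES = ("unclassified", "random", "clusters", "polar")

#: rendering convention: magenta = random, green = clusters, red = polar
CLASS_COLORS = {
    "unclassified": (0, 0, 0),
    "random": (255, 0, 255),
    "clusters": (0, 255, 0),
    "polar": (255, 0, 0),
}


@dataclass
class LocalClassificationMap:
    table: pd.DataFrame  # tile_id, class, r2, distance, diameter_used_um
    tiles: TileSet

    def label_raster(self) -> np.ndarray:
        """Integer raster of class codes (index into LOCAL_CLASSES)."""
        code = {c: i for i, c in enumerate(LOCAL_CLASSES)}
        lut = np.zeros(int(self.tiles.tile_labels.max()) + 1, dtype=np.uint8)
        for tid, cls in zip(self.table["tile_id"], self.table["class"]):
            lut[int(tid)] = code[cls]
        return lut[self.tiles.tile_labels]

    def render_rgb(self) -> np.ndarray:
        """8-bit RGB rendering using the magenta/green/red convention."""
        codes = self.label_raster()
        palette = np.array(
            [CLASS_COLORS[c] for c in LOCAL_CLASSES], dtype=np.uint8
        )
        return palette[codes]

    def class_fractions(self) -> dict:
        counts = self.table["class"].value_counts()
        total = len(self.table)
        return {c: counts.get(c, 0) / total for c in LOCAL_CLASSES}


def circle_rect_intersection_area(
    cx: float, cy: float, r: float, w: float, h: float
) -> float:
    """Area of the intersection of a circle with the rectangle [0,w]x[0,h].

    Used so the local density stays unbiased when the sliding circle juts
    over the image edge. Computed by 1-D integration of the chord length
    clipped to the rectangle (adaptive quadrature is overkill; a fine
    Simpson grid is exact to ~1e-6 relative for these smooth integrands).
    """
    if r <= 0:
        return 0.0
    x0, x1 = max(0.0, cx - r), min(w, cx + r)
    if x1 <= x0:
        return 0.0
    n = 513  # odd for Simpson
    x = np.linspace(x0, x1, n)
    half = np.sqrt(np.clip(r * r - (x - cx) ** 2, 0.0, None))
    y_top = np.minimum(h, cy + half)
    y_bot = np.maximum(0.0, cy - half)
    chord = np.clip(y_top - y_bot, 0.0, None)
    from scipy.integrate import simpson

    return float(simpson(chord, x=x))


def select_local_subset(
    tiles: TileSet, center_tile_id: int, diameter_um: float
) -> np.ndarray:
    """Tile ids whose centroid lies within the circle of ``diameter_um``
    centred on the centre tile's centroid (the centre tile included)."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    cents = tiles.centroids_um()
    ids = tiles.tiles["tile_id"].to_numpy()
    idx = np.flatnonzero(ids == center_tile_id)
    if len(idx) == 0:
        raise KeyError(f"tile {center_tile_id} not in tile set")
    center = cents[idx[0]]
    d = np.linalg.norm(cents - center, axis=1)
    return ids[d <= diameter_um / 2.0]


def classify_local(
    tiles: TileSet,
    measurements: list,
    correction: CorrectionFactor,
    reference: ReferenceGraph,
    diameter_range_um: tuple[float, float] = (4.0, 10.0),
    step_um: float = 1.0,
    min_r2: float = 0.45,
    max_distance: float = 1.0,
    min_tiles: int = 20,
    extrapolation_limit: float = 2.0,
) -> LocalClassificationMap:
    """Per-tile classification by sliding-circle re-analysis.

    For each tile and each diameter in the sweep, the corrected areas of the
    member tiles are fitted; the local density for the reference lookup is
    the number of corrected areas divided by the circle's own area. Among
    diameters whose fit passes both cutoffs the one with the highest r^2
    decides the class.
    """
    dmin, dmax = diameter_range_um
    if not (0 < dmin <= dmax):
        raise ValueError("empty or invalid diameter range")
    diameters = np.arange(dmin, dmax + 1e-9, step_um)
    if len(diameters) == 0:
        raise ValueError("empty diameter range")
    by_tile = {m.tile_id: m for m in measurements}
    corrected_all = correct_tile_areas(measurements, correction)
    # per-tile list of its split areas, for fast subset assembly
    areas_by_tile: dict[int, np.ndarray] = {}
    pos = 0
    for tid, n in zip(corrected_all.tile_ids, corrected_all.n_per_tile):
        areas_by_tile[int(tid)] = corrected_all.areas[pos : pos + n]
        pos += n
    cents = tiles.centroids_um()
    ids = tiles.tiles["tile_id"].to_numpy()
    id_to_row = {int(t): i for i, t in enumerate(ids)}
    rows = []
    for tid in ids:
        tid = int(tid)
        if tid not in by_tile:  # e.g. excluded border tile
            continue
        center = cents[id_to_row[tid]]
        dists = np.linalg.norm(cents - center, axis=1)
        best = None  # (r2, class, distance, diameter)
        for diam in diameters:
            member_ids = ids[dists <= diam / 2.0]
            member_ids = [int(m) for m in member_ids if int(m) in areas_by_tile]
            if len(member_ids) < min_tiles:
                continue
            areas = np.concatenate([areas_by_tile[m] for m in member_ids])
            # density over the part of the circle actually inside the image
            circle_area = circle_rect_intersection_area(
                center[0],
                center[1],
                diam / 2.0,
                tiles.field.width_nm * 1e-3,
                tiles.field.height_nm * 1e-3,
            )
            try:
                fit = fit_and_score(areas, min_areas=min_tiles, min_r2=min_r2)
            except (InsufficientDataError, ValueError, RuntimeError):
                continue
            if not fit.valid:
                continue
            rho = compute_density(len(areas), circle_area)
            try:
                inh = inhomogeneity(
                    fit,
                    rho,
                    reference,
                    max_distance=max_distance,
                    extrapolation_limit=extrapolation_limit,
                )
            except ValueError:
                continue
            if inh.nearest_class == "unclassified":
                continue
            cls = COARSE_CLASS[inh.nearest_class]
            if best is None or fit.r2 > best[0]:
                best = (fit.r2, cls, inh.distance_to_nearest, float(diam))
        if best is None:
            rows.append(
                {
                    "tile_id": tid,
                    "class": "unclassified",
                    "r2": np.nan,
                    "distance": np.nan,
                    "diameter_used_um": np.nan,
                }
            )
        else:
            rows.append(
                {
                    "tile_id": tid,
                    "class": best[1],
                    "r2": best[0],
                    "distance": best[2],
                    "diameter_used_um": best[3],
                }
            )
    return LocalClassificationMap(table=pd.DataFrame(rows), tiles=tiles)
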