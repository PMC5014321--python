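"""Per-tile area/intensity measurement, correction factor, and area splitting.

A tile's integrated intensity is proportional to the number of emitters it
contains, so dividing by the intensity of one detectable fluorescent entity
(the correction factor C) and splitting the tile into n = floor(I/C) equal
areas recovers, approximately, one area per emitter — enriching the tile-area
histogram with the density information carried by unresolved points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .segment import TileSet
from .simulate import GrayscaleImage

__all__ = [
    "TileMeasurement",
    "CorrectionFactor",
    "CorrectedAreas",
    "CORRECTION_METHODS",
    "measure_tiles",
    "estimate_correction_factor",
    "correct_tile_areas",
    "split_counts",
]

CORRECTION_METHODS = (
    "explicit",
    "minimum",
    "average_5pct",
    "average_10pct",
    "quartile1",
    "median",
    "accuracy_calibrated",
)


@dataclass(frozen=True)
class TileMeasurement:
    tile_id: int
    object_id: int
    area_um2: float
    intensity: float  # integrated (summed) intensity over the tile's pixels

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("tile area must be positive")
        if not np.isfinite(self.intensity):
            raise ValueError("tile intensity must be finite")


@dataclass(frozen=True)
class CorrectionFactor:
    value: float
    method: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise ValueError("correction factor must be > 0")
        if self.method not in CORRECTION_METHODS:
            raise ValueError(f"unknown correction method {self.method!r}")


@dataclass
class CorrectedAreas:
    """Tile areas after intensity-based splitting; total area is conserved."""

    areas: np.ndarray  # all corrected areas, um^2
    n_per_tile: np.ndarray  # split count n per source tile
    tile_ids: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.n_per_tile = np.asarray(self.n_per_tile, dtype=int)
        self.tile_ids = np.asarray(self.tile_ids, dtype=int)
        if np.any(self.n_per_tile < 1):
            raise ValueError("split counts must be >= 1")
        if len(self.areas) != int(self.n_per_tile.sum()):
            raise ValueError("|areas| must equal the sum of split counts")

    @property
    def n_areas(self) -> int:
        return len(self.areas)


def measure_tiles(
    tiles: TileSet, smoothed: GrayscaleImage, exclude_border: bool = False
) -> list[TileMeasurement]:
    """One measurement per tile on the smoothed grayscale image.

    Intensity is the *sum* of pixel values inside the tile (integrated
    intensity), the statistic proportional to the emitter count.
    """
    if tiles.tile_labels.shape != smoothed.pixels.shape:
        raise ValueError("tile set and image geometry differ")
    ids = tiles.tiles["tile_id"].to_numpy()
    sums = ndi.sum_labels(smoothed.pixels, tiles.tile_labels, index=ids)
    px_um2 = (tiles.field.pixel_size_nm * 1e-3) ** 2
    if exclude_border:
        border = np.unique(
            np.concatenate(
                [
                    tiles.tile_labels[0, :],
                    tiles.tile_labels[-1, :],
                    tiles.tile_labels[:, 0],
                    tiles.tile_labels[:, -1],
                ]
            )
        )
        keep = ~np.isin(ids, border)
    else:
        keep = np.ones(len(ids), bool)
    out = []
    for tid, oid, area_px, s, k in zip(
        ids,
        tiles.tiles["object_id"].to_numpy(),
        tiles.tiles["area_px"].to_numpy(),
        sums,
        keep,
    ):
        if k:
            out.append(
                TileMeasurement(
                    tile_id=int(tid),
                    object_id=int(oid),
                    area_um2=float(area_px * px_um2),
                    intensity=float(s),
                )
            )
    return out


def split_counts(intensities: np.ndarray, c: float) -> np.ndarray:
    """n = floor(I/C) with a minimum of one area per tile (no correction when
    I < C)."""
    n = np.floor(np.asarray(intensities, dtype=float) / c).astype(int)
    return np.maximum(n, 1)


def _total_areas_for(intensities: np.ndarray, c: float) -> int:
    return int(split_counts(intensities, c).sum())


def _calibrate_accuracy(intensities: np.ndarray, true_count: int) -> float:
    """Search C so the number of corrected areas best matches the true emitter
    count (accuracy N_A / N closest to 1). N_A(C) is a nonincreasing step
    function of C, so a bisection over C converges to the optimum."""
    if true_count <= 0:
        raise ValueError("true point count must be positive for calibration")
    total = float(np.sum(intensities))
    lo = max(total / (10.0 * true_count), 1e-12)
    hi = float(np.max(intensities)) + 1.0
    best_c, best_err = hi, abs(_total_areas_for(intensities, hi) - true_count)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        na = _total_areas_for(intensities, mid)
        err = abs(na - true_count)
        if err < best_err or (err == best_err and mid < best_c):
            best_c, best_err = mid, err
        if na > true_count:
            lo = mid
        else:
            hi = mid
    return best_c


def estimate_correction_factor(
    measurements: list[TileMeasurement],
    method: str = "quartile1",
    explicit_value: float | None = None,
    true_count: int | None = None,
) -> CorrectionFactor:
    """Estimate C from the tile-intensity distribution (or pass it through).

    Quantile methods use linear interpolation between order statistics.
    ``accuracy_calibrated`` is simulation-only: it needs the true emitter
    count and tunes C so the corrected-area count reproduces it.
    """
    if method == "explicit":
        if explicit_value is None or explicit_value <= 0:
            raise ValueError("explicit method requires a positive value")
        return CorrectionFactor(float(explicit_value), "explicit", "user supplied")
    intensities = np.array([m.intensity for m in measurements], dtype=float)
    if method in ("quartile1", "median", "average_5pct", "average_10pct") and len(
        intensities
    ) < 4:
        raise ValueError("quantile methods need at least 4 tiles")
    if len(intensities) == 0:
        raise ValueError("no tile measurements")
    if method == "minimum":
        value = float(np.min(intensities))
    elif method == "average_5pct":
        value = _tail_mean(intensities, 0.05)
    elif method == "average_10pct":
        value = _tail_mean(intensities, 0.10)
    elif method == "quartile1":
        value = float(np.percentile(intensities, 25))
    elif method == "median":
        value = float(np.percentile(intensities, 50))
    elif method == "accuracy_calibrated":
        if true_count is None:
            raise ValueError("accuracy calibration requires the true point count")
        value = _calibrate_accuracy(intensities, int(true_count))
    else:
        raise ValueError(f"unknown correction method {method!r}")
    if value <= 0:
        raise ValueError(
            f"correction method {method!r} produced a non-positive factor; "
            "background subtraction may have zeroed the dimmest tiles"
        )
    return CorrectionFactor(value, method, f"estimated from {len(intensities)} tiles")


def _tail_mean(x: np.ndarray, frac: float) -> float:
    k = max(1, int(np.ceil(frac * len(x))))
    return float(np.mean(np.sort(x)[:k]))


def correct_tile_areas(
    measurements: list[TileMeasurement], c: CorrectionFactor
) -> CorrectedAreas:
    """Split each tile into n = floor(I/C) equal areas (n >= 1).

    The per-tile total is conserved exactly: n copies of A/n sum back to A.
    """
    intensities = np.array([m.intensity for m in measurements], dtype=float)
    areas_t = np.array([m.area_um2 for m in measurements], dtype=float)
    ids = np.array([m.tile_id for m in measurements], dtype=int)
    n = split_counts(intensities, c.value)
    areas = np.repeat(areas_t / n, n)
    return CorrectedAreas(areas=areas, n_per_tile=n, tile_ids=ids)
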