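"""Standard-format I/O: TIFF images and localization tables.

Localization tables (e.g. from single-molecule localization microscopy,
already drift-corrected and blink-grouped upstream) are rendered onto a
fine raster — 2.5 nm pixels by default — sized from the coordinate extrema,
after which they enter the ordinary image pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .simulate import FieldGeometry, GrayscaleImage

__all__ = [
    "read_image",
    "write_image",
    "LocalizationTable",
    "read_localizations",
    "render_localizations",
]


def read_image(
    path: str | Path, pixel_size_nm: Optional[float] = None, channel: Optional[int] = None
) -> GrayscaleImage:
    """Read a single-channel TIFF as a float raster with physical pixel size.

    The pixel size is taken from the TIFF resolution tag when present
    (expected in pixels-per-unit with a centimetre or inch unit), otherwise
    ``pixel_size_nm`` is required. Multi-channel files need ``channel``.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = tf.asarray()
        tag_size = _pixel_size_from_tags(page)
    if data.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path.name}: multi-channel image; pass an explicit channel"
            )
        axis = int(np.argmin(data.shape))
        data = np.take(data, channel, axis=axis)
    if data.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2-D image, got shape {data.shape}")
    px = pixel_size_nm if pixel_size_nm is not None else tag_size
    if px is None:
        raise ValueError(
            f"{path.name}: no resolution metadata; pass pixel_size_nm explicitly"
        )
    field = FieldGeometry(data.shape[1], data.shape[0], float(px))
    return GrayscaleImage(
        pixels=data.astype(float), field=field, provenance=str(path)
    )


def _pixel_size_from_tags(page) -> Optional[float]:
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags.get("ResolutionUnit")
    except (KeyError, AttributeError):
        return None
    num, den = xres if isinstance(xres, tuple) else (xres, 1)
    if not num:
        return None
    pixels_per_unit = num / den
    unit_nm = {2: 2.54e7, 3: 1e7}.get(getattr(unit, "value", unit and unit.value), None)
    if unit_nm is None:
        return None
    return unit_nm / pixels_per_unit


def write_image(path: str | Path, img: GrayscaleImage, dtype: str = "float32") -> Path:
    """Write a single-channel TIFF with a resolution tag (pixels per cm)."""
    path = Path(path)
    if dtype == "uint16":
        data = np.clip(np.round(img.pixels), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = img.pixels.astype(np.float32)
    else:
        raise ValueError("dtype must be 'float32' or 'uint16'")
    px_per_cm = 1e7 / img.field.pixel_size_nm
    tifffile.imwrite(
        path,
        data,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )
    return path


@dataclass
class LocalizationTable:
    """x/y localization coordinates with a unit tag ('nm' or 'px')."""

    coords: pd.DataFrame  # columns x, y (+ optional precision_nm)
    unit: str
    source_pixel_size_nm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.unit not in ("nm", "px"):
            raise ValueError("unit must be 'nm' or 'px'")
        if self.unit == "px" and not self.source_pixel_size_nm:
            raise ValueError("pixel-unit tables need source_pixel_size_nm")
        if not np.all(np.isfinite(self.coords[["x", "y"]].to_numpy(float))):
            raise ValueError("coordinates must be finite")

    def coords_nm(self) -> np.ndarray:
        xy = self.coords[["x", "y"]].to_numpy(dtype=float)
        if self.unit == "px":
            xy = xy * self.source_pixel_size_nm
        return xy


def read_localizations(
    path: str | Path,
    unit: str = "nm",
    source_pixel_size_nm: Optional[float] = None,
    x_col: str = "x",
    y_col: str = "y",
    precision_col: Optional[str] = None,
) -> LocalizationTable:
    """Read a delimited localization table (delimiter sniffed by pandas)."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {x_col: "x", y_col: "y"}
    if precision_col:
        cols[precision_col] = "precision_nm"
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns {missing} in {path}")
    return LocalizationTable(
        coords=df[list(cols)].rename(columns=cols),
        unit=unit,
        source_pixel_size_nm=source_pixel_size_nm,
    )


def render_localizations(
    table: LocalizationTable,
    render_px_nm: float = 2.5,
    mode: str = "counts",
) -> GrayscaleImage:
    """Rasterise localizations at ``render_px_nm`` pixels.

    The canvas spans the coordinate extrema. In 'counts' mode each
    localization deposits one count in its pixel bin; in 'gaussian' mode it
    deposits a unit-integral Gaussian of its localization precision.
    """
    if len(table.coords) == 0:
        raise ValueError("empty localization table")
    xy = table.coords_nm()
    mins = xy.min(axis=0)
    span = xy.max(axis=0) - mins
    width = max(int(math.floor(span[0] / render_px_nm)) + 1, 16)
    height = max(int(math.floor(span[1] / render_px_nm)) + 1, 16)
    raster = np.zeros((height, width))
    ij = np.floor((xy - mins) / render_px_nm).astype(int)
    ij[:, 0] = np.clip(ij[:, 0], 0, width - 1)
    ij[:, 1] = np.clip(ij[:, 1], 0, height - 1)
    if mode == "counts":
        np.add.at(raster, (ij[:, 1], ij[:, 0]), 1.0)
    elif mode == "gaussian":
        from scipy import ndimage as ndi

        if "precision_nm" not in table.coords.columns:
            raise ValueError("gaussian mode needs a precision column")
        prec = table.coords["precision_nm"].to_numpy(dtype=float)
        for (cx, cy), p in zip(ij, prec):
            stamp = np.zeros_like(raster)
            stamp[cy, cx] = 1.0
            raster += ndi.gaussian_filter(
                stamp, max(p / render_px_nm, 1e-3), truncate=4.0
            )
    else:
        raise ValueError("mode must be 'counts' or 'gaussian'")
    field = FieldGeometry(width, height, render_px_nm)
    return GrayscaleImage(pixels=raster, field=field, provenance="localizations")
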