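"""End-to-end analysis pipeline and configuration.

Order of operations: background subtraction -> edge-preserving smoothing ->
automatic threshold -> optional watershed separation -> tessellation ->
per-tile measurement -> correction factor -> area splitting -> Inverse-Gamma
fit + r^2 gate -> density -> (optional) inhomogeneity against a reference
graph -> (optional) local classification.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .fitting import (
    DEFAULT_MIN_AREAS,
    DEFAULT_MIN_R2,
    DensityResult,
    InhomogeneityResult,
    InsufficientDataError,
    InverseGammaFit,
    ReferenceGraph,
    compute_density,
    fit_and_score,
    inhomogeneity,
)
from .measure import (
    CorrectedAreas,
    CorrectionFactor,
    correct_tile_areas,
    estimate_correction_factor,
    measure_tiles,
)
from .segment import (
    ObjectMask,
    TileSet,
    binarize,
    preprocess,
    separate_touching,
    subtract_background,
    tessellate,
)
from .simulate import (
    DEFAULT_WF_FIELD,
    FieldGeometry,
    GrayscaleImage,
    PatternSpec,
    PointPattern,
    SimulationConfig,
    generate_pattern,
    render_microscope_image,
)

__all__ = [
    "AnalysisConfig",
    "ImageResult",
    "analyze_image",
    "simulate_and_analyze",
    "pattern_spec_for_class",
    "run_batch",
    "aggregate_results",
]

log = logging.getLogger("tilestats")


@dataclass
class AnalysisConfig:
    """All tunable parameters of the analysis, serialised with every result."""

    threshold_method: str = "isodata"
    sigma_radius: int = 2
    sigma_mult: float = 2.0
    sigma_min_fraction: float = 0.2
    smooth_size: int = 3
    background_mode: str = "median"  # none | median | constant | rolling_ball
    background_value: Optional[float] = None
    rolling_ball_radius: int = 50
    watershed_fraction: float = 0.25
    correction_method: str = "quartile1"
    correction_value: Optional[float] = None
    exclude_border_tiles: bool = False
    min_areas: int = DEFAULT_MIN_AREAS
    min_r2: float = DEFAULT_MIN_R2
    binning: str = "fd"
    max_distance: float = 1.0
    local_dmin_um: float = 4.0
    local_dmax_um: float = 10.0
    local_step_um: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class ImageResult:
    """Bundle of everything one image produced, plus a flat summary row."""

    config: AnalysisConfig
    image: GrayscaleImage
    smoothed: GrayscaleImage
    mask: ObjectMask
    tiles: TileSet
    measurements: list
    correction: CorrectionFactor
    corrected: CorrectedAreas
    fit: Optional[InverseGammaFit]
    density: DensityResult
    inhomogeneity: Optional[InhomogeneityResult] = None
    fit_error: Optional[str] = None
    provenance: str = ""
    true_count: Optional[int] = None
    pattern: Optional[PointPattern] = None

    def summary(self) -> dict:
        row = {
            "provenance": self.provenance,
            "n_objects": self.mask.n_objects,
            "n_tiles": self.tiles.n_tiles,
            "threshold": self.mask.threshold,
            "foreground_fraction": self.mask.foreground_fraction,
            "correction_factor": self.correction.value,
            "correction_method": self.correction.method,
            "n_areas": self.density.n_areas,
            "rho": self.density.rho,
            "alpha": self.fit.shape if self.fit else np.nan,
            "beta": self.fit.scale if self.fit else np.nan,
            "r2": self.fit.r2 if self.fit else np.nan,
            "valid": bool(self.fit.valid) if self.fit else False,
            "config_hash": self.config.hash(),
            "version": __version__,
        }
        if self.true_count is not None:
            row["true_count"] = self.true_count
            row["accuracy"] = self.density.n_areas / self.true_count
        if self.inhomogeneity is not None:
            row["inhomogeneity"] = self.inhomogeneity.value
            row["nearest_class"] = self.inhomogeneity.nearest_class
            row["distance"] = self.inhomogeneity.distance_to_nearest
        return row

    def tile_table(self) -> pd.DataFrame:
        n_map = dict(zip(self.corrected.tile_ids, self.corrected.n_per_tile))
        return pd.DataFrame(
            {
                "tile_id": [m.tile_id for m in self.measurements],
                "object_id": [m.object_id for m in self.measurements],
                "area_um2": [m.area_um2 for m in self.measurements],
                "intensity": [m.intensity for m in self.measurements],
                "n_split": [n_map.get(m.tile_id, 1) for m in self.measurements],
            }
        )


def analyze_image(
    img: GrayscaleImage,
    config: Optional[AnalysisConfig] = None,
    reference: Optional[ReferenceGraph] = None,
    true_count: Optional[int] = None,
    pattern: Optional[PointPattern] = None,
) -> ImageResult:
    """Run the full global analysis on one grayscale image."""
    config = config or AnalysisConfig()
    log.info("analyze: %s, config %s", img.provenance, config.hash())
    stage = "background"
    try:
        bg = subtract_background(
            img,
            mode=config.background_mode,
            value=config.background_value,
            rolling_ball_radius=config.rolling_ball_radius,
        )
        stage = "preprocess"
        smoothed = preprocess(
            bg,
            radius=config.sigma_radius,
            sigma_mult=config.sigma_mult,
            min_fraction=config.sigma_min_fraction,
            smooth_size=config.smooth_size,
        )
        stage = "binarize"
        mask = binarize(smoothed, method=config.threshold_method)
        stage = "separate_touching"
        mask = separate_touching(mask, fraction_threshold=config.watershed_fraction)
        stage = "tessellate"
        tiles = tessellate(mask, field=img.field)
        stage = "measure"
        measurements = measure_tiles(
            tiles, smoothed, exclude_border=config.exclude_border_tiles
        )
        stage = "correction"
        correction = estimate_correction_factor(
            measurements,
            method=config.correction_method,
            explicit_value=config.correction_value,
            true_count=true_count,
        )
        corrected = correct_tile_areas(measurements, correction)
        stage = "fit"
        density = compute_density(corrected, img.field)
        fit: Optional[InverseGammaFit] = None
        fit_error: Optional[str] = None
        try:
            fit = fit_and_score(
                corrected,
                min_areas=config.min_areas,
                rule=config.binning,
                min_r2=config.min_r2,
            )
        except (InsufficientDataError, ValueError, RuntimeError) as exc:
            fit_error = str(exc)
            log.warning("fit failed: %s", exc)
        inh = None
        if reference is not None and fit is not None and fit.valid:
            stage = "inhomogeneity"
            try:
                inh = inhomogeneity(
                    fit, density, reference, max_distance=config.max_distance
                )
            except ValueError as exc:
                # e.g. density outside the reference range: keep the fit,
                # report no inhomogeneity for this image
                fit_error = (fit_error + "; " if fit_error else "") + str(exc)
                log.warning("inhomogeneity unavailable: %s", exc)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return ImageResult(
        config=config,
        image=img,
        smoothed=smoothed,
        mask=mask,
        tiles=tiles,
        measurements=measurements,
        correction=correction,
        corrected=corrected,
        fit=fit,
        density=density,
        inhomogeneity=inh,
        fit_error=fit_error,
        provenance=img.provenance,
        true_count=true_count,
        pattern=pattern,
    )


def pattern_spec_for_class(pattern_class: str, n_points: int) -> PatternSpec:
    """Map a reference-graph class name to a concrete pattern specification."""
    if pattern_class == "random":
        return PatternSpec(kind="random", n_points=n_points)
    if pattern_class == "clusters_80":
        return PatternSpec(kind="clustered", n_points=n_points, cluster_diameter_nm=80.0)
    if pattern_class == "clusters_240":
        return PatternSpec(kind="clustered", n_points=n_points, cluster_diameter_nm=240.0)
    if pattern_class == "polar":
        return PatternSpec(kind="polar", n_points=n_points)
    if pattern_class == "polar_clusters":
        return PatternSpec(
            kind="polar_clustered", n_points=n_points, cluster_diameter_nm=240.0
        )
    if pattern_class == "regular":
        return PatternSpec(kind="regular", n_points=n_points)
    raise ValueError(f"unknown pattern class {pattern_class!r}")


def simulate_and_analyze(
    pattern_class: str,
    density: float,
    field: FieldGeometry = DEFAULT_WF_FIELD,
    sim_cfg: Optional[SimulationConfig] = None,
    config: Optional[AnalysisConfig] = None,
    seed: int = 0,
    reference: Optional[ReferenceGraph] = None,
) -> ImageResult:
    """Simulate one image of ``pattern_class`` at the nominal density
    (points per um^2) and run the full analysis; the true emitter count is
    passed through so accuracy calibration is available."""
    sim_cfg = sim_cfg or SimulationConfig()
    config = config or AnalysisConfig(correction_method="accuracy_calibrated")
    n_points = max(2, round(density * field.area_um2))
    spec = pattern_spec_for_class(pattern_class, n_points)
    pat = generate_pattern(spec, field, seed=seed)
    img = render_microscope_image(
        pat, dataclasses.replace(sim_cfg, seed=seed + 1)
    )
    img.provenance = f"simulated:{pattern_class}@{density}"
    return analyze_image(
        img, config, reference=reference, true_count=n_points, pattern=pat
    )


def run_pipeline(
    config: Optional[AnalysisConfig],
    source,
    reference: Optional[ReferenceGraph] = None,
    render_px_nm: float = 2.5,
    true_count: Optional[int] = None,
) -> ImageResult:
    """Analyze a grayscale image or a localization table.

    Localization tables are first rendered onto a fine raster (default
    2.5 nm pixels) and then follow the standard image pipeline.
    """
    from .io import LocalizationTable, render_localizations

    if isinstance(source, LocalizationTable):
        source = render_localizations(source, render_px_nm=render_px_nm)
    if not isinstance(source, GrayscaleImage):
        raise TypeError("source must be a GrayscaleImage or LocalizationTable")
    return analyze_image(source, config, reference=reference, true_count=true_count)


def run_batch(
    images: list[GrayscaleImage],
    config: Optional[AnalysisConfig] = None,
    reference: Optional[ReferenceGraph] = None,
) -> pd.DataFrame:
    """Analyze a list of images; returns one summary row per image."""
    rows = []
    for img in images:
        res = analyze_image(img, config, reference=reference)
        rows.append(res.summary())
    return pd.DataFrame(rows)


def aggregate_results(summaries: pd.DataFrame) -> dict:
    """Mean/SEM of the fit parameters over images, excluding invalid fits
    (r^2 below the quality gate) from every aggregate."""
    valid = summaries[summaries["valid"].astype(bool)]
    n = len(valid)
    out = {
        "n_images": int(len(summaries)),
        "n_valid": int(n),
        "n_discarded": int(len(summaries) - n),
    }
    for col in ("alpha", "beta", "rho", "r2", "inhomogeneity"):
        if col in valid.columns and n:
            v = valid[col].to_numpy(dtype=float)
            out[f"{col}_mean"] = float(np.mean(v))
            out[f"{col}_sem"] = (
                float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            )
    return out
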