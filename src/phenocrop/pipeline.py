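"""End-to-end per-pixel classification and the file-based pipeline driver.

Stage order: preprocessing (indices + smoothing + availability), purity
stratification, wavelet cropping intensity, season segmentation, per-season
crop rules, pattern encoding, and (when truth is available) accuracy
assessment.  Every input pixel appears in the output either as a pattern code
or as the reserved no-data code with an explicit reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .crop_rules import (
    DEFAULT_THRESHOLDS,
    SeasonMetrics,
    ThresholdConfig,
    WheatCalendar,
    classify_season,
    maize_metrics,
    rice_metrics,
    wheat_metrics,
)
from .intensity import IntensityParams, SeasonWindow, cropping_index, segment_seasons, wavelet_spectrum
from .pattern_codes import Crop, NODATA_CODE, decode_pattern, encode_pattern
from .preprocess import (
    DEFAULT_LAMBDA,
    Availability,
    IndexSeries,
    ReflectanceSeries,
    UnprocessablePixelError,
    smooth_indices,
)
from .purity import Stratum, classify_purity
from .validation import accuracy_metrics, confusion_matrix

__all__ = [
    "PipelineParams",
    "PixelResult",
    "SceneResult",
    "classify_pixel",
    "compute_season_metrics",
    "pattern_scores",
    "run_pipeline",
    "run_scene",
]

log = logging.getLogger("phenocrop")


@dataclass(frozen=True)
class PipelineParams:
    """All tunable constants of the classification pipeline."""

    lam: dict = field(default_factory=lambda: dict(DEFAULT_LAMBDA))
    intensity: IntensityParams = field(default_factory=IntensityParams)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    wheat_calendar: WheatCalendar = field(default_factory=lambda: WheatCalendar(120.0, 150.0))
    wheat_gate_days: float = 30.0  # wheat rule only near the calendar heading
    maize_window_halfwidth: float = 24.0


@dataclass
class PixelResult:
    code: int
    reason: str  # "ok" or the explicit no-data reason
    availability: Availability
    stratum: Stratum
    intensity: int | None = None
    windows: list = field(default_factory=list)
    labels: list = field(default_factory=list)
    metrics: list = field(default_factory=list)


def compute_season_metrics(
    idx: IndexSeries, window: SeasonWindow, params: PipelineParams
) -> SeasonMetrics:
    """Assemble the rule metrics of one season from daily trajectories.

    The wheat metrics are only evaluated when the season's detected heading
    date falls within ``wheat_gate_days`` of the calendar-predicted heading
    (the calendar surface encodes where/when wheat is possible at all).
    """
    m = SeasonMetrics()
    rm = rice_metrics(idx.grid, idx.lswi, idx.evi2, window)
    if rm is not None:
        m.lswi_min, m.lswi_max, m.rcle = rm
    cal = params.wheat_calendar
    if abs(window.heading_doy - cal.heading_doy) <= params.wheat_gate_days:
        wm = wheat_metrics(idx.grid, idx.evi2, cal, window.harvest_doy)
        if wm is not None:
            m.eve, m.evl = wm
    hw = params.maize_window_halfwidth
    m.rcpn = maize_metrics(
        idx.grid,
        idx.nmdi,
        (window.heading_doy - hw, window.heading_doy + hw),
        sigma=params.thresholds.sigma,
    )
    return m


def classify_pixel(
    series: ReflectanceSeries,
    fraction: float,
    params: PipelineParams | None = None,
) -> PixelResult:
    """Classify one pixel's reflectance series into a cropping-pattern code."""
    params = params or PipelineParams()
    stratum = classify_purity(fraction)
    try:
        idx = smooth_indices(series, lam=params.lam)
        availability = idx.availability
    except UnprocessablePixelError:
        from .preprocess import data_availability

        availability = data_availability(series.dates, series.valid)
        return PixelResult(NODATA_CODE, "unprocessable", availability, stratum)
    if stratum == Stratum.EXCLUDED:
        return PixelResult(NODATA_CODE, "excluded_purity", availability, stratum)

    feats = wavelet_spectrum(idx.grid, idx.evi2, params.intensity)
    k = cropping_index(feats, params.intensity)
    result = PixelResult(0, "ok", availability, stratum, intensity=k)
    if k == 0:
        return result
    if k >= 3:
        result.code = 3
        return result

    windows = segment_seasons(idx.grid, idx.evi2, k, params.intensity)
    if not windows:
        result.intensity = 0
        return result
    k = min(k, len(windows))
    result.intensity = k
    result.windows = windows
    for w in windows:
        m = compute_season_metrics(idx, w, params)
        result.metrics.append(m)
        result.labels.append(classify_season(m, stratum, params.thresholds))
    result.code = encode_pattern(k, result.labels)
    return result


@dataclass
class SceneResult:
    pattern: np.ndarray  # uint16 codes, NODATA_CODE where not classified
    availability: np.ndarray  # uint8 classes 1/2/3
    diagnostics: pd.DataFrame  # one row per pixel
    seasons: pd.DataFrame  # one row per detected season


def run_scene(scene, fraction: np.ndarray | None = None, params: PipelineParams | None = None) -> SceneResult:
    """Classify every pixel of a (simulated or loaded) scene."""
    params = params or PipelineParams()
    fraction = scene.config.purity_map if fraction is None else np.asarray(fraction)
    rows, cols = fraction.shape
    pattern = np.full((rows, cols), NODATA_CODE, dtype=np.uint16)
    avail = np.zeros((rows, cols), dtype=np.uint8)
    diag_rows, season_rows = [], []
    for r in range(rows):
        for c in range(cols):
            res = classify_pixel(scene.pixel(r, c), float(fraction[r, c]), params)
            pattern[r, c] = res.code
            avail[r, c] = int(res.availability)
            diag_rows.append(
                {
                    "row": r,
                    "col": c,
                    "fraction": float(fraction[r, c]),
                    "stratum": int(res.stratum),
                    "availability": int(res.availability),
                    "intensity": res.intensity,
                    "code": int(res.code),
                    "reason": res.reason,
                }
            )
            for rank, (w, label) in enumerate(zip(res.windows, res.labels), start=1):
                season_rows.append(
                    {
                        "row": r,
                        "col": c,
                        "season_rank": rank,
                        "start": w.start_doy,
                        "tillering": w.tillering_doy,
                        "heading": w.heading_doy,
                        "harvest": w.harvest_doy,
                        "amplitude": round(w.amplitude, 4),
                        "label": label.value,
                    }
                )
    return SceneResult(pattern, avail, pd.DataFrame(diag_rows), pd.DataFrame(season_rows))


def pattern_scores(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Pattern-level accuracy and per-crop presence F1 between code rasters.

    Overall accuracy counts exact code agreement over classified pixels;
    the per-crop F1 compares binary presence of each staple crop (a pixel
    contains the crop if its decoded composition does).
    """
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    ok = pred != NODATA_CODE
    scores = {"n": int(ok.sum()), "pattern_accuracy": float((pred[ok] == truth[ok]).mean())}
    for crop in (Crop.RICE, Crop.WHEAT, Crop.MAIZE):
        def has(codes):
            return np.array([crop in decode_pattern(int(k))[1] for k in codes])

        cm = confusion_matrix(has(pred[ok]), has(truth[ok]), [True, False])
        rep = accuracy_metrics(cm, classes=[True, False])
        scores[f"f1_{crop.value}"] = rep.f1[True]
    return scores


def run_pipeline(config: "pio.PipelineConfig") -> SceneResult:
    """File-based pipeline: read a scene directory, classify, persist outputs.

    Writes the pattern raster, the availability raster, per-pixel diagnostics
    and per-season metrics CSVs, and a JSON run report (plus an accuracy
    report when the scene carries a truth raster).
    """
    params = config.params()
    scene = pio.read_scene(config.scene_dir)
    log.info("scene %s: %dx%d pixels", config.scene_dir, *scene.truth.shape)
    result = run_scene(scene, params=params)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_raster(out / "pattern.tif", result.pattern, nodata=NODATA_CODE)
    pio.write_raster(out / "availability.tif", result.availability)
    result.diagnostics.to_csv(out / "diagnostics.csv", index=False)
    result.seasons.to_csv(out / "seasons.csv", index=False)

    report = {
        "seed": scene.config.seed,
        "n_pixels": int(result.pattern.size),
        "n_classified": int((result.pattern != NODATA_CODE).sum()),
        "params": {
            "lambda": params.lam,
            "thresholds": {
                "theta1": params.thresholds.theta1,
                "theta2": params.thresholds.theta2,
                "theta3": params.thresholds.theta3,
                "theta4": params.thresholds.theta4,
                "theta5": params.thresholds.theta5,
                "sigma": params.thresholds.sigma,
            },
        },
    }
    if scene.truth is not None:
        report["accuracy"] = pattern_scores(result.pattern, scene.truth)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    log.info("outputs written to %s", out)
    return result
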