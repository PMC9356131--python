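"""Raster and table adapters plus pipeline configuration.

Rasters are written as plain TIFF via tifffile with a JSON sidecar
(``<name>.aux.json``) carrying the georeferencing a practitioner expects from
a GeoTIFF: CRS (WGS-84 by default), a GDAL-style affine transform, and the
no-data value.  Values, grid and metadata round-trip losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .crop_rules import ThresholdConfig, WheatCalendar
from .intensity import IntensityParams
from .preprocess import DEFAULT_LAMBDA

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_ground_truth",
    "read_raster",
    "read_scene",
    "write_raster",
    "write_scene",
]

DEFAULT_CRS = "EPSG:4326"
DEFAULT_TRANSFORM = (100.0, 0.005, 0.0, 40.0, 0.0, -0.005)  # ~500 m cells at 40 N


def write_raster(
    path,
    array: np.ndarray,
    nodata=None,
    crs: str = DEFAULT_CRS,
    transform=DEFAULT_TRANSFORM,
) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array), photometric="minisblack")
    meta = {
        "crs": crs,
        "transform": list(transform),
        "nodata": None if nodata is None else float(nodata),
        "dtype": str(np.asarray(array).dtype),
    }
    path.with_suffix(path.suffix + ".aux.json").write_text(json.dumps(meta, indent=2))


def read_raster(path, expect_crs: str | None = None) -> tuple[np.ndarray, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    array = tifffile.imread(path)
    aux = path.with_suffix(path.suffix + ".aux.json")
    meta = json.loads(aux.read_text()) if aux.exists() else {}
    if expect_crs and meta.get("crs") not in (None, expect_crs):
        raise ValueError(f"CRS mismatch: {meta.get('crs')} != {expect_crs}")
    return array, meta


def write_scene(scene, directory) -> None:
    """Persist a simulated scene: band stack, validity, truth, fraction, meta."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_raster(d / "reflectance.tif", scene.reflectance.astype(np.float32))
    write_raster(d / "valid.tif", scene.valid.astype(np.uint8))
    write_raster(d / "truth.tif", scene.truth.astype(np.uint16))
    write_raster(d / "fraction.tif", scene.config.purity_map.astype(np.float32))
    meta = {
        "dates": [int(x) for x in scene.dates],
        "n_rows": scene.config.n_rows,
        "n_cols": scene.config.n_cols,
        "noise_sd": scene.config.noise_sd,
        "gap_rate": scene.config.gap_rate,
        "seed": scene.config.seed,
    }
    (d / "scene.json").write_text(json.dumps(meta, indent=2))


def read_scene(directory):
    from .simulate import Scene, SceneConfig

    d = Path(directory)
    meta_path = d / "scene.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"scene metadata not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    refl, _ = read_raster(d / "reflectance.tif")
    valid, _ = read_raster(d / "valid.tif")
    truth, _ = read_raster(d / "truth.tif")
    fraction, _ = read_raster(d / "fraction.tif")
    if truth.shape != fraction.shape:
        raise ValueError("truth and fraction rasters are misaligned")
    config = SceneConfig(
        n_rows=meta["n_rows"],
        n_cols=meta["n_cols"],
        pattern_map=truth.astype(int),
        purity_map=fraction.astype(float),
        noise_sd=meta.get("noise_sd", 0.0),
        gap_rate=meta.get("gap_rate", 0.0),
        seed=meta.get("seed", 0),
    )
    return Scene(
        np.asarray(meta["dates"]), refl.astype(float), valid.astype(bool),
        truth.astype(int), config,
    )


GROUND_TRUTH_COLUMNS = ("site_id", "lon", "lat", "year", "class")


def read_ground_truth(path) -> pd.DataFrame:
    """Read a ground-truth site table; malformed rows are rejected by number."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ground truth table not found: {path}")
    df = pd.read_csv(path)
    missing = set(GROUND_TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ground truth table missing columns: {sorted(missing)}")
    for col in ("lon", "lat", "year"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((coerced.isna()).idxmax())
            raise ValueError(f"malformed value in column {col!r} at data row {row}")
        df[col] = coerced
    return df


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (paths + constant overrides)."""

    scene_dir: str
    output_dir: str
    year: int = 2020
    seed: int = 0
    lam: dict = field(default_factory=lambda: dict(DEFAULT_LAMBDA))
    thresholds: dict = field(default_factory=dict)
    intensity: dict = field(default_factory=dict)
    wheat_calendar: dict = field(default_factory=dict)

    def params(self):
        from .pipeline import PipelineParams

        intens = IntensityParams(**{
            k: (np.asarray(v, dtype=float) if k == "scales" else
                tuple(v) if isinstance(v, list) else v)
            for k, v in self.intensity.items()
        })
        thr = ThresholdConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in self.thresholds.items()
        })
        cal = WheatCalendar(**self.wheat_calendar) if self.wheat_calendar else WheatCalendar(120.0, 150.0)
        return PipelineParams(
            lam=dict(DEFAULT_LAMBDA, **self.lam),
            intensity=intens,
            thresholds=thr,
            wheat_calendar=cal,
        )


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration, rejecting unknown keys."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "scene_dir" not in raw or "output_dir" not in raw:
        raise ValueError("config must define scene_dir and output_dir")
    return PipelineConfig(**raw)
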