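"""Spectral indices, Whittaker smoothing, and data-availability classification.

This module converts raw 8-day surface-reflectance composites into daily,
gap-filled EVI2 / LSWI / NMDI trajectories on a common calendar grid.  The
mapping year is processed with a +-90-day pad from the adjacent years so that
winter-crop cycles that straddle the calendar boundary are seen whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solveh_banded

__all__ = [
    "Availability",
    "IndexObservations",
    "IndexSeries",
    "ReflectanceSeries",
    "UnprocessablePixelError",
    "DEFAULT_GRID",
    "GROWING_SEASON",
    "MIN_VALID_OBS",
    "compute_indices",
    "data_availability",
    "smooth_indices",
    "whittaker_smooth",
]

#: Daily day-of-year axis: the mapping year extended by ~90 days on each side.
DEFAULT_GRID = np.arange(-90, 456)

#: Growing season used for the data-availability classes (March 1 - October 31).
GROWING_SEASON = (60, 304)

#: Minimum number of valid composites required to smooth a pixel at all.
MIN_VALID_OBS = 8

# Default roughness weights for the penalised least-squares smoother.  EVI2 and
# LSWI keep enough flexibility to preserve double-cropping bimodality; NMDI is
# smoothed harder because its slope sums (RCPN) are evaluated over a short
# flowering window and must not be dominated by residual observation noise.
DEFAULT_LAMBDA = {"evi2": 500.0, "lswi": 500.0, "nmdi": 8000.0}


class Availability(IntEnum):
    """Valid-observation classes over the growing season (Mar-Oct).

    GOOD (>70 % valid), MEDIUM (50-70 %, both ends inclusive), LOW (<50 %).
    Encoded 1/2/3 in availability rasters.
    """

    GOOD = 1
    MEDIUM = 2
    LOW = 3


class UnprocessablePixelError(ValueError):
    """Raised when a pixel has too few valid observations to smooth."""


@dataclass
class ReflectanceSeries:
    """Per-pixel time-stamped 4-band reflectance with a validity mask.

    Dates are integer day-of-year coordinates relative to the mapping year;
    values outside [1, 365] belong to the padding from adjacent years.
    Each 8-day composite is timestamped at the first day it covers.
    """

    dates: np.ndarray
    rho_red: np.ndarray
    rho_nir: np.ndarray
    rho_swir6: np.ndarray
    rho_swir7: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype=int)
        for name in ("rho_red", "rho_nir", "rho_swir6", "rho_swir7"):
            band = np.asarray(getattr(self, name), dtype=float)
            if band.shape != self.dates.shape:
                raise ValueError(f"{name} length {band.shape} != dates {self.dates.shape}")
            setattr(self, name, band)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.dates.shape:
            raise ValueError("valid mask length does not match dates")
        if np.any(np.diff(self.dates) <= 0):
            raise ValueError("dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.dates)


@dataclass
class IndexObservations:
    """EVI2/LSWI/NMDI sampled at the (valid) composite dates."""

    dates: np.ndarray
    evi2: np.ndarray
    lswi: np.ndarray
    nmdi: np.ndarray
    valid: np.ndarray


@dataclass
class IndexSeries:
    """Daily smoothed index trajectories on the padded calendar grid."""

    grid: np.ndarray
    evi2: np.ndarray
    lswi: np.ndarray
    nmdi: np.ndarray
    availability: Availability = Availability.GOOD
    lam: dict = field(default_factory=lambda: dict(DEFAULT_LAMBDA))


def compute_indices(series: ReflectanceSeries) -> IndexObservations:
    """Compute EVI2, LSWI and NMDI from band reflectances.

    EVI2 = 2.5 (rho_NIR - rho_Red) / (rho_NIR + 2.4 rho_Red + 1)
    LSWI = (rho_NIR - rho_SWIR6) / (rho_NIR + rho_SWIR6)
    NMDI = (rho_NIR - (rho_SWIR6 - rho_SWIR7)) / (rho_NIR + (rho_SWIR6 - rho_SWIR7))

    Dates where a denominator vanishes are flagged invalid rather than raising;
    dates already flagged invalid (cloud) stay invalid.
    """
    nir, red = series.rho_nir, series.rho_red
    s6, s7 = series.rho_swir6, series.rho_swir7

    with np.errstate(divide="ignore", invalid="ignore"):
        d1 = nir + 2.4 * red + 1.0
        evi2 = np.where(d1 != 0, 2.5 * (nir - red) / np.where(d1 == 0, 1, d1), np.nan)
        d2 = nir + s6
        lswi = np.where(d2 != 0, (nir - s6) / np.where(d2 == 0, 1, d2), np.nan)
        diff = s6 - s7
        d3 = nir + diff
        nmdi = np.where(d3 != 0, (nir - diff) / np.where(d3 == 0, 1, d3), np.nan)

    valid = series.valid & np.isfinite(evi2) & np.isfinite(lswi) & np.isfinite(nmdi)
    return IndexObservations(series.dates.copy(), evi2, lswi, nmdi, valid)


@lru_cache(maxsize=8)
def _penalty_bands(n: int) -> np.ndarray:
    """Upper banded form (3 x n) of D'D for second-order differences."""
    D = sp.diags_array([1.0, -2.0, 1.0], offsets=[0, 1, 2], shape=(n - 2, n))
    P = (D.T @ D).todia()
    ab = np.zeros((3, n))
    ab[2] = P.diagonal(0)
    ab[1, 1:] = P.diagonal(1)
    ab[0, 2:] = P.diagonal(2)
    return ab


def whittaker_smooth(
    dates: np.ndarray,
    values: np.ndarray,
    valid: np.ndarray,
    grid: np.ndarray | None = None,
    lam: float = 500.0,
) -> np.ndarray:
    """Penalised least-squares smoothing onto a daily grid.

    Solves (W + lam * D'D) z = W y where W is diagonal with weight 1 at the
    days of valid observations and 0 elsewhere (invalid observations keep the
    grid uniform but contribute nothing), and D takes second differences.

    Parameters
    ----------
    dates, values, valid
        Observation day coordinates, values, and validity flags.
    grid
        Daily target axis; defaults to :data:`DEFAULT_GRID`.
    lam
        Roughness weight (> 0).  Larger means smoother.

    Raises
    ------
    UnprocessablePixelError
        If fewer than :data:`MIN_VALID_OBS` observations are valid.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid)
    dates = np.asarray(dates, dtype=int)
    valid = np.asarray(valid, dtype=bool) & np.isfinite(values)
    if valid.sum() < MIN_VALID_OBS:
        raise UnprocessablePixelError(
            f"only {int(valid.sum())} valid observations; need >= {MIN_VALID_OBS}"
        )

    n = len(grid)
    w = np.zeros(n)
    wy = np.zeros(n)
    pos = np.searchsorted(grid, dates[valid])
    inside = (pos < n) & (grid[np.clip(pos, 0, n - 1)] == dates[valid])
    w[pos[inside]] = 1.0
    wy[pos[inside]] = np.asarray(values, dtype=float)[valid][inside]

    ab = lam * _penalty_bands(n)
    ab = ab.copy()
    ab[2] += w
    return solveh_banded(ab, wy)


def data_availability(
    dates: np.ndarray,
    valid: np.ndarray,
    season: tuple[int, int] = GROWING_SEASON,
) -> Availability:
    """Classify the valid-observation fraction over the growing season.

    f > 0.70 -> GOOD; 0.50 <= f <= 0.70 -> MEDIUM; f < 0.50 -> LOW.
    Both boundary fractions fall in MEDIUM.
    """
    dates = np.asarray(dates)
    lo, hi = season
    in_season = (dates >= lo) & (dates <= hi)
    if not in_season.any():
        raise ValueError(f"no composites inside season window {season}")
    f = np.asarray(valid, dtype=bool)[in_season].mean()
    if f > 0.70:
        return Availability.GOOD
    if f >= 0.50:
        return Availability.MEDIUM
    return Availability.LOW


def smooth_indices(
    series: ReflectanceSeries,
    grid: np.ndarray | None = None,
    lam: dict | None = None,
) -> IndexSeries:
    """Full preprocessing for one pixel: indices, smoothing, availability."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid)
    lam = dict(DEFAULT_LAMBDA, **(lam or {}))
    obs = compute_indices(series)
    channels = {}
    for name in ("evi2", "lswi", "nmdi"):
        channels[name] = whittaker_smooth(
            obs.dates, getattr(obs, name), obs.valid, grid=grid, lam=lam[name]
        )
    avail = data_availability(series.dates, series.valid)
    return IndexSeries(grid, channels["evi2"], channels["lswi"], channels["nmdi"], avail, lam)
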