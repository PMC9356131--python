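"""Phenology metrics and purity-stratified decision rules for rice/wheat/maize.

Per detected growing season three families of metrics are computed from the
daily smoothed index trajectories:

* RCLE (rice)  -- ratio of the LSWI change amplitude to the EVI2 rise between
  tillering and heading.  Flooded paddies keep LSWI high and nearly constant,
  so rice shows a high LSWI minimum with a small RCLE.
* EVE / EVL (wheat) -- EVI2 variation sums over the early (seedling->heading)
  and late (heading->harvest) growth stages, anchored on a heading date and
  early-growing-length predicted by a calendar trend surface.
* RCPN (maize) -- ratio of cumulative positive to negative NMDI slopes across
  the flowering window, scaled by 100; leaf-moisture dynamics give maize a
  rise-then-fall NMDI signature.

Thresholds are stratified by pixel purity: mixing with non-crop background
dilutes the signal, so the mixed strata use laxer cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pattern_codes import Crop
from .intensity import SeasonWindow
from .purity import Stratum

__all__ = [
    "SeasonMetrics",
    "ThresholdConfig",
    "WheatCalendar",
    "classify_season",
    "estimate_wheat_calendar",
    "maize_metrics",
    "rice_metrics",
    "wheat_metrics",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_WHEAT_SURFACES",
]

_STRATA = (Stratum.PURE, Stratum.MODERATE, Stratum.SERIOUS)


@dataclass(frozen=True)
class ThresholdConfig:
    """Decision-rule thresholds; triples are (pure, moderate, serious)."""

    theta1: float = 0.1  # LSWI floor (all strata)
    theta2: tuple[float, float, float] = (0.42, 0.52, 0.62)  # RCLE ceiling
    theta3: tuple[float, float, float] = (0.32, 0.24, 0.16)  # EVE floor
    theta4: float = 0.12  # EVL floor (all strata)
    theta5: tuple[float, float, float] = (0.45, 0.35, 0.25)  # RCPN floor
    sigma: float = 0.05  # RCPN denominator stabiliser

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def column(self, stratum: Stratum) -> dict:
        """Threshold column for one purity stratum."""
        if stratum not in _STRATA:
            raise ValueError(f"no threshold column for stratum {stratum!r}")
        i = _STRATA.index(stratum)
        return {
            "theta1": self.theta1,
            "theta2": self.theta2[i],
            "theta3": self.theta3[i],
            "theta4": self.theta4,
            "theta5": self.theta5[i],
        }


DEFAULT_THRESHOLDS = ThresholdConfig()


@dataclass
class SeasonMetrics:
    """Metric values for one season; ``None`` marks a metric whose rule is
    not applicable (e.g. wheat outside its calendar window, undefined RCLE)."""

    lswi_min: float | None = None
    lswi_max: float | None = None
    rcle: float | None = None
    eve: float | None = None
    evl: float | None = None
    rcpn: float | None = None


@dataclass(frozen=True)
class WheatCalendar:
    """Predicted wheat phenology at a site: heading day-of-year and the
    length (days) of the early growth stage (seedling to heading)."""

    heading_doy: float
    early_growing_length: float
    wheat_type: str = "winter"  # winter | spring

    def __post_init__(self):
        if self.early_growing_length <= 0:
            raise ValueError("early_growing_length must be positive")
        if self.wheat_type not in ("winter", "spring"):
            raise ValueError("wheat_type must be 'winter' or 'spring'")


def _at(grid: np.ndarray, values: np.ndarray, day: float) -> float:
    return float(np.interp(day, grid, values))


def rice_metrics(
    grid: np.ndarray,
    lswi: np.ndarray,
    evi2: np.ndarray,
    window: SeasonWindow,
) -> tuple[float, float, float] | None:
    """(LSWI_min, LSWI_max, RCLE) over the tillering->heading window.

    Returns ``None`` when the EVI2 rise is non-positive, in which case the
    ratio is undefined and the season cannot be rice.
    """
    grid = np.asarray(grid)
    sel = (grid >= window.tillering_doy) & (grid <= window.heading_doy)
    if not sel.any():
        return None
    rise = _at(grid, evi2, window.heading_doy) - _at(grid, evi2, window.tillering_doy)
    if rise <= 0:
        return None
    lswi_min = float(np.min(lswi[sel]))
    lswi_max = float(np.max(lswi[sel]))
    return lswi_min, lswi_max, (lswi_max - lswi_min) / rise


def wheat_metrics(
    grid: np.ndarray,
    evi2: np.ndarray,
    calendar: WheatCalendar,
    harvest_doy: float,
) -> tuple[float, float] | None:
    """(EVE, EVL) around the calendar-predicted heading date.

    EVE = (EVI2_heading - EVI2_seedling) + (EVI2_max1 - EVI2_min1) over the
    early stage [seedling, heading]; EVL = (EVI2_heading - EVI2_harvest) +
    (EVI2_max2 - EVI2_min2) over the late stage [heading, harvest].
    Returns ``None`` if either stage extends beyond the series span.
    """
    grid = np.asarray(grid)
    heading = calendar.heading_doy
    seedling = heading - calendar.early_growing_length
    if seedling < grid[0] or harvest_doy > grid[-1] or harvest_doy <= heading:
        return None
    early = (grid >= seedling) & (grid <= heading)
    late = (grid >= heading) & (grid <= harvest_doy)
    e_head = _at(grid, evi2, heading)
    eve = (e_head - _at(grid, evi2, seedling)) + (np.max(evi2[early]) - np.min(evi2[early]))
    evl = (e_head - _at(grid, evi2, harvest_doy)) + (np.max(evi2[late]) - np.min(evi2[late]))
    return float(eve), float(evl)


def maize_metrics(
    grid: np.ndarray,
    nmdi: np.ndarray,
    flowering_window: tuple[float, float],
    sigma: float = DEFAULT_THRESHOLDS.sigma,
) -> float:
    """RCPN over the flowering window, split at its midpoint.

    RCPN = (P_early + P_late) * N_late / (N_early + N_late + sigma) * 100,
    where P/N are the sums of positive / absolute negative day-to-day NMDI
    differences in each half.  A flat series yields 0.
    """
    lo, hi = flowering_window
    if hi <= lo:
        raise ValueError("flowering window must be non-empty")
    grid = np.asarray(grid)
    sel = (grid >= lo) & (grid <= hi)
    w = np.asarray(nmdi, dtype=float)[sel]
    if len(w) < 3:
        return 0.0
    d = np.diff(w)
    k = len(w) // 2  # first half gets diffs 0..k-1
    de, dl = d[:k], d[k:]
    p = de[de > 0].sum() + dl[dl > 0].sum()
    n_early = -de[de < 0].sum()
    n_late = -dl[dl < 0].sum()
    return float(p * n_late / (n_early + n_late + sigma) * 100.0)


#: Planar trend-surface coefficients (intercept, coef1, coef2) fitted to the
#: synthetic scenes' declared calendar: intercept-only by default, i.e. every
#: site heads at DOY 120 (winter) / 170 (spring).  Predictors are
#: (latitude, altitude) for winter wheat and (latitude, accumulated
#: temperature above 5 C) for spring wheat.
DEFAULT_WHEAT_SURFACES = {
    "winter": {"heading": (120.0, 0.0, 0.0), "egl": (150.0, 0.0, 0.0),
               "domain": ((20.0, 45.0), (0.0, 3000.0))},
    "spring": {"heading": (170.0, 0.0, 0.0), "egl": (90.0, 0.0, 0.0),
               "domain": ((35.0, 50.0), (0.0, 4000.0))},
}


def estimate_wheat_calendar(
    latitude: float,
    altitude_or_accum_temp: float,
    wheat_type: str = "winter",
    surfaces: dict | None = None,
) -> WheatCalendar:
    """Evaluate the planar calendar trend surface at a site.

    ``heading_doy = a0 + a1 * latitude + a2 * predictor2`` and likewise for
    the early-growing length, where predictor2 is altitude (winter wheat) or
    accumulated temperature above 5 C (spring wheat).  Out-of-domain
    predictors are clamped to the configured domain with a warning.
    """
    import warnings

    surfaces = surfaces or DEFAULT_WHEAT_SURFACES
    if wheat_type not in surfaces:
        raise ValueError(f"wheat_type must be one of {sorted(surfaces)}")
    surf = surfaces[wheat_type]
    (lat_lo, lat_hi), (p2_lo, p2_hi) = surf["domain"]
    lat, p2 = latitude, altitude_or_accum_temp
    if not lat_lo <= lat <= lat_hi or not p2_lo <= p2 <= p2_hi:
        warnings.warn("predictors outside configured domain; clamped", stacklevel=2)
        lat = float(np.clip(lat, lat_lo, lat_hi))
        p2 = float(np.clip(p2, p2_lo, p2_hi))
    a = surf["heading"]
    b = surf["egl"]
    return WheatCalendar(
        heading_doy=a[0] + a[1] * lat + a[2] * p2,
        early_growing_length=b[0] + b[1] * lat + b[2] * p2,
        wheat_type=wheat_type,
    )


def classify_season(
    metrics: SeasonMetrics,
    stratum: Stratum,
    thresholds: ThresholdConfig = DEFAULT_THRESHOLDS,
    return_details: bool = False,
):
    """Apply the stratified decision rules to one season's metrics.

    Rules (with the stratum's threshold column): rice if LSWI_min > theta1 and
    RCLE < theta2; wheat if EVE > theta3 and EVL > theta4; maize if
    RCPN > theta5.  When several rules fire the label with the largest
    relative margin ``(metric - threshold) / threshold`` wins (for rice and
    wheat the smaller of their two condition margins), with the deterministic
    ordering rice -> wheat -> maize on exact ties.  No rule fired -> other.
    """
    col = thresholds.column(stratum)
    margins: dict[Crop, float] = {}

    if metrics.lswi_min is not None and metrics.rcle is not None:
        if metrics.lswi_min > col["theta1"] and metrics.rcle < col["theta2"]:
            margins[Crop.RICE] = min(
                (metrics.lswi_min - col["theta1"]) / col["theta1"],
                (col["theta2"] - metrics.rcle) / col["theta2"],
            )
    if metrics.eve is not None and metrics.evl is not None:
        if metrics.eve > col["theta3"] and metrics.evl > col["theta4"]:
            margins[Crop.WHEAT] = min(
                (metrics.eve - col["theta3"]) / col["theta3"],
                (metrics.evl - col["theta4"]) / col["theta4"],
            )
    if metrics.rcpn is not None and metrics.rcpn > col["theta5"]:
        margins[Crop.MAIZE] = (metrics.rcpn - col["theta5"]) / col["theta5"]

    if not margins:
        label = Crop.OTHER
    else:
        best = max(margins.values())
        # deterministic tie-break follows dict insertion order rice->wheat->maize
        label = next(c for c, m in margins.items() if m == best)
    return (label, margins) if return_details else label
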