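"""Cropping-intensity detection from wavelet spectra of daily EVI2.

The number of growing cycles per year (0-3) is read off the continuous
Mexican-hat wavelet transform of the mean-centred daily EVI2 trajectory.
Three features identify a genuine crop cycle: a strong brightness centre
(local power maximum), a wide enough time skeleton at the centre's scale, and
a scale interval intersecting the plausible crop-season band.  Centres are
attributed to the mapping year by their day (winter-wheat cycles straddling
the year boundary count for the year of their heading date).

The Mexican hat is real and symmetric, suited to bump detection; its peak
response occurs at a scale of roughly half the cycle length, hence the
season-length conversion ``days ~ 2 x scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage
from scipy.signal import find_peaks

__all__ = [
    "IntensityParams",
    "SeasonWindow",
    "WaveletCenter",
    "WaveletFeatures",
    "cropping_index",
    "segment_seasons",
    "wavelet_spectrum",
]


@dataclass(frozen=True)
class IntensityParams:
    """Declared, configurable constants of the intensity detector."""

    scales: np.ndarray = field(default_factory=lambda: np.arange(30.0, 241.0, 5.0))
    rel_power_threshold: float = 0.2
    min_skeleton_days: float = 30.0
    season_band_days: tuple[float, float] = (60.0, 200.0)
    scale_to_days: float = 2.0  # season length ~ 2 x mexh scale
    merge_days: float = 45.0  # twin peaks of one stressed crop merge
    min_amplitude: float = 0.18  # fallow floor on the annual EVI2 range
    year_span: tuple[int, int] = (1, 365)


@dataclass
class WaveletCenter:
    """A strong brightness centre of the wavelet power spectrum."""

    day: int
    scale: float
    power: float
    skeleton_days: float
    scale_interval: tuple[float, float]


@dataclass
class WaveletFeatures:
    """Wavelet power matrix with its detected centres."""

    days: np.ndarray
    scales: np.ndarray
    power: np.ndarray  # (scale, time)
    centers: list  # of WaveletCenter, sorted by day
    series_range: float  # in-year EVI2 max - min (fallow floor check)


def wavelet_spectrum(
    grid: np.ndarray, evi2: np.ndarray, params: IntensityParams | None = None
) -> WaveletFeatures:
    """Mexican-hat CWT of the mean-centred daily EVI2 with centre detection.

    Brightness centres are 2-D local maxima of the positive wavelet response
    exceeding ``rel_power_threshold`` times the global maximum (troughs give
    negative response and never qualify).  An all-constant series yields zero
    centres.  Centres closer than ``merge_days`` keep only the strongest.
    """
    params = params or IntensityParams()
    grid = np.asarray(grid)
    evi2 = np.asarray(evi2, dtype=float)
    if not np.all(np.isfinite(evi2)):
        raise ValueError("EVI2 series contains non-finite values")

    coef, _ = pywt.cwt(evi2 - evi2.mean(), params.scales, "mexh")
    in_year = (grid >= params.year_span[0]) & (grid <= params.year_span[1])
    series_range = float(np.ptp(evi2[in_year])) if in_year.any() else float(np.ptp(evi2))

    pmax = coef.max()
    centers: list[WaveletCenter] = []
    if pmax > 1e-9:  # an (all-but-)constant series has no centres
        thresh = params.rel_power_threshold * pmax
        local_max = (ndimage.maximum_filter(coef, size=3, mode="nearest") == coef)
        cand = np.argwhere(local_max & (coef > thresh))
        # strongest-first greedy merge of centres closer than merge_days;
        # only centres of comparable scale merge (a twin peak of one stressed
        # crop), never a cycle centre with the large-scale annual envelope
        cand = cand[np.argsort(coef[cand[:, 0], cand[:, 1]])[::-1]]
        kept: list[tuple[int, int]] = []
        for si, ti in cand:
            close = (
                abs(grid[ti] - grid[tj]) < params.merge_days
                and max(params.scales[si], params.scales[sj])
                <= 2.0 * min(params.scales[si], params.scales[sj])
                for sj, tj in kept
            )
            if not any(close):
                kept.append((si, ti))
        for si, ti in kept:
            row = coef[si]
            above = row > thresh
            left = ti
            while left > 0 and above[left - 1]:
                left -= 1
            right = ti
            while right < len(row) - 1 and above[right + 1]:
                right += 1
            skeleton = float(grid[right] - grid[left] + 1)
            col_above = coef[:, ti] > thresh
            lo = si
            while lo > 0 and col_above[lo - 1]:
                lo -= 1
            hi = si
            while hi < len(params.scales) - 1 and col_above[hi + 1]:
                hi += 1
            centers.append(
                WaveletCenter(
                    day=int(grid[ti]),
                    scale=float(params.scales[si]),
                    power=float(coef[si, ti]),
                    skeleton_days=skeleton,
                    scale_interval=(float(params.scales[lo]), float(params.scales[hi])),
                )
            )
        centers.sort(key=lambda c: c.day)
    return WaveletFeatures(grid, params.scales, coef, centers, series_range)


def cropping_index(
    features: WaveletFeatures, params: IntensityParams | None = None
) -> int:
    """Count growing cycles (0-3) from the wavelet features.

    A centre counts when (i) its day falls inside the mapping year, (ii) its
    skeleton is at least ``min_skeleton_days`` wide, and (iii) its scale and
    scale interval, converted to season length, fall in / intersect the
    crop-season band.  Criterion (iii) is what rejects the large-scale
    "annual envelope" centre that multi-cropping profiles produce between
    their cycles.  A pixel whose in-year EVI2 range is below
    ``min_amplitude`` is fallow.  The count is capped at 3 (triple cropping).
    """
    params = params or IntensityParams()
    if features.series_range < params.min_amplitude:
        return 0
    lo_band, hi_band = params.season_band_days
    n = 0
    for c in features.centers:
        if not params.year_span[0] <= c.day <= params.year_span[1]:
            continue
        if c.skeleton_days < params.min_skeleton_days:
            continue
        if not lo_band <= c.scale * params.scale_to_days <= hi_band:
            continue
        s_lo, s_hi = c.scale_interval
        if s_lo * params.scale_to_days > hi_band or s_hi * params.scale_to_days < lo_band:
            continue
        n += 1
    return min(n, 3)


@dataclass
class SeasonWindow:
    """One detected growing cycle with its key phenological dates."""

    start_doy: int
    tillering_doy: int
    heading_doy: int
    harvest_doy: int
    amplitude: float

    def __post_init__(self):
        if not self.start_doy < self.tillering_doy < self.heading_doy < self.harvest_doy:
            raise ValueError("season dates must satisfy start < tillering < heading < harvest")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


def segment_seasons(
    grid: np.ndarray,
    evi2: np.ndarray,
    intensity: int,
    params: IntensityParams | None = None,
) -> list[SeasonWindow]:
    """Split the year into one window per growing cycle.

    The ``intensity`` most prominent in-year EVI2 peaks become heading dates
    (plateaus resolve to their earliest day).  Relative to each cycle's local
    baseline (the series minimum between neighbouring peaks), the start /
    harvest dates are the 10 %-of-amplitude crossings on the rising / falling
    flank and the tillering date is the 30 % crossing on the rising flank.
    Windows are clipped at inter-peak minima so they never overlap.
    """
    params = params or IntensityParams()
    if intensity < 1:
        return []
    grid = np.asarray(grid)
    evi2 = np.asarray(evi2, dtype=float)

    # plateau maxima resolve to their earliest day (left edge)
    peaks, props = find_peaks(evi2, prominence=1e-6, plateau_size=1)
    peaks = props["left_edges"]
    in_year = (grid[peaks] >= params.year_span[0]) & (grid[peaks] <= params.year_span[1])
    peaks, prom = peaks[in_year], props["prominences"][in_year]
    # keep the `intensity` most prominent peaks at least merge_days apart
    order = np.argsort(prom)[::-1]
    chosen: list[int] = []  # day values
    for i in order:
        day = int(grid[peaks[i]])
        if all(abs(day - d) >= params.merge_days for d in chosen):
            chosen.append(day)
        if len(chosen) == intensity:
            break
    chosen.sort()

    windows: list[SeasonWindow] = []
    idx_of = {int(d): int(np.searchsorted(grid, d)) for d in chosen}
    for k, day in enumerate(chosen):
        pi = idx_of[day]
        left_lim = idx_of[chosen[k - 1]] if k > 0 else 0
        right_lim = idx_of[chosen[k + 1]] if k < len(chosen) - 1 else len(grid) - 1
        li = left_lim + int(np.argmin(evi2[left_lim : pi + 1]))
        ri = pi + int(np.argmin(evi2[pi : right_lim + 1]))
        base = min(evi2[li], evi2[ri])
        peak_val = evi2[pi]
        amp = peak_val - base
        if amp <= 0:
            continue

        def crossing(level: float, lo: int, hi: int, rising: bool) -> int:
            seg = evi2[lo : hi + 1]
            below = seg <= level
            if rising:
                idx = np.nonzero(below)[0]
                return lo + (idx[-1] if len(idx) else 0)
            idx = np.nonzero(below)[0]
            return lo + (idx[0] if len(idx) else len(seg) - 1)

        start_i = crossing(base + 0.10 * amp, li, pi, rising=True)
        till_i = crossing(base + 0.30 * amp, li, pi, rising=True)
        harv_i = crossing(base + 0.10 * amp, pi, ri, rising=False)
        # enforce strict ordering on degenerate flanks
        start_i = min(start_i, pi - 2)
        till_i = int(np.clip(till_i, start_i + 1, pi - 1))
        harv_i = max(harv_i, pi + 1)
        windows.append(
            SeasonWindow(
                start_doy=int(grid[start_i]),
                tillering_doy=int(grid[till_i]),
                heading_doy=int(day),
                harvest_doy=int(grid[harv_i]),
                amplitude=float(amp),
            )
        )
    return windows
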