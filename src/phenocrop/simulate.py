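"""Seeded synthetic generator of MODIS-like reflectance scenes with known truth.

The generator works in index space and back-solves band reflectances, so the
simulated pixels enter the pipeline through the same band-level door as real
data.  Per crop cycle the EVI2 trajectory is a double logistic; LSWI and NMDI
are coupled to EVI2 with crop-specific signatures layered on top:

* rice      -- surface flooding keeps LSWI at/above ``flood_lswi_level`` from
               transplanting to heading, so its tillering->heading LSWI range
               is small relative to the EVI2 rise (small RCLE);
* maize     -- leaf-moisture dynamics during flowering produce an NMDI rise of
               ``nmdi_flowering_rise`` followed by a symmetric fall;
* winter wheat -- autumn growth, a winter dormancy trough crossing the year
               boundary, spring green-up peaking at heading.

Band back-solve (one consistent solution; exact round trip through the index
formulas): rho_NIR = 0.2 + 0.5 EVI2, then Red from the EVI2 equation, SWIR6
from LSWI, and SWIR7 from NMDI.  Mixed pixels are linear per-band mixtures of
the crop endmember and a constant non-crop background endmember
(EVI2 0.15, LSWI 0.0, NMDI 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pattern_codes import PATTERN_NAMES, Crop, decode_pattern
from .preprocess import DEFAULT_GRID, ReflectanceSeries

__all__ = [
    "BACKGROUND_INDICES",
    "COMPOSITE_DATES",
    "CropCycleParams",
    "DEFAULT_CYCLES",
    "Scene",
    "SceneConfig",
    "crop_index_trajectories",
    "demo_pattern_map",
    "indices_to_bands",
    "simulate_pixel",
    "simulate_scene",
]

#: 8-day composite start days covering the padded mapping year.  Composite i
#: covers DOY 8(i-1)+1 .. 8i and is timestamped at its first day; in-year
#: composites start at DOY 1, 9, ..., 361 (46 per year).
COMPOSITE_DATES = np.arange(-87, 450, 8)

#: Constant non-crop endmember (other vegetation / soil) in index space.
BACKGROUND_INDICES = (0.15, 0.0, 0.6)

#: EVI2 floor of the crop endmember outside growing cycles.
CROP_BASE_EVI2 = 0.12

# Index couplings of the crop endmember (calibrated once; see docs/methods.md).
_LSWI_SLOPE, _LSWI_OFFSET = 0.5, -0.12
_NMDI_BASE, _NMDI_SLOPE = 0.6, 0.10
_RICE_LSWI_EVI2_GAIN = 0.08
_RICE_DRAIN_DAYS = 30
_RICE_FLOOD_LEAD = 15  # paddies are inundated before transplanting
_MAIZE_BUMP_HALFWIDTH = 32
_WHEAT_AUTUMN_REL_AMP = 0.25


@dataclass(frozen=True)
class CropCycleParams:
    """One growing cycle of one crop.

    Day-of-year coordinates are relative to the mapping year and may be
    negative for cycles sown in the preceding autumn (winter wheat).
    ``evi2_amplitude`` should stay within (0, 0.9] so that the band
    back-solve keeps all reflectances inside [0, 1].
    """

    crop: str  # rice | wheat_winter | wheat_spring | maize | other
    sowing_doy: int
    peak_doy: int
    season_length: int
    evi2_amplitude: float
    flood_lswi_level: float = 0.30  # rice only
    nmdi_flowering_rise: float = 0.35  # maize only

    def __post_init__(self):
        if self.crop not in ("rice", "wheat_winter", "wheat_spring", "maize", "other"):
            raise ValueError(f"unknown crop {self.crop!r}")
        if not self.sowing_doy < self.peak_doy:
            raise ValueError("sowing_doy must precede peak_doy")
        if not 0 < self.evi2_amplitude < 1:
            raise ValueError("evi2_amplitude must lie in (0, 1)")
        if self.season_length <= 0:
            raise ValueError("season_length must be positive")

    @property
    def harvest_doy(self) -> int:
        return self.sowing_doy + self.season_length

    @property
    def pattern_crop(self) -> Crop:
        if self.crop in ("wheat_winter", "wheat_spring"):
            return Crop.WHEAT
        return Crop(self.crop)


@dataclass
class SceneConfig:
    """Configuration of a whole synthetic scene."""

    n_rows: int
    n_cols: int
    pattern_map: np.ndarray
    purity_map: np.ndarray
    noise_sd: float = 0.0
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.pattern_map = np.asarray(self.pattern_map)
        self.purity_map = np.asarray(self.purity_map, dtype=float)
        shape = (self.n_rows, self.n_cols)
        if self.pattern_map.shape != shape or self.purity_map.shape != shape:
            raise ValueError("pattern_map / purity_map shape must match n_rows x n_cols")
        bad = ~np.isin(self.pattern_map, list(PATTERN_NAMES))
        if bad.any():
            cells = [(int(r), int(c)) for r, c in zip(*np.nonzero(bad))]
            raise ValueError(f"invalid pattern codes at cells {cells[:20]}")
        if np.any((self.purity_map < 0) | (self.purity_map > 1)):
            raise ValueError("purity_map values must lie in [0, 1]")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must lie in [0, 1)")


@dataclass
class Scene:
    """A simulated raster stack plus its ground truth."""

    dates: np.ndarray  # (T,)
    reflectance: np.ndarray  # (T, 4, rows, cols): red, nir, swir6, swir7
    valid: np.ndarray  # (T, rows, cols) bool
    truth: np.ndarray  # (rows, cols) pattern codes
    config: SceneConfig

    def pixel(self, row: int, col: int) -> ReflectanceSeries:
        b = self.reflectance[:, :, row, col]
        return ReflectanceSeries(
            self.dates, b[:, 0], b[:, 1], b[:, 2], b[:, 3], self.valid[:, row, col]
        )


# --- default cycle library -------------------------------------------------
# Sowing / peak (heading) / season-length choices follow typical calendars of
# the studied cropping systems: winter wheat heads around DOY 120, single
# summer crops peak around DOY 190-215, double-cropping seasons split the year
# around DOY 160/270, triple cropping squeezes three short cycles in.

def _rice(sow, peak, length, amp=0.55):
    return CropCycleParams("rice", sow, peak, length, amp)


def _maize(sow, peak, length, amp=0.60):
    return CropCycleParams("maize", sow, peak, length, amp)


def _wwheat(amp=0.50):
    return CropCycleParams("wheat_winter", -80, 120, 240, amp)


def _other(sow, peak, length, amp=0.50):
    return CropCycleParams("other", sow, peak, length, amp)


DEFAULT_CYCLES: dict[int, tuple[CropCycleParams, ...]] = {
    0: (),
    14: (_maize(130, 200, 140),),
    15: (_rice(140, 210, 130),),
    16: (_wwheat(),),
    17: (_other(130, 190, 120),),
    245: (_rice(100, 162, 105, amp=0.50), _maize(210, 270, 108, amp=0.55)),
    246: (_wwheat(), _maize(165, 225, 115, amp=0.55)),
    255: (_rice(95, 165, 115, amp=0.50), _rice(215, 277, 110, amp=0.50)),
    256: (_wwheat(), _rice(170, 235, 115, amp=0.50)),
    277: (_other(105, 165, 110), _other(225, 285, 105)),
    3: (_other(20, 75, 95, amp=0.45), _other(135, 190, 95, amp=0.45),
        _other(245, 300, 95, amp=0.45)),
}


def _bump(t: np.ndarray, sow: float, peak: float, harvest: float) -> np.ndarray:
    """Double-logistic bump normalised to max 1, peaking near ``peak``."""
    r_on = max((peak - sow) / 6.0, 3.0)
    r_off = max((harvest - peak) / 6.0, 3.0)
    g = 1.0 / (1.0 + np.exp(-(t - (sow + peak) / 2.0) / r_on))
    g *= 1.0 / (1.0 + np.exp((t - (peak + harvest) / 2.0) / r_off))
    return g / g.max()


def _cycle_evi2(grid: np.ndarray, c: CropCycleParams) -> np.ndarray:
    """EVI2 contribution (above base) of one cycle."""
    if c.crop == "wheat_winter":
        # autumn establishment bump, dormancy trough, spring main bump
        autumn_peak = c.sowing_doy + 50
        dormancy = c.sowing_doy + 105
        autumn = _WHEAT_AUTUMN_REL_AMP * c.evi2_amplitude * _bump(
            grid, c.sowing_doy, autumn_peak, dormancy
        )
        spring = c.evi2_amplitude * _bump(grid, c.peak_doy - 80, c.peak_doy, c.harvest_doy)
        return np.maximum(autumn, spring)
    return c.evi2_amplitude * _bump(grid, c.sowing_doy, c.peak_doy, c.harvest_doy)


def crop_index_trajectories(
    cycles, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Daily (EVI2, LSWI, NMDI) trajectories of the pure crop endmember."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid)
    contribs = [_cycle_evi2(grid, c) for c in cycles]
    evi2 = CROP_BASE_EVI2 + (np.max(contribs, axis=0) if contribs else np.zeros(len(grid)))

    lswi = _LSWI_SLOPE * evi2 + _LSWI_OFFSET
    for c in cycles:
        if c.crop != "rice":
            continue
        flood_track = c.flood_lswi_level + _RICE_LSWI_EVI2_GAIN * (evi2 - CROP_BASE_EVI2)
        w = np.zeros(len(grid))
        w[(grid >= c.sowing_doy - _RICE_FLOOD_LEAD) & (grid <= c.peak_doy)] = 1.0
        drain = (grid > c.peak_doy) & (grid <= c.peak_doy + _RICE_DRAIN_DAYS)
        w[drain] = 1.0 - (grid[drain] - c.peak_doy) / _RICE_DRAIN_DAYS
        lswi = np.maximum(lswi, lswi + w * (flood_track - lswi))

    nmdi = _NMDI_BASE - _NMDI_SLOPE * (evi2 - CROP_BASE_EVI2)
    for c in cycles:
        if c.crop != "maize":
            continue
        tri = np.clip(1.0 - np.abs(grid - c.peak_doy) / _MAIZE_BUMP_HALFWIDTH, 0.0, None)
        nmdi = nmdi + c.nmdi_flowering_rise * tri
    return evi2, lswi, nmdi


def indices_to_bands(evi2, lswi, nmdi) -> tuple[np.ndarray, ...]:
    """Back-solve (red, nir, swir6, swir7) reflectances from index values.

    Exact inverse of the index formulas given the closure rho_NIR =
    0.2 + 0.5 EVI2; requires NMDI >= LSWI so that SWIR7 stays non-negative
    (always true for the documented parameter ranges).
    """
    evi2 = np.asarray(evi2, dtype=float)
    nir = 0.2 + 0.5 * evi2
    red = (nir * (2.5 - evi2) - evi2) / (2.5 + 2.4 * evi2)
    s6 = nir * (1.0 - lswi) / (1.0 + lswi)
    s7 = s6 - nir * (1.0 - nmdi) / (1.0 + nmdi)
    return red, nir, s6, s7


_BACKGROUND_BANDS = indices_to_bands(*BACKGROUND_INDICES)


def _check_cycles(pattern: int, cycles) -> None:
    intensity, crops, _ = decode_pattern(pattern)
    if len(cycles) != intensity:
        raise ValueError(
            f"pattern {pattern} implies {intensity} cycle(s) but {len(cycles)} given"
        )
    if crops:  # codes 0 and 3 carry no composition
        given = sorted(c.pattern_crop.value for c in cycles)
        wanted = sorted(c.value for c in crops.elements())
        if given != wanted:
            raise ValueError(
                f"cycle crops {given} do not match pattern {pattern} composition {wanted}"
            )


def simulate_pixel(
    pattern: int,
    cycles=None,
    purity: float = 1.0,
    noise_sd: float = 0.0,
    gap_rate: float = 0.0,
    seed=0,
    dates: np.ndarray | None = None,
) -> ReflectanceSeries:
    """Simulate the 8-day 4-band reflectance series of one pixel.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.  The pixel
    is a linear per-band mixture ``purity * crop + (1 - purity) * background``
    before i.i.d. Gaussian noise (sd in reflectance units, clipped to [0, 1])
    and Bernoulli cloud gaps are applied.
    """
    if cycles is None:
        cycles = DEFAULT_CYCLES[int(pattern)]
    _check_cycles(int(pattern), cycles)
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must lie in [0, 1]")
    dates = COMPOSITE_DATES if dates is None else np.asarray(dates)

    evi2, lswi, nmdi = crop_index_trajectories(cycles, grid=dates)
    bands = np.stack(indices_to_bands(evi2, lswi, nmdi))  # (4, T)
    bg = np.asarray(_BACKGROUND_BANDS).reshape(4, 1)
    mixed = purity * bands + (1.0 - purity) * bg

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    valid = rng.random(len(dates)) >= gap_rate
    if noise_sd > 0:
        mixed = mixed + rng.normal(0.0, noise_sd, mixed.shape)
    mixed = np.clip(mixed, 0.0, 1.0)
    return ReflectanceSeries(dates, mixed[0], mixed[1], mixed[2], mixed[3], valid)


def simulate_scene(config: SceneConfig) -> Scene:
    """Simulate a whole scene; per-pixel sub-seeds derive from (seed, row, col)."""
    dates = COMPOSITE_DATES
    T = len(dates)
    refl = np.empty((T, 4, config.n_rows, config.n_cols))
    valid = np.empty((T, config.n_rows, config.n_cols), dtype=bool)
    for r in range(config.n_rows):
        for c in range(config.n_cols):
            series = simulate_pixel(
                int(config.pattern_map[r, c]),
                purity=float(config.purity_map[r, c]),
                noise_sd=config.noise_sd,
                gap_rate=config.gap_rate,
                seed=np.random.SeedSequence([int(config.seed), r, c]),
            )
            refl[:, 0, r, c] = series.rho_red
            refl[:, 1, r, c] = series.rho_nir
            refl[:, 2, r, c] = series.rho_swir6
            refl[:, 3, r, c] = series.rho_swir7
            valid[:, r, c] = series.valid
    return Scene(dates, refl, valid, config.pattern_map.copy(), config)


def demo_pattern_map(n_rows: int, n_cols: int, codes=None) -> np.ndarray:
    """Deterministic pattern raster cycling through the code vocabulary."""
    codes = np.asarray(sorted(PATTERN_NAMES) if codes is None else codes)
    idx = np.arange(n_rows * n_cols) % len(codes)
    return codes[idx].reshape(n_rows, n_cols)
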