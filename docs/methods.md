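# Methods

This note documents the models, the tunable constants with their defaults and
rationale, the synthetic-data design, the numerical choices, and the known
limitations of the package.

## Scope and data model

The pipeline maps one calendar year per pixel from 8-day, 4-band
surface-reflectance composites (red, NIR, SWIR ~1640 nm, SWIR ~2130 nm) with
a validity (cloud) mask.  Composite *i* covers days 8(i−1)+1 … 8i and is
timestamped at its first day, so an unpadded year holds 46 composites.  All
processing uses a daily day-of-year axis from −90 to +455: winter wheat is
sown in the preceding autumn and the pad lets its whole cycle be observed.
Cycles that straddle the year boundary are attributed to the year of their
heading date.

## Preprocessing

EVI2, LSWI and NMDI are computed per valid composite; a vanishing denominator
flags that date invalid rather than raising.  Each index is smoothed onto the
daily grid with a Whittaker smoother, (W + λ DᵀD) z = W y, W diagonal with
weight 1 at valid observation days and 0 elsewhere (gaps keep the grid
uniform so D is constant), D the second-difference operator.  The system is
pentadiagonal and solved with a banded Cholesky factorisation.

λ defaults: **EVI2 500, LSWI 500, NMDI 8000** (unitless roughness weights on
the daily grid).  500 keeps the bimodal/trimodal structure of multiple
cropping while suppressing composite-level noise; a 46-point annual profile
smoothed at λ = 500 loses under 1 % of a 120-day cycle's amplitude.  NMDI is
smoothed an order of magnitude harder because the maize statistic (RCPN)
sums day-to-day slopes over a short flowering window and is therefore far
more sensitive to residual noise than any peak-level statistic; at λ = 8000 a
~60-day flowering bump still passes at roughly half amplitude, which the
rule thresholds accommodate.

Fewer than 8 valid observations makes a pixel unprocessable; it is emitted
with the reserved no-data code and an explicit reason, never dropped.  The
data-availability class uses the March–October growing season (day-of-year
60–304): >70 % valid → class 1 (good), 50–70 % inclusive → 2 (medium),
<50 % → 3 (low).  Low availability does not block classification — it is a
reliability flag for the map user.

## Cropping intensity

The detector works on the Mexican-hat continuous wavelet transform of the
mean-centred daily EVI2 (scales 30–240 days in steps of 5).  The Mexican hat
is real and symmetric and responds maximally to an isolated bump at a scale
of about half the bump's length; the empirical peak-response calibration on
double-logistic cycles of 80–140 days gave season_length ≈ 2.05 × scale, so
the scale → season-length conversion factor is fixed at 2.

A growing cycle is a **strong brightness centre**: a 2-D local maximum of the
positive wavelet response above 0.2 × the global maximum, whose time skeleton
(contiguous above-threshold ridge at the centre's scale) spans at least 30
days, whose day falls inside the mapping year, and whose scale and scale
interval map into / intersect the 60–200-day crop-season band.  The band
criterion is what rejects the large-scale "annual envelope" centre that any
multi-cropping profile produces between its cycles.  Centres closer than 45
days merge (twin peaks of a single stressed crop), but only when their scales
agree within a factor of two — the envelope centre sits at several times the
cycle scale and must never swallow a genuine mid-year cycle centre.  A pixel
whose in-year EVI2 range is below **0.18** is fallow; intensity is capped
at 3.  The fallow floor is 0.03 above the smallest crop signal the simulator
emits at the lowest admissible purity, and above the in-year range that
smoothing residue reaches on non-crop pixels at the documented noise level.

Season windows: the *k* most prominent in-year daily-EVI2 peaks (≥45 days
apart; plateaus resolve to their earliest day) become heading dates; each
cycle's local baseline is the series minimum towards its neighbours, and the
10 % / 30 % amplitude crossings on the rising flank give the start and
tillering dates, the 10 % crossing on the falling flank the harvest date.
Windows are clipped at inter-peak minima and never overlap.

## Crop rules

Thresholds (pure / moderate / serious): θ₂ = 0.42 / 0.52 / 0.62 (RCLE
ceiling), θ₃ = 0.32 / 0.24 / 0.16 (EVE floor), θ₅ = 0.45 / 0.35 / 0.25
(RCPN floor), θ₁ = 0.1 (LSWI floor), θ₄ = 0.12 (EVL floor).  Mixing with
non-crop background dilutes index dynamics, so the mixed strata are laxer;
the triples are nested, which the tests verify as a monotone-containment
property.  Purity strata: pure >0.90, moderate 0.50–0.90 (both boundaries
inclusive), serious 0.30–0.50 (0.30 inclusive), excluded <0.30 — excluded
pixels carry a reserved no-data code so rasters stay aligned.

* **Rice** (tillering→heading window from the season segmentation): RCLE is
  undefined when the EVI2 rise is non-positive; such seasons cannot be rice.
* **Wheat**: heading date and early-growing length come from a planar
  calendar trend surface — heading = a₀ + a₁·latitude + a₂·altitude for
  winter wheat, with accumulated temperature above 5 °C replacing altitude
  for spring wheat.  The default surfaces are intercept-only (heading DOY
  120 / 170, early growing length 150 / 90 days for winter / spring),
  matching the synthetic scenes' declared calendar; coefficients are
  configurable for real deployments.  The wheat rule is evaluated only for
  seasons whose detected heading falls within ±30 days of the calendar
  prediction — the calendar surface encodes where and when wheat is possible
  at all, and this gate is what keeps summer crops with wheat-like EVI2
  dynamics out of the wheat class.
* **Maize**: the flowering window is the detected heading ±24 days, split at
  its midpoint; P/N are the sums of positive / absolute-negative day-to-day
  NMDI differences per half.  σ, the denominator stabiliser, defaults to
  **0.05**: with the θ₅ values fixed, σ must dominate the noise floor of the
  slope sums of non-maize pixels at the documented noise level, and labels
  on clean fixtures are insensitive to σ across [0.001, 0.05] (tested).

When several rules fire for one season, the label with the largest relative
margin (metric − threshold)/threshold wins — for the two-condition rules the
smaller of their condition margins — with the deterministic ordering
rice → wheat → maize on exact ties.

## Pattern codes and areas

Codes: first digit intensity, crop digits 4 maize / 5 rice / 6 wheat /
7 other; double-cropping digits are stored in ascending numeric order (the
code does not carry temporal order — the rotation 245 pairs digit 4 with
digit 5 yet is the rice→maize sequence), and the triple code carries no
composition.  Double patterns pairing one staple with "other" have no code of
their own and fold into 277; this is a documented convention of this package.
Sown areas are fraction-weighted and count every season separately (a
double-rice pixel contributes twice to rice) because that is the quantity
regional census statistics report.  Suitability masking demotes a target crop
to "other" outside its suitable area; the mask is an input.

## Accuracy assessment

Confusion-matrix rows are map predictions, columns reference labels.
Producer's accuracy is reported per predicted class (diagonal / row total)
and user's accuracy per reference class (diagonal / column total), matching
the reference accuracy-table layout this package reproduces; percentages are
displayed at 2 dp, full precision internally.  Kappa uses the standard
chance-agreement correction p_e = Σ rowᵢ·colᵢ / N².  Classes with an empty
row or column report the affected metrics as undefined (None), never NaN.
Area agreement is an OLS regression of estimated on reference areas with R²
the squared Pearson correlation; it requires ≥3 regions and non-degenerate
reference variance.

## The synthetic generator

Each crop cycle is a double-logistic EVI2 bump (product of two logistics,
normalised, rate = span/6 with a 3-day floor) over a base EVI2 of 0.12.
Winter wheat is the maximum of a small autumn bump (25 % of the cycle
amplitude, sown ~DOY 285 of the previous year) and the spring bump peaking
at heading, which produces the dormancy trough.  LSWI is coupled to greenness
as 0.5·EVI2 − 0.12; rice overrides it with a flood track,
flood_level + 0.08·(EVI2 − base), from 15 days before sowing (paddies are
inundated before transplanting) until heading, draining linearly over 30
days.  NMDI is 0.6 − 0.10·(EVI2 − base); maize adds a triangular flowering
bump (default rise 0.35, half-width 32 days) centred on heading.  Defaults:
flood level 0.30, cycle amplitudes 0.45–0.60, calendars typical of the
studied cropping systems (winter wheat heading DOY 120, single summer crops
peaking DOY 190–210, double-cropping seasons splitting the year near DOY
160/270, triple cropping three 95-day cycles).

Index trajectories are back-solved into bands via the closure
ρ_NIR = 0.2 + 0.5·EVI2 (NIR rises with greenness), red from the EVI2
equation, SWIR6 from LSWI, SWIR7 from NMDI — an exact inverse, so indices
recomputed from the simulated bands reproduce the targets to machine
precision.  Reflectances stay in [0, 1] for amplitudes ≤ 0.9, flood levels
≤ 0.45 and flowering rises ≤ 0.35 (NMDI ≥ LSWI keeps SWIR7 non-negative).
A mixed pixel is the per-band linear combination purity × crop +
(1 − purity) × background, the background being a constant endmember at
EVI2 0.15 / LSWI 0.0 / NMDI 0.6 on which no crop rule fires.  Gaussian
observation noise (sd in reflectance units, default scenarios 0.02) is added
per band and clipped to [0, 1]; cloud gaps are i.i.d. Bernoulli flags.
Scenes derive per-pixel seeds from (seed, row, col) via SeedSequence, so
output is bit-identical across runs and independent of pixel order.

What the generator does **not** emulate: spatially correlated clouds,
bidirectional-reflectance and atmospheric residuals, phenology shifts along
climate gradients, inter-annual calendar variability, non-constant
backgrounds (urban, water, forest mosaics), and sensor geolocation error.
Passing tests therefore demonstrate the internal consistency and noise
robustness of the rule machinery under controlled violations (mixing, noise,
gaps), not performance on real imagery.

## Numerical and interface choices

* Problem sizes: evaluation scenes are 50×50 pixels (2,500 series, all 11
  codes) — large enough for stable per-crop F1 while a full scene classifies
  in well under a minute on one CPU.
* The banded Whittaker solve caches the penalty matrix per grid length;
  per-pixel cost is dominated by the CWT (~10 ms).
* Rasters are written as TIFF with a JSON sidecar carrying CRS (WGS-84),
  a GDAL-style affine transform and the no-data value (pattern rasters:
  uint16, no-data 65535); values and metadata round-trip losslessly.
* Configuration is YAML with unknown keys rejected; every constant above is
  overridable there or via the Python API.
* CLI exit codes: 0 success, 2 configuration/validation error, 3 stage
  failure.

## Known limitations

* The intensity constants (relative power threshold 0.2, minimum skeleton 30
  days, merge distance 45 days, season band 60–200 days) are surrogates
  calibrated once against the generator, not re-derivations of any published
  wavelet-intensity implementation.
* The wheat calendar surfaces default to intercept-only planes; mapping real
  scenes requires fitting them to agro-meteorological station records.
* Crops beyond rice/wheat/maize are labelled "other"; the triple-cropping
  code carries no crop composition by design.
* RCPN discrimination degrades fastest with purity: the flowering NMDI bump
  dilutes linearly while its noise floor does not, so maize recall at purity
  ≈ 0.5 is the binding constraint in noisy scenes.
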