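"""Cropping-pattern integer codes, suitability masking, and sown-area tallies.

A pattern code packs the cropping intensity and the crop composition of a
pixel-year into at most three digits: the first digit is the intensity
(0 fallow, 1 single, 2 double, 3 triple); crop digits are 4 maize, 5 rice,
6 wheat, 7 other.  Double-cropping codes carry their two crop digits in
ascending numeric order (the code does not store temporal order; 245 is the
rice-maize rotation), and the triple-cropping code carries no composition.
"""

from __future__ import annotations

from collections import Counter
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Crop",
    "CROP_DIGIT",
    "DIGIT_CROP",
    "NODATA_CODE",
    "PATTERN_NAMES",
    "VALID_CODES",
    "apply_suitability_mask",
    "crop_area",
    "decode_pattern",
    "encode_pattern",
]


class Crop(str, Enum):
    RICE = "rice"
    WHEAT = "wheat"
    MAIZE = "maize"
    OTHER = "other"


CROP_DIGIT = {Crop.MAIZE: 4, Crop.RICE: 5, Crop.WHEAT: 6, Crop.OTHER: 7}
DIGIT_CROP = {v: k for k, v in CROP_DIGIT.items()}

PATTERN_NAMES = {
    0: "fallow",
    14: "single maize",
    15: "single rice",
    16: "single wheat",
    17: "single others",
    245: "rice-maize",
    246: "wheat-maize",
    255: "double rice",
    256: "wheat-rice",
    277: "other double cropping",
    3: "triple cropping",
}

VALID_CODES = tuple(PATTERN_NAMES)

#: Reserved raster no-data value (uint16) for excluded / unprocessable pixels.
NODATA_CODE = 65535


def _as_crop(label) -> Crop:
    return label if isinstance(label, Crop) else Crop(str(label))


def encode_pattern(intensity: int, season_labels) -> int:
    """Combine cropping intensity and ordered per-season crop labels into a code.

    Intensity 0 -> 0 and 3 -> 3 regardless of labels; single cropping ->
    ``1X``; double cropping -> ``2XY`` with the two crop digits in ascending
    order.  Double patterns pairing one staple with "other" are not part of
    the published vocabulary and are folded into 277 (other double cropping).
    """
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity must be 0..3, got {intensity}")
    labels = [_as_crop(c) for c in season_labels]
    if len(labels) != intensity:
        raise ValueError(
            f"{len(labels)} season labels incompatible with intensity {intensity}"
        )
    if intensity == 0:
        return 0
    if intensity == 3:
        return 3
    if intensity == 1:
        return 10 + CROP_DIGIT[labels[0]]
    d1, d2 = sorted(CROP_DIGIT[c] for c in labels)
    code = 200 + 10 * d1 + d2
    if code not in PATTERN_NAMES:  # staple + other pairs fold into 277
        return 277
    return code


def decode_pattern(code: int) -> tuple[int, Counter, str]:
    """Invert :func:`encode_pattern` up to temporal order.

    Returns ``(intensity, crop multiset, pattern name)``.  The triple code
    carries no composition, and 277 decodes to two "other" seasons.
    """
    code = int(code)
    if code not in PATTERN_NAMES:
        raise ValueError(f"unknown pattern code {code}; valid codes: {sorted(PATTERN_NAMES)}")
    name = PATTERN_NAMES[code]
    if code == 0:
        return 0, Counter(), name
    if code == 3:
        return 3, Counter(), name
    if code < 100:
        return 1, Counter([DIGIT_CROP[code - 10]]), name
    d1, d2 = (code // 10) % 10, code % 10
    return 2, Counter([DIGIT_CROP[d1], DIGIT_CROP[d2]]), name


def apply_suitability_mask(codes: np.ndarray, mask: np.ndarray, target: Crop) -> np.ndarray:
    """Demote the target crop to "other" outside its suitable area.

    ``mask`` is binary (1 = suitable).  Pattern codes containing the target
    crop in unsuitable pixels are re-encoded with that crop replaced by
    :attr:`Crop.OTHER`; everything else is unchanged.
    """
    codes = np.asarray(codes)
    mask = np.asarray(mask)
    if codes.shape != mask.shape:
        raise ValueError(f"misaligned grids: codes {codes.shape} vs mask {mask.shape}")
    target = _as_crop(target)
    out = codes.copy()
    for code in np.unique(codes):
        if code == NODATA_CODE or code not in PATTERN_NAMES:
            continue
        intensity, crops, _ = decode_pattern(int(code))
        if target not in crops:
            continue
        demoted = [Crop.OTHER if c == target else c for c in crops.elements()]
        new_code = encode_pattern(intensity, demoted)
        out[(codes == code) & (mask == 0)] = new_code
    return out


def crop_area(
    codes: np.ndarray,
    fraction: np.ndarray,
    pixel_area_ha: float,
) -> pd.DataFrame:
    """Fraction-weighted sown area per crop, in hectares.

    Sown-area convention: every season counts, so a wheat-maize pixel
    contributes its cropland area to wheat *and* maize, and a double-rice
    pixel contributes twice to rice.  The triple-cropping code carries no
    composition and contributes to no specific crop.
    """
    codes = np.asarray(codes)
    fraction = np.asarray(fraction, dtype=float)
    if codes.shape != fraction.shape:
        raise ValueError("codes and fraction rasters are misaligned")
    if pixel_area_ha <= 0:
        raise ValueError("pixel_area_ha must be positive")
    totals = {crop: 0.0 for crop in Crop}
    for code in np.unique(codes):
        if code == NODATA_CODE or int(code) not in PATTERN_NAMES:
            continue
        _, crops, _ = decode_pattern(int(code))
        if not crops:
            continue
        area = fraction[codes == code].sum() * pixel_area_ha
        for crop, mult in crops.items():
            totals[crop] += mult * area
    return pd.DataFrame(
        {"crop": [c.value for c in Crop], "area_ha": [totals[c] for c in Crop]}
    )
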