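"""Pixel-purity (cropland fraction) aggregation and stratification.

A fine-resolution binary cropland mask (e.g. 30 m) is block-aggregated to the
coarse sensor grid (e.g. 500 m) as a cropland fraction, and each coarse pixel
is assigned a purity stratum.  The stratum selects which threshold column the
crop decision rules use; pixels with very little cropland are excluded from
classification but are kept in the rasters under a reserved no-data stratum.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = ["Stratum", "aggregate_fraction", "classify_purity"]


class Stratum(IntEnum):
    """Purity strata: fraction > 0.90 pure, 0.50-0.90 moderate mixed,
    0.30-0.50 seriously mixed, < 0.30 excluded from classification.

    Boundary reading: 0.90 and 0.50 belong to MODERATE, 0.30 to SERIOUS.
    """

    EXCLUDED = 0
    PURE = 1
    MODERATE = 2
    SERIOUS = 3


def aggregate_fraction(fine_mask: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a binary cropland mask to a coarse fraction raster.

    Each coarse cell is the mean of its ``factor x factor`` block of fine
    cells; edge blocks that extend past the raster are averaged over the
    cells that exist (partial-block mean).  Aggregation conserves total
    cropland area exactly on divisible grids.
    """
    fine = np.asarray(fine_mask)
    if not np.isin(fine, (0, 1)).all():
        raise ValueError("fine mask must be binary (0/1)")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    fine = fine.astype(float)
    nr, nc = fine.shape
    out_r = -(-nr // factor)
    out_c = -(-nc // factor)
    out = np.empty((out_r, out_c))
    for i in range(out_r):
        for j in range(out_c):
            block = fine[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
            out[i, j] = block.mean()
    return out


def classify_purity(fraction):
    """Map cropland fraction(s) in [0, 1] to purity strata.

    Accepts a scalar or an array; returns a :class:`Stratum` or a uint8 array
    of stratum codes.
    """
    arr = np.asarray(fraction, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("fraction must lie in [0, 1]")
    strata = np.select(
        [arr > 0.90, arr >= 0.50, arr >= 0.30],
        [Stratum.PURE, Stratum.MODERATE, Stratum.SERIOUS],
        default=Stratum.EXCLUDED,
    ).astype(np.uint8)
    if np.isscalar(fraction) or arr.ndim == 0:
        return Stratum(int(strata))
    return strata
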