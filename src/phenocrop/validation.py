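"""Map accuracy assessment: confusion matrices, OA/UA/PA/F1/kappa, and
region-level sown-area agreement.

Convention: confusion-matrix rows are map predictions, columns are reference
labels.  Producer's accuracy is reported per *predicted* class
(diagonal / row total) and user's accuracy per *reference* class
(diagonal / column total), matching the layout of the accuracy table this
pipeline reports against.  Percentages are rounded to 2 dp for display;
internal values keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AccuracyReport",
    "accuracy_metrics",
    "area_agreement",
    "confusion_matrix",
]


@dataclass
class AccuracyReport:
    """Confusion matrix with its summary statistics.

    ``ua``, ``pa`` and ``f1`` are per-class dicts; entries are ``None`` when
    the corresponding row/column total is zero (metric undefined).  ``oa``
    is a fraction in [0, 1]; ``ua``/``pa`` are percentages.
    """

    classes: tuple
    matrix: np.ndarray
    oa: float
    kappa: float
    ua: dict
    pa: dict
    f1: dict

    def to_frame(self) -> pd.DataFrame:
        """Human-readable table mirroring the standard accuracy-table layout."""
        df = pd.DataFrame(self.matrix, index=self.classes, columns=self.classes)
        df["Total"] = df.sum(axis=1)
        df["Producer accuracy (%)"] = [
            None if self.pa[c] is None else round(self.pa[c], 2) for c in self.classes
        ]
        df["F1"] = [None if self.f1[c] is None else round(self.f1[c], 2) for c in self.classes]
        return df


def confusion_matrix(pred, ref, classes) -> np.ndarray:
    """Cell (i, j) counts samples predicted ``classes[i]`` with reference
    ``classes[j]``."""
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    pred = list(pred)
    ref = list(ref)
    if len(pred) != len(ref):
        raise ValueError("prediction and reference vectors differ in length")
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for p, r in zip(pred, ref):
        if p not in index or r not in index:
            raise ValueError(f"label {p if p not in index else r!r} not in class order")
        m[index[p], index[r]] += 1
    return m


def accuracy_metrics(matrix: np.ndarray, classes=None) -> AccuracyReport:
    """OA, kappa and per-class UA/PA/F1 from a confusion matrix.

    OA = trace / N; PA_i = m_ii / row_i (per predicted class); UA_i = m_ii /
    col_i (per reference class); F1_i harmonises UA and PA; kappa =
    (p_o - p_e) / (1 - p_e) with p_e = sum(row_i * col_i) / N^2.
    Classes with a zero row or column report ``None`` for the undefined
    metrics instead of propagating NaN.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    k = m.shape[0]
    classes = tuple(classes) if classes is not None else tuple(range(k))
    if len(classes) != k:
        raise ValueError("class order length does not match matrix")
    n = m.sum()
    if n <= 0:
        raise ValueError("matrix grand total must be positive")

    row = m.sum(axis=1)
    col = m.sum(axis=0)
    diag = np.diag(m)
    oa = diag.sum() / n
    p_e = float(row @ col) / n**2
    kappa = (oa - p_e) / (1 - p_e) if p_e < 1 else None

    ua, pa, f1 = {}, {}, {}
    for i, c in enumerate(classes):
        pa_i = diag[i] / row[i] if row[i] > 0 else None
        ua_i = diag[i] / col[i] if col[i] > 0 else None
        pa[c] = None if pa_i is None else 100.0 * pa_i
        ua[c] = None if ua_i is None else 100.0 * ua_i
        if pa_i is None or ua_i is None or (pa_i + ua_i) == 0:
            f1[c] = None
        else:
            f1[c] = 2.0 * ua_i * pa_i / (ua_i + pa_i)
    return AccuracyReport(classes, np.asarray(matrix), float(oa), kappa, ua, pa, f1)


def area_agreement(estimated, reference) -> tuple[float, float, float]:
    """OLS of estimated on reference areas: returns (slope, intercept, R^2).

    R^2 is the squared Pearson correlation.  Requires at least 3 regions and
    non-degenerate reference variance.
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("estimated and reference must be 1-D and equal length")
    if len(est) < 3:
        raise ValueError("need at least 3 regions")
    if np.ptp(ref) == 0:
        raise ValueError("reference areas have zero variance; agreement undefined")
    res = stats.linregress(ref, est)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
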