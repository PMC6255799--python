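"""pH calibration of the exchange rate, correlations, and ROC analysis.

Hydroxyl-proton exchange in the acidic disc regime follows

    k_sw(pH) = a * 10**(-pH + 8) + b          (a > 0)

so the exchange rate rises as the disc acidifies.  The model is fitted by
least squares to (pH, k_sw) pairs, inverted to read pH off a measured
exchange rate, and the exchange rate is used as the classifier score in a
healthy-vs-degenerated ROC analysis (higher k_sw means degenerated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationModel",
    "ROCResult",
    "fit_ph_calibration",
    "ph_from_ksw",
    "linear_correlation",
    "roc_analysis",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Coefficients of ``k_sw = a * 10**(8 - pH) + b`` (both 1/s).

    A physically meaningful calibration has ``a > 0`` (exchange rate rises
    as pH falls); a fit can produce ``a <= 0`` on degenerate data, which is
    flagged through :attr:`physical` rather than rejected outright.
    """

    a: float
    b: float
    r_squared: float = np.nan

    @property
    def physical(self) -> bool:
        return self.a > 0

    def ksw(self, ph: np.ndarray | float) -> np.ndarray | float:
        return self.a * 10.0 ** (8.0 - np.asarray(ph, dtype=float)) + self.b


def fit_ph_calibration(ph: np.ndarray, ksw: np.ndarray) -> CalibrationModel:
    """Least-squares fit of ``k_sw = a*10**(8-pH) + b``.

    The model is linear in (a, b) given the regressor ``x = 10**(8-pH)``,
    so the least-squares solution is exact.  Requires >= 3 pairs spanning
    more than 0.3 pH units; a fitted ``a <= 0`` (exchange rate not rising
    with acidity) is rejected as non-physical.
    """
    ph = np.asarray(ph, dtype=float)
    ksw = np.asarray(ksw, dtype=float)
    if ph.shape != ksw.shape or ph.ndim != 1:
        raise ValueError("ph and ksw must be 1-D arrays of equal length")
    if ph.size < 3:
        raise ValueError("need >= 3 (pH, k_sw) pairs")
    if np.ptp(ph) <= 0.3:
        raise ValueError("pH values must span more than 0.3 units")
    if np.ptp(ksw) == 0:
        raise ValueError("degenerate input: constant k_sw")
    x = 10.0 ** (8.0 - ph)
    a, b = np.polyfit(x, ksw, 1)
    pred = a * x + b
    ss_tot = float(np.sum((ksw - ksw.mean()) ** 2))
    r2 = 1.0 - float(np.sum((ksw - pred) ** 2)) / ss_tot
    return CalibrationModel(a=float(a), b=float(b), r_squared=r2)


def ph_from_ksw(model: CalibrationModel, ksw: float) -> float:
    """Invert the calibration: ``pH = 8 - log10((k_sw - b) / a)``.

    Only defined for ``k_sw > b``; the offset ``b`` is the floor of the
    calibrated exchange-rate range.
    """
    if not model.physical:
        raise ValueError("calibration is non-physical (a <= 0); cannot invert")
    if ksw <= model.b:
        raise ValueError(
            f"k_sw = {ksw} is at or below the calibration offset floor "
            f"b = {model.b}; pH is undefined there"
        )
    return float(8.0 - np.log10((ksw - model.b) / model.a))


def linear_correlation(x: np.ndarray, y: np.ndarray):
    """OLS line plus Pearson correlation.

    Returns ``(slope, intercept, r, r_squared, p_value)`` with the two-sided
    p-value from the t distribution on n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D arrays with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        float(res.rvalue**2),
        float(res.pvalue),
    )


@dataclass
class ROCResult:
    """ROC curve of a score that is high in the positive (degenerated) class."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float

    @property
    def youden_j(self) -> float:
        return self.youden_sensitivity + self.youden_specificity - 1.0


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC analysis of exchange-rate scores against binary disc labels.

    ``labels`` are 1/True for degenerated (positive class, higher scores)
    and 0/False for healthy.  Thresholds sweep the unique scores (a point
    is positive when ``score >= threshold``); AUC is the trapezoidal area
    under sensitivity vs (1 - specificity); the operating point maximizes
    Youden's J = sensitivity + specificity - 1, ties broken toward higher
    sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    # thresholds: +inf (nothing positive) down through each unique score
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate([[np.inf], uniq])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, th in enumerate(thresholds):
        pred = scores >= th
        sens[i] = (pred & labels).sum() / n_pos
        spec[i] = (~pred & ~labels).sum() / n_neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))

    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())
    # ties in J broken toward higher sensitivity
    i_best = best[np.argmax(sens[best])]
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_threshold=float(thresholds[i_best]),
        youden_sensitivity=float(sens[i_best]),
        youden_specificity=float(spec[i_best]),
    )
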