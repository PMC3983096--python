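"""External-validation statistics and the Golbraikh-Tropsha acceptance gate.

A model that cross-validates well internally can still fail on compounds it
never saw. The external suite compares predicted with measured activities
on a held-out test set:

* ``r^2_pred = 1 - PRESS_test / SD`` where PRESS_test sums squared test-set
  prediction errors and SD sums squared deviations of the measured test
  activities from the *training-set* mean activity;
* R, the Pearson correlation of actual and predicted;
* the free regression (slope/intercept) in both directions, since the
  convention is ambiguous in parts of the literature;
* through-origin slopes ``k = sum(y yhat) / sum(yhat^2)`` and
  ``k' = sum(y yhat) / sum(y^2)`` and the corresponding through-origin
  determination coefficients ``r^2_0`` (actual vs predicted) and ``r'^2_0``;
* ``r^2_m = r^2 (1 - sqrt(r^2 - r^2_0))``, which penalises divergence
  between the free and through-origin fits.

The acceptance gate passes a model only when all five conditions hold:
q^2 > 0.5, r^2 > 0.6, (r^2 - r^2_0)/r^2 < 0.1, 0.85 <= k <= 1.15 and
r^2_m > 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ExternalValidationReport", "GTVerdict", "external_validation",
           "gt_gate"]


@dataclass(frozen=True)
class ExternalValidationReport:
    n_test: int
    press_test: float
    sd: float
    r2_pred: float
    r: float  # Pearson correlation
    r2: float  # squared correlation of the free regression
    slope: float  # actual regressed on predicted
    intercept: float
    slope_rev: float  # predicted regressed on actual
    intercept_rev: float
    k: float  # through-origin slope, actual vs predicted
    k_rev: float
    r2_0: float  # through-origin determination, actual vs predicted
    r2_0_rev: float
    r2_m: float  # from r2 and r2_0
    r2_m_rev: float


@dataclass(frozen=True)
class GTVerdict:
    passed: bool
    criteria: dict[str, tuple[float, str, bool]]  # name -> (value, threshold, ok)


def _through_origin_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Determination coefficient of the zero-intercept fit of y on yhat."""
    k = float(np.sum(y * yhat) / np.sum(yhat * yhat))
    ss_res = float(np.sum((y - k * yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def _r2m(r2: float, r2_0: float) -> float:
    gap = r2 - r2_0
    if gap < 0:
        # through-origin fit no worse than free fit (possible since r2_0 is
        # not bounded by r2): no penalty
        return r2
    return r2 * (1.0 - math.sqrt(gap))


def external_validation(actual: Sequence[float], predicted: Sequence[float],
                        training_mean: float) -> ExternalValidationReport:
    """Compute the full external-validation statistic set on a test set."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 3:
        raise ValueError("need matching 1-d arrays with at least 3 test compounds")
    if not math.isfinite(training_mean):
        raise ValueError("training mean must be finite")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance actual activities")
    press = float(np.sum((yhat - y) ** 2))
    sd = float(np.sum((y - training_mean) ** 2))
    if np.ptp(yhat) == 0:
        # constant predictions: r2_pred is still defined (it is 0 when the
        # constant is the training mean), correlation statistics are not
        nan = float("nan")
        return ExternalValidationReport(
            n_test=len(y), press_test=press, sd=sd, r2_pred=1.0 - press / sd,
            r=nan, r2=nan, slope=nan, intercept=nan, slope_rev=nan,
            intercept_rev=nan, k=nan, k_rev=nan, r2_0=nan, r2_0_rev=nan,
            r2_m=nan, r2_m_rev=nan)
    r = float(np.corrcoef(y, yhat)[0, 1])
    r2 = r * r
    # free regressions in both directions
    slope, intercept = np.polyfit(yhat, y, 1)
    slope_rev, intercept_rev = np.polyfit(y, yhat, 1)
    k = float(np.sum(y * yhat) / np.sum(yhat * yhat))
    k_rev = float(np.sum(y * yhat) / np.sum(y * y))
    r2_0 = _through_origin_r2(y, yhat)
    r2_0_rev = _through_origin_r2(yhat, y)
    return ExternalValidationReport(
        n_test=len(y), press_test=press, sd=sd, r2_pred=1.0 - press / sd,
        r=r, r2=r2, slope=float(slope), intercept=float(intercept),
        slope_rev=float(slope_rev), intercept_rev=float(intercept_rev),
        k=k, k_rev=k_rev, r2_0=r2_0, r2_0_rev=r2_0_rev,
        r2_m=_r2m(r2, r2_0), r2_m_rev=_r2m(r2, r2_0_rev))


def gt_gate(report: ExternalValidationReport, q2: float, r2: float) -> GTVerdict:
    """Apply the five-way acceptance gate to a validation report.

    ``q2`` and ``r2`` are the model's internal cross-validated and
    non-validated correlation coefficients.
    """
    ratio = (report.r2 - report.r2_0) / report.r2
    criteria = {
        "q2": (q2, "> 0.5", q2 > 0.5),
        "r2": (r2, "> 0.6", r2 > 0.6),
        "(r2 - r2_0)/r2": (ratio, "< 0.1", ratio < 0.1),
        "k": (report.k, "in [0.85, 1.15]", 0.85 <= report.k <= 1.15),
        "r2_m": (report.r2_m, "> 0.5", report.r2_m > 0.5),
    }
    return GTVerdict(passed=all(ok for _, _, ok in criteria.values()),
                     criteria=criteria)
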