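"""Calibration, discrimination, and overall-accuracy metrics on a target set.

Calibration-in-the-large (CITL) is the intercept of a logistic model with the
linear predictor fixed as an offset (0 = perfect overall calibration); the
calibration slope is the coefficient of the linear predictor when it is the
sole covariate (1 = no over/underfitting). Discrimination is measured by the
concordance statistic C (ties half-credited) and by the area under the
precision-recall step curve, which is more informative than ROC at the low
event rates typical of this setting. The Brier score is the mean squared
error of the predicted probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.metrics import average_precision_score, roc_auc_score

from .cohort import Cohort
from .cpm import FittedCPM
from .exceptions import DegenerateOutcomeError, SchemaError

__all__ = [
    "METRIC_NAMES",
    "PerformanceReport",
    "citl",
    "calibration_slope",
    "c_statistic",
    "auc_pr",
    "brier",
    "evaluate",
]

METRIC_NAMES = ("citl", "calibration_slope", "c_statistic", "auc_pr", "brier")


@dataclass(frozen=True)
class PerformanceReport:
    citl: float
    calibration_slope: float
    c_statistic: float
    auc_pr: float
    brier: float
    n_eval: int
    events_eval: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def to_json(self) -> str:
        d = self.as_dict()
        d.update(n_eval=self.n_eval, events_eval=self.events_eval)
        return json.dumps(d)


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("metric undefined: outcome has a single class")
    return y


def citl(y: np.ndarray, lp: np.ndarray) -> float:
    """Calibration-in-the-large: MLE intercept with ``lp`` as offset."""
    y = _check_two_classes(y)
    lp = np.asarray(lp, dtype=float)
    if lp.shape != y.shape:
        raise SchemaError("y and lp must be the same length")
    res = sm.GLM(
        y, np.ones((y.size, 1)), family=sm.families.Binomial(), offset=lp
    ).fit()
    return float(res.params[0])


def calibration_slope(y: np.ndarray, lp: np.ndarray) -> float:
    """Slope of a logistic regression of ``y`` on ``lp`` (free intercept)."""
    y = _check_two_classes(y)
    lp = np.asarray(lp, dtype=float)
    if np.ptp(lp) == 0:
        raise DegenerateOutcomeError("calibration slope undefined for constant lp")
    A = np.column_stack([np.ones_like(lp), lp])
    res = sm.GLM(y, A, family=sm.families.Binomial()).fit()
    return float(res.params[1])


def c_statistic(y: np.ndarray, p: np.ndarray) -> float:
    """Concordance over case-control pairs; tied predictions score 1/2."""
    y = _check_two_classes(y)
    return float(roc_auc_score(y, np.asarray(p, dtype=float)))


def auc_pr(y: np.ndarray, p: np.ndarray) -> float:
    """Area under the non-interpolated precision-recall step curve."""
    y = np.asarray(y)
    if y.sum() == 0:
        raise DegenerateOutcomeError("AUC-PR undefined with no events")
    return float(average_precision_score(y, np.asarray(p, dtype=float)))


def brier(y: np.ndarray, p: np.ndarray) -> float:
    """Mean squared difference between outcomes and predicted risks."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise SchemaError("y and p must be the same length")
    return float(np.mean((y - p) ** 2))


def evaluate(model: FittedCPM, target_cohort: Cohort) -> PerformanceReport:
    """All five metrics for ``model`` on a pure target cohort (all R=0).

    Predictions are made at the target level of the membership dummy.
    """
    if (target_cohort.R != 0).any():
        raise SchemaError("evaluation cohort must contain target rows only (R=0)")
    X = target_cohort.columns(model.predictor_names)
    lp = model.linear_predictor(X, as_target=True)
    p = model.predict_risk(X, as_target=True)
    y = target_cohort.Y
    return PerformanceReport(
        citl=citl(y, lp),
        calibration_slope=calibration_slope(y, lp),
        c_statistic=c_statistic(y, p),
        auc_pr=auc_pr(y, p),
        brier=brier(y.astype(float), p),
        n_eval=int(y.size),
        events_eval=int(y.sum()),
    )
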