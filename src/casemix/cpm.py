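"""Weighted logistic prediction models and the three development strategies.

The weighted fit maximizes the weighted binomial log-likelihood

    LL = sum_i w_i * ( y_i * log p_i + (1 - y_i) * log(1 - p_i) )

with the membership weights treated as fixed known constants. Three
development strategies are supported:

``all_unweighted``
    ordinary logistic regression on all rows (source + target), ignoring
    the shift;
``target_only``
    ordinary logistic regression on the target rows only;
``membership_weighted``
    the weighted fit on all rows, with source rows carrying inverse-odds
    membership weights and target rows weight 1.

The two all-data strategies can additionally absorb an event-rate shift by
including the source-membership dummy R as a predictor (calibration-in-the-
large adjustment); at prediction time the dummy is set to 0, the target
level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .cohort import Cohort
from .exceptions import (
    ConfigurationError,
    ConvergenceError,
    DegenerateOutcomeError,
    SchemaError,
)
from .weighting import (
    MembershipModel,
    WeightVector,
    fit_membership_model,
    propensity,
    weights_capped,
    weights_raw,
    weights_scaled,
)

__all__ = [
    "STRATEGIES",
    "WEIGHT_REGIMES",
    "FittedCPM",
    "fit_weighted_logistic",
    "membership_weights",
    "develop_model",
    "predict_risk",
    "linear_predictor",
]

STRATEGIES = ("all_unweighted", "target_only", "membership_weighted")
WEIGHT_REGIMES = ("raw", "capped", "scaled")

_REGIME_FN = {"raw": weights_raw, "capped": weights_capped, "scaled": weights_scaled}


@dataclass(frozen=True)
class FittedCPM:
    """A fitted (possibly weighted) logistic clinical prediction model."""

    intercept: float
    coefficients: np.ndarray
    predictor_names: tuple[str, ...]
    dummy_R_coefficient: float | None = None
    strategy: str | None = None
    weight_regime: str | None = None
    converged: bool = True
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )
        object.__setattr__(self, "predictor_names", tuple(self.predictor_names))

    def linear_predictor(self, X: np.ndarray, as_target: bool = True) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.coefficients.size:
            raise SchemaError(
                f"X has wrong shape {X.shape}; model expects "
                f"{self.coefficients.size} predictor columns"
            )
        lp = self.intercept + X @ self.coefficients
        if self.dummy_R_coefficient is not None and not as_target:
            lp = lp + self.dummy_R_coefficient
        return lp

    def predict_risk(self, X: np.ndarray, as_target: bool = True) -> np.ndarray:
        return expit(self.linear_predictor(X, as_target=as_target))

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients.tolist(),
                "predictor_names": list(self.predictor_names),
                "dummy_R_coefficient": self.dummy_R_coefficient,
                "strategy": self.strategy,
                "weight_regime": self.weight_regime,
                "converged": self.converged,
                "loglik": self.loglik,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedCPM":
        return cls(**json.loads(text))


def fit_weighted_logistic(
    cohort: Cohort,
    predictors: Sequence[str] | None = None,
    weights: WeightVector | np.ndarray | None = None,
    include_dummy_R: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
    strategy: str | None = None,
) -> FittedCPM:
    """Maximize the weighted binomial log-likelihood by IRLS.

    Rows with zero weight contribute nothing and are excluded from the fit.
    The outcome must have both classes among the rows with positive weight.
    """
    if predictors is None:
        predictors = cohort.predictor_names
    predictors = tuple(predictors)
    if weights is None:
        w = np.ones(cohort.N)
        regime = None
    elif isinstance(weights, WeightVector):
        w = weights.w
        regime = weights.regime
    else:
        w = np.asarray(weights, dtype=float)
        regime = None
    if w.shape != (cohort.N,):
        raise SchemaError("weights must have one entry per cohort row")
    if w.sum() <= 0:
        raise DegenerateOutcomeError("all weights are zero")

    keep = w > 0
    y = cohort.Y[keep]
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError(
            "outcome has a single class among positively weighted rows"
        )
    X = cohort.columns(predictors)[keep]
    design = [np.ones(keep.sum()), *X.T]
    if include_dummy_R:
        design.append(cohort.R[keep].astype(float))
    A = np.column_stack(design)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sm.GLM(y, A, family=sm.families.Binomial(), var_weights=w[keep]).fit(
            maxiter=max_iter, tol=tol
        )
    if not res.converged:
        raise ConvergenceError(
            f"weighted logistic fit did not converge in {max_iter} iterations"
        )
    params = np.asarray(res.params, dtype=float)
    dummy = float(params[-1]) if include_dummy_R else None
    k = len(predictors)
    return FittedCPM(
        intercept=float(params[0]),
        coefficients=params[1 : 1 + k],
        predictor_names=predictors,
        dummy_R_coefficient=dummy,
        strategy=strategy,
        weight_regime=regime,
        converged=True,
        loglik=float(res.llf),
    )


def membership_weights(
    cohort: Cohort,
    regime: str = "capped",
    predictors: Sequence[str] | None = None,
    ridge: float = 0.0,
) -> tuple[MembershipModel, WeightVector]:
    """Fit the membership model and produce weights under ``regime``.

    By default the membership model uses the same predictor set as the
    prediction model.
    """
    if regime not in WEIGHT_REGIMES:
        raise ConfigurationError(f"unknown weight regime {regime!r}")
    if predictors is None:
        predictors = cohort.predictor_names
    model = fit_membership_model(cohort, predictors, ridge=ridge)
    ps = propensity(model, cohort.columns(predictors))
    wv = _REGIME_FN[regime](ps, cohort.R)
    return model, wv


def develop_model(
    cohort: Cohort,
    predictors: Sequence[str] | None = None,
    strategy: str = "membership_weighted",
    weight_regime: str | None = "capped",
    include_dummy_R: bool = False,
    ridge: float = 0.0,
    membership_predictors: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FittedCPM:
    """Develop a prediction model under one of the three strategies.

    ``target_only`` never takes weights nor the membership dummy (its
    training rows have a single membership level); weight regimes apply only
    to ``membership_weighted``.
    """
    if strategy not in STRATEGIES:
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    if strategy == "target_only":
        if include_dummy_R:
            raise ConfigurationError("target_only cannot include the membership dummy")
        if weight_regime not in (None, "none"):
            raise ConfigurationError("target_only takes no weights")
        target = cohort.target
        fit = fit_weighted_logistic(
            target, predictors, None, False, max_iter, tol, strategy
        )
        return fit
    if strategy == "all_unweighted":
        if weight_regime not in (None, "none"):
            raise ConfigurationError("all_unweighted takes no weight regime")
        return fit_weighted_logistic(
            cohort, predictors, None, include_dummy_R, max_iter, tol, strategy
        )
    # membership_weighted
    if weight_regime not in WEIGHT_REGIMES:
        raise ConfigurationError(
            f"membership_weighted requires a weight regime from {WEIGHT_REGIMES}"
        )
    mpred = membership_predictors if membership_predictors is not None else predictors
    _, wv = membership_weights(cohort, weight_regime, mpred, ridge)
    return fit_weighted_logistic(
        cohort, predictors, wv, include_dummy_R, max_iter, tol, strategy
    )


def linear_predictor(
    model: FittedCPM, X: np.ndarray, as_target: bool = True
) -> np.ndarray:
    return model.linear_predictor(X, as_target=as_target)


def predict_risk(model: FittedCPM, X: np.ndarray, as_target: bool = True) -> np.ndarray:
    """Predicted event probabilities; the membership dummy (if any) is set to
    0 when ``as_target`` (the deployment population) and 1 otherwise."""
    return model.predict_risk(X, as_target=as_target)
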