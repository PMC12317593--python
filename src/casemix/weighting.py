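"""Membership propensity scores and inverse-odds weights for source rows.

The membership propensity score ``PS_i = P(R=1 | X_i)`` is the probability
that row *i* belongs to the source set (the pre-shift data), estimated with a
binary logistic regression of R on the predictors. Source rows then receive
the inverse-odds weight

    w_i = ((1 - PS_i) / PS_i) * (s / n)

which transports the source predictor distribution toward the target
distribution; target rows always keep weight 1. Three regimes control the
effective sample size (ESS, the plain sum of weights) of the weighted source
set:

``raw``
    no limit — the baseline importance-weighting comparator, which can
    inflate the ESS and produce overoptimistic standard errors;
``capped``
    each source weight is truncated at 1, so the weighted source set can
    never count for more than the actual source rows;
``scaled``
    when the raw source ESS exceeds the actual source size ``s``, all source
    weights are multiplied by ``c = s / sum(w)`` so the source ESS equals
    ``s`` exactly; otherwise the raw weights are kept unchanged.
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
    DegenerateLabelsError,
    FitConvergenceWarning,
    QuasiSeparationWarning,
    SchemaError,
)

__all__ = [
    "PS_EPS",
    "MembershipModel",
    "WeightVector",
    "fit_membership_model",
    "propensity",
    "weights_raw",
    "weights_capped",
    "weights_scaled",
    "effective_sample_size",
]

#: propensities are clipped into [PS_EPS, 1 - PS_EPS] before forming odds
PS_EPS = 1e-12


@dataclass(frozen=True)
class MembershipModel:
    """Fitted logistic membership model P(R=1 | X)."""

    intercept: float
    coefficients: np.ndarray
    predictor_names: tuple[str, ...]
    ridge: float = 0.0
    converged: bool = True
    separation_suspected: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )
        object.__setattr__(self, "predictor_names", tuple(self.predictor_names))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.coefficients.size:
            raise SchemaError(
                f"X has {X.shape[-1] if X.ndim == 2 else X.ndim} columns, "
                f"model expects {self.coefficients.size}"
            )
        return self.intercept + X @ self.coefficients

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients.tolist(),
                "predictor_names": list(self.predictor_names),
                "ridge": self.ridge,
                "converged": self.converged,
                "separation_suspected": self.separation_suspected,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MembershipModel":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class WeightVector:
    """Per-row analysis weights with their regime and ESS accounting.

    ``ess_source`` is the sum of weights over source rows and ``ess_total``
    adds the n target rows (each weighted 1). ``scaling_factor`` is the
    factor ``c`` actually applied, present only when the scaled regime
    triggered.
    """

    w: np.ndarray
    R: np.ndarray
    regime: str  # raw | capped | scaled
    scaling_factor: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        object.__setattr__(self, "R", np.asarray(self.R, dtype=int))
        if self.w.shape != self.R.shape:
            raise SchemaError("weights and membership must be the same length")
        if (self.w < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def ess_source(self) -> float:
        return float(self.w[self.R == 1].sum())

    @property
    def ess_total(self) -> float:
        return self.ess_source + float((self.R == 0).sum())


def fit_membership_model(
    cohort: Cohort,
    predictors: Sequence[str] | None = None,
    ridge: float = 0.0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> MembershipModel:
    """Fit the logistic membership model of R on the chosen predictors.

    The default fit is unpenalized maximum likelihood. Complete or quasi-
    complete separation of the two membership classes (which arises by design
    under a complete case-mix shift) is detected after the fit and reported
    through :class:`QuasiSeparationWarning` rather than an error: boundary
    propensities are precisely what makes the inverse-odds weights vanish for
    irrelevant source rows. A small ``ridge`` penalty can be supplied to
    regularize the fit when separation is *not* intended.
    """
    if predictors is None:
        predictors = cohort.predictor_names
    X = cohort.columns(predictors)
    R = cohort.R
    if len(np.unique(R)) < 2:
        raise DegenerateLabelsError(
            "membership indicator has a single class; cannot fit a propensity model"
        )

    if ridge > 0:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(  # L2 penalty with strength `ridge`
            C=1.0 / ridge, solver="lbfgs", max_iter=max_iter, tol=tol
        )
        clf.fit(X, R)
        converged = int(clf.n_iter_[0]) < max_iter
        intercept = float(clf.intercept_[0])
        coef = clf.coef_[0]
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(R, sm.add_constant(X, has_constant="add")).fit(
                disp=0, method="lbfgs", maxiter=max_iter, pgtol=tol
            )
        converged = bool(res.mle_retvals.get("converged", False))
        intercept = float(res.params[0])
        coef = np.asarray(res.params[1:], dtype=float)

    lp = intercept + X @ coef
    ps = expit(lp)
    # quasi-separation: classes near-perfectly ranked with boundary propensities
    separated = bool(
        (np.abs(lp) > 15).any()
        and (ps[R == 1] > 0.5).mean() > 0.99
        and (ps[R == 0] < 0.5).mean() > 0.99
    )
    if separated and ridge == 0:
        warnings.warn(
            "membership classes appear (quasi-)separated; propensities are at "
            "the boundary. Set ridge > 0 if this is not an intended complete "
            "case-mix shift.",
            QuasiSeparationWarning,
            stacklevel=2,
        )
    if not converged and ridge == 0:
        warnings.warn(
            "membership model did not converge at ridge=0; consider ridge > 0",
            FitConvergenceWarning,
            stacklevel=2,
        )
    return MembershipModel(
        intercept, coef, tuple(predictors), ridge, converged, separated
    )


def propensity(model: MembershipModel, X: np.ndarray) -> np.ndarray:
    """Membership propensities, clipped into [PS_EPS, 1 - PS_EPS]."""
    return np.clip(expit(model.linear_predictor(X)), PS_EPS, 1.0 - PS_EPS)


def _source_odds_weights(ps: np.ndarray, R: np.ndarray, s: int, n: int) -> np.ndarray:
    ps = np.clip(np.asarray(ps, dtype=float), PS_EPS, 1.0 - PS_EPS)
    w = np.ones_like(ps)
    src = np.asarray(R) == 1
    w[src] = (1.0 - ps[src]) / ps[src] * (s / n)
    return w


def _sizes(R: np.ndarray, s: int | None, n: int | None) -> tuple[int, int]:
    R = np.asarray(R)
    s = int(R.sum()) if s is None else int(s)
    n = int((R == 0).sum()) if n is None else int(n)
    if s < 1 or n < 1:
        raise ValueError("both source and target sets must be non-empty")
    return s, n


def weights_raw(
    ps: np.ndarray, R: np.ndarray, s: int | None = None, n: int | None = None
) -> WeightVector:
    """Unlimited inverse-odds weights (baseline importance weighting)."""
    s, n = _sizes(R, s, n)
    return WeightVector(_source_odds_weights(ps, R, s, n), R, "raw")


def weights_capped(
    ps: np.ndarray, R: np.ndarray, s: int | None = None, n: int | None = None
) -> WeightVector:
    """Inverse-odds weights truncated at 1 on source rows."""
    s, n = _sizes(R, s, n)
    w = _source_odds_weights(ps, R, s, n)
    src = np.asarray(R) == 1
    w[src] = np.minimum(w[src], 1.0)
    return WeightVector(w, R, "capped")


def weights_scaled(
    ps: np.ndarray, R: np.ndarray, s: int | None = None, n: int | None = None
) -> WeightVector:
    """Raw weights rescaled so the source ESS never exceeds ``s``.

    The factor ``c = s / sum(w)`` is applied only when the raw source weight
    sum exceeds ``s``; otherwise the raw weights pass through unchanged and
    no scaling factor is recorded.
    """
    s, n = _sizes(R, s, n)
    w = _source_odds_weights(ps, R, s, n)
    src = np.asarray(R) == 1
    total = float(w[src].sum())
    c = None
    if total > s:
        c = s / total
        w[src] *= c
    return WeightVector(w, R, "scaled", scaling_factor=c)


def effective_sample_size(weights: WeightVector) -> tuple[float, float]:
    """(source ESS, total ESS) as plain weight sums."""
    return weights.ess_source, weights.ess_total
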