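"""Bootstrap-optimism internal validation of a development strategy.

For each of B bootstrap replicates the development cohort is resampled with
replacement, stratified by membership so the source/target sizes (and hence
the s/n ratio entering the weights) are preserved. The entire development
pipeline — membership model, weights, and prediction-model fit — is rerun on
the replicate. The optimism draw for each metric is

    boot_apparent (replicate model on the replicate's target rows)
  - boot_test     (replicate model on the original target set)

and the optimism-adjusted metric is the apparent metric minus the mean draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import Cohort
from .cpm import FittedCPM, develop_model
from .exceptions import ConvergenceError, DegenerateOutcomeError
from .metrics import METRIC_NAMES, PerformanceReport, evaluate

__all__ = ["DevelopmentConfig", "OptimismReport", "adjust", "bootstrap_optimism"]


@dataclass(frozen=True)
class DevelopmentConfig:
    """One of the Table-of-modelling-options development strategies."""

    strategy: str = "membership_weighted"
    weight_regime: str | None = "capped"
    include_dummy_R: bool = False
    predictors: tuple[str, ...] | None = None
    ridge: float = 0.0

    def develop(self, cohort: Cohort) -> FittedCPM:
        return develop_model(
            cohort,
            predictors=self.predictors,
            strategy=self.strategy,
            weight_regime=self.weight_regime,
            include_dummy_R=self.include_dummy_R,
            ridge=self.ridge,
        )

    @property
    def label(self) -> str:
        parts = [self.strategy]
        if self.strategy == "membership_weighted" and self.weight_regime:
            parts.append(self.weight_regime)
        if self.include_dummy_R:
            parts.append("citl_adjusted")
        return "_".join(parts)


@dataclass(frozen=True)
class OptimismReport:
    """Apparent performance, per-replicate optimism draws, and adjusted values."""

    apparent: PerformanceReport
    draws: dict[str, np.ndarray]
    B: int
    seed: int | None
    n_discarded: int = 0

    @property
    def mean_optimism(self) -> dict[str, float]:
        return {m: float(np.mean(self.draws[m])) for m in METRIC_NAMES}

    @property
    def adjusted(self) -> dict[str, float]:
        apparent = self.apparent.as_dict()
        return {m: adjust(apparent[m], self.draws[m]) for m in METRIC_NAMES}

    def to_json(self) -> str:
        return json.dumps(
            {
                "apparent": self.apparent.as_dict(),
                "adjusted": self.adjusted,
                "mean_optimism": self.mean_optimism,
                "draws": {m: self.draws[m].tolist() for m in METRIC_NAMES},
                "B": self.B,
                "seed": self.seed,
                "n_discarded": self.n_discarded,
            }
        )


def adjust(apparent: float, optimism_draws: Sequence[float]) -> float:
    """Apparent metric minus the mean optimism draw."""
    draws = np.asarray(optimism_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("optimism draws must be non-empty")
    return float(apparent - draws.mean())


def _stratified_resample(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    src = np.flatnonzero(cohort.R == 1)
    tgt = np.flatnonzero(cohort.R == 0)
    idx = np.concatenate(
        [rng.choice(src, size=src.size, replace=True) if src.size else src,
         rng.choice(tgt, size=tgt.size, replace=True)]
    )
    return Cohort(cohort.X[idx], cohort.Y[idx], cohort.R[idx], cohort.predictor_names)


def bootstrap_optimism(
    cohort: Cohort,
    config: DevelopmentConfig,
    B: int = 200,
    seed: int | None = None,
) -> OptimismReport:
    """Optimism-adjusted performance of ``config`` on ``cohort``.

    Replicates whose target rows end up with a single outcome class (or whose
    fit is otherwise degenerate) are discarded and redrawn; if more draws are
    discarded than kept the procedure fails rather than report a biased
    estimate. Deterministic under a fixed ``seed``.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    rng = np.random.default_rng(seed)
    model = config.develop(cohort)
    original_target = cohort.target
    apparent = evaluate(model, original_target)

    draws: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    discarded = 0
    completed = 0
    while completed < B:
        if discarded > B:  # more than half of all attempts degenerate
            raise RuntimeError(
                f"more than half of bootstrap replicates degenerate "
                f"({discarded} discarded for {completed} kept)"
            )
        boot = _stratified_resample(cohort, rng)
        if len(np.unique(boot.target.Y)) < 2:
            discarded += 1
            continue
        try:
            boot_model = config.develop(boot)
            boot_apparent = evaluate(boot_model, boot.target)
            boot_test = evaluate(boot_model, original_target)
        except (DegenerateOutcomeError, ConvergenceError):
            discarded += 1
            continue
        ba, bt = boot_apparent.as_dict(), boot_test.as_dict()
        for m in METRIC_NAMES:
            draws[m].append(ba[m] - bt[m])
        completed += 1

    return OptimismReport(
        apparent=apparent,
        draws={m: np.asarray(v) for m, v in draws.items()},
        B=B,
        seed=seed,
        n_discarded=discarded,
    )
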