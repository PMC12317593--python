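"""Patient-level cohort container, CSV round-trip, and source/target splitting.

A cohort couples a numeric predictor matrix ``X`` with a binary outcome ``Y``
and a membership indicator ``R`` (1 = source set, i.e. rows observed before
the latest case-mix shift; 0 = target set, the distribution the model will be
deployed in). Splitting a combined dataset into source and target sets is
expressed declaratively through :class:`SplitRule` so scenario designs are
serialisable and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError, SchemaError, SizeError

__all__ = ["Cohort", "SplitRule", "load_cohort", "write_cohort", "apply_split"]


@dataclass(frozen=True)
class Cohort:
    """Predictor matrix plus outcome and source/target membership.

    Parameters
    ----------
    X : ndarray of shape (N, K)
        Predictors in natural units; binary predictors coded 0/1.
    Y : ndarray of shape (N,)
        Binary outcome, 0/1.
    R : ndarray of shape (N,)
        Membership indicator: 1 = source set, 0 = target set.
    predictor_names : tuple of str
        Unique labels matching the columns of ``X``.
    """

    X: np.ndarray
    Y: np.ndarray
    R: np.ndarray
    predictor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=int)
        R = np.asarray(self.R, dtype=int)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "predictor_names", tuple(self.predictor_names))
        if X.ndim != 2:
            raise SchemaError("X must be a 2-D matrix")
        if len(self.predictor_names) != X.shape[1]:
            raise SchemaError(
                f"{len(self.predictor_names)} predictor names for {X.shape[1]} columns"
            )
        if len(set(self.predictor_names)) != len(self.predictor_names):
            raise SchemaError("predictor names must be unique")
        if Y.shape != (X.shape[0],) or R.shape != (X.shape[0],):
            raise SchemaError("Y and R must have one entry per row of X")
        if not np.isin(Y, (0, 1)).all():
            raise ParseError("outcome Y must be coded 0/1")
        if not np.isin(R, (0, 1)).all():
            raise ParseError("membership R must be coded 0/1")
        if not np.isfinite(X).all():
            bad = int(np.argwhere(~np.isfinite(X))[0, 0])
            raise ParseError(f"non-finite predictor value at row {bad}")

    # -- basic accessors ---------------------------------------------------
    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def K(self) -> int:
        return self.X.shape[1]

    @property
    def s(self) -> int:
        """Source-set size (rows with R=1)."""
        return int(self.R.sum())

    @property
    def n(self) -> int:
        """Target-set size (rows with R=0)."""
        return int((self.R == 0).sum())

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.predictor_names.index(name)
        except ValueError:
            raise SchemaError(f"unknown predictor column {name!r}") from None
        return self.X[:, j]

    def columns(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.predictor_names.index(n) if n in self.predictor_names else -1 for n in names]
        missing = [n for n, j in zip(names, idx) if j < 0]
        if missing:
            raise SchemaError(f"unknown predictor column(s) {missing}")
        return self.X[:, idx]

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask)
        return Cohort(self.X[mask], self.Y[mask], self.R[mask], self.predictor_names)

    @property
    def source(self) -> "Cohort":
        return self.subset(self.R == 1)

    @property
    def target(self) -> "Cohort":
        return self.subset(self.R == 0)

    # -- interchange -------------------------------------------------------
    def to_frame(self, outcome_col: str = "y", membership_col: str = "R") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.predictor_names))
        df[outcome_col] = self.Y
        df[membership_col] = self.R
        return df


@dataclass(frozen=True)
class SplitRule:
    """Declarative rule dividing a combined cohort into source and target sets.

    ``covariate_cutoff`` mode places rows strictly above ``cutoff`` on
    ``source_side='above'`` into the source pool and rows at or below it into
    the target pool (and vice versa for ``'below'``). The range modes use
    closed intervals; rows eligible for both sets are allocated to the target
    set first, since the target set is the scarce, defining set in every
    scenario design. ``time_ranges`` is semantically identical to
    ``covariate_ranges`` but signals that ``variable`` is a calendar-time
    column rather than a predictor proper.
    """

    mode: str  # covariate_cutoff | covariate_ranges | time_ranges
    variable: str
    cutoff: float | None = None
    source_side: str = "above"  # for covariate_cutoff
    source_range: tuple[float, float] | None = None
    target_range: tuple[float, float] | None = None
    subsample_sizes: tuple[int, int] | None = None  # (s, n)

    def __post_init__(self) -> None:
        if self.mode not in ("covariate_cutoff", "covariate_ranges", "time_ranges"):
            raise SchemaError(f"unknown split mode {self.mode!r}")
        if self.mode == "covariate_cutoff":
            if self.cutoff is None:
                raise SchemaError("covariate_cutoff mode requires a cutoff")
            if self.source_side not in ("above", "below"):
                raise SchemaError("source_side must be 'above' or 'below'")
        else:
            for rng, label in ((self.source_range, "source"), (self.target_range, "target")):
                if rng is None or rng[0] > rng[1]:
                    raise SchemaError(f"{label}_range must be a non-empty closed interval")

    def eligibility(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks of rows eligible for the source and target pools."""
        v = np.asarray(values, dtype=float)
        if self.mode == "covariate_cutoff":
            above, at_or_below = v > self.cutoff, v <= self.cutoff
            if self.source_side == "above":
                return above, at_or_below
            return at_or_below, above
        src = (v >= self.source_range[0]) & (v <= self.source_range[1])
        tgt = (v >= self.target_range[0]) & (v <= self.target_range[1])
        return src, tgt

    def to_json(self) -> str:
        return json.dumps(
            {k: v for k, v in self.__dict__.items() if v is not None}, default=list
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitRule":
        d = json.loads(text)
        for key in ("source_range", "target_range", "subsample_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def load_cohort(
    path,
    outcome_col: str,
    membership_col: str | None = None,
    predictor_cols: Sequence[str] | None = None,
) -> Cohort:
    """Read a delimited-text cohort (comma-separated, header row, '.' decimal).

    When ``membership_col`` is absent every row is assigned R=0; membership is
    then expected to come from a later :func:`apply_split`. Row order is
    preserved. Missing or non-numeric cells are rejected with the row index.
    """
    df = pd.read_csv(path)
    if outcome_col not in df.columns:
        raise SchemaError(f"missing outcome column {outcome_col!r}")
    if membership_col is not None and membership_col not in df.columns:
        raise SchemaError(f"missing membership column {membership_col!r}")
    if predictor_cols is None:
        drop = {outcome_col} | ({membership_col} if membership_col else set())
        predictor_cols = [c for c in df.columns if c not in drop]
    else:
        missing = [c for c in predictor_cols if c not in df.columns]
        if missing:
            raise SchemaError(f"missing predictor column(s) {missing}")

    def numeric(col: str) -> np.ndarray:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            raise ParseError(
                f"column {col!r}: non-numeric or missing value at row {int(bad[0])}"
            )
        return parsed.to_numpy(dtype=float)

    X = np.column_stack([numeric(c) for c in predictor_cols]) if predictor_cols else np.empty((len(df), 0))
    Y = numeric(outcome_col)
    if membership_col is not None:
        R = numeric(membership_col)
    else:
        R = np.zeros(len(df))
    return Cohort(X, Y, R, tuple(predictor_cols))


def write_cohort(
    cohort: Cohort, path, outcome_col: str = "y", membership_col: str = "R"
) -> None:
    """Write a cohort as CSV; continuous values keep 12 significant digits."""
    cohort.to_frame(outcome_col, membership_col).to_csv(
        path, index=False, float_format="%.12g"
    )


def apply_split(cohort: Cohort, rule: SplitRule, seed: int | None = None) -> Cohort:
    """Assign source/target membership by a :class:`SplitRule`.

    Rows falling in neither range are dropped. Rows eligible for both ranges
    are allocated to the target set first, then source sampling proceeds from
    the remainder, so no row is ever used twice. Subsampling (when
    ``rule.subsample_sizes`` is given) is without replacement and
    deterministic under a fixed ``seed``.
    """
    values = cohort.column(rule.variable)
    src_ok, tgt_ok = rule.eligibility(values)
    rng = np.random.default_rng(seed)

    def draw(mask: np.ndarray, size: int | None, label: str) -> np.ndarray:
        idx = np.flatnonzero(mask)
        if size is None:
            return idx
        if size > idx.size:
            raise SizeError(
                f"requested {label} subsample of {size} but only {idx.size} eligible rows"
            )
        return rng.choice(idx, size=size, replace=False)

    s_req, n_req = rule.subsample_sizes if rule.subsample_sizes else (None, None)
    tgt_idx = draw(tgt_ok, n_req, "target")
    src_pool = src_ok.copy()
    src_pool[tgt_idx] = False  # target claims overlap rows first
    src_idx = draw(src_pool, s_req, "source")

    keep = np.sort(np.concatenate([src_idx, tgt_idx]))
    R = np.zeros(cohort.N, dtype=int)
    R[src_idx] = 1
    return Cohort(cohort.X[keep], cohort.Y[keep], R[keep], cohort.predictor_names)
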