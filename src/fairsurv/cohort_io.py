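"""Data model and I/O for right-censored multi-group survival cohorts.

The universal container is :class:`SurvivalCohort`: per-subject follow-up
time, event indicator (1 = event observed, 0 = censored), an integer
sensitive-attribute group label in ``1..K``, and a numeric covariate matrix.
The sensitive attribute is deliberately kept out of the covariate matrix:
it is used only by fairness-aware losses and by group-stratified metrics,
never as a predictor.

Categorical covariates are one-hot encoded with missing values modelled as a
distinct category (an extra indicator column) rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("fairsurv")

MISSING_TOKENS = ("", "NA")
_MISSING_LEVEL = "missing"


class SchemaError(ValueError):
    """A mandatory column is absent or mis-declared."""


class CohortValidationError(ValueError):
    """Cohort data violate a structural invariant (e.g. nonpositive time)."""


@dataclass(frozen=True)
class SurvivalCohort:
    """Immutable container for a censored, group-labelled survival dataset.

    Attributes
    ----------
    time : (n,) float array, strictly positive follow-up times.
    event : (n,) int array in {0, 1}; 1 means the event was observed.
    group : (n,) int array with labels in ``1..K``; no missing labels.
    covariates : (n, p) float matrix, fully finite.
    feature_names : p column names for ``covariates``.
    group_names : K display names; ``group_names[k-1]`` names label ``k``.
    """

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray
    covariates: np.ndarray
    feature_names: tuple[str, ...]
    group_names: tuple[str, ...]

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        group = np.asarray(self.group)
        X = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if X.shape[0] != time.shape[0]:
            X = X.reshape(time.shape[0], -1)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int64))
        object.__setattr__(self, "group", group.astype(np.int64))
        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "group_names", tuple(self.group_names))
        self._validate()

    def _validate(self) -> None:
        n = self.time.shape[0]
        if n == 0:
            raise CohortValidationError("empty cohort")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            bad = int(np.flatnonzero(~(np.isfinite(self.time) & (self.time > 0)))[0])
            raise CohortValidationError(
                f"row {bad}: follow-up time must be strictly positive and finite "
                f"(got {self.time[bad]!r})"
            )
        if not np.isin(self.event, (0, 1)).all():
            raise CohortValidationError("event indicator must be 0 or 1")
        K = len(self.group_names)
        if self.group.shape != (n,) or np.any(self.group < 1) or np.any(self.group > K):
            raise CohortValidationError(f"group labels must lie in 1..{K}")
        if self.covariates.shape != (n, len(self.feature_names)):
            raise CohortValidationError(
                f"covariates shape {self.covariates.shape} does not match "
                f"n={n}, p={len(self.feature_names)}"
            )
        if not np.all(np.isfinite(self.covariates)):
            raise CohortValidationError("covariates contain non-finite values")

    # -- convenience ------------------------------------------------------

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalCohort":
        idx = np.asarray(idx)
        return SurvivalCohort(
            time=self.time[idx],
            event=self.event[idx],
            group=self.group[idx],
            covariates=self.covariates[idx],
            feature_names=self.feature_names,
            group_names=self.group_names,
        )

    def to_frame(self, schema: "CohortSchema | None" = None) -> pd.DataFrame:
        schema = schema or CohortSchema()
        df = pd.DataFrame(self.covariates, columns=list(self.feature_names))
        df.insert(0, schema.group_col, self.group)
        df.insert(0, schema.event_col, self.event)
        df.insert(0, schema.time_col, self.time)
        return df


@dataclass(frozen=True)
class CohortSchema:
    """Names of the mandatory columns and the declared categorical covariates."""

    time_col: str = "time"
    event_col: str = "event"
    group_col: str = "group"
    categorical_cols: tuple[str, ...] = ()


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation split stratified on the event indicator."""

    train_fraction: float = 0.8
    seed: int = 0
    stratify_on_event: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Covariate encoding
# ---------------------------------------------------------------------------

def encode_covariates(
    raw: pd.DataFrame, categorical_cols: tuple[str, ...] | list[str] = ()
) -> tuple[np.ndarray, list[str]]:
    """One-hot encode ``categorical_cols``, passing other columns through.

    Missing entries in a categorical column become a distinct ``missing``
    level with its own indicator column (no imputation). Continuous columns
    must parse as numbers and contain no missing values. Column order is
    deterministic: raw column order, with each categorical expanding to its
    sorted levels (missing last).
    """
    categorical_cols = tuple(categorical_cols)
    unknown = set(categorical_cols) - set(raw.columns)
    if unknown:
        raise SchemaError(f"declared categorical columns not in table: {sorted(unknown)}")
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for col in raw.columns:
        s = raw[col]
        if col in categorical_cols:
            vals = s.astype("object").where(~s.isna(), _MISSING_LEVEL)
            vals = vals.replace({t: _MISSING_LEVEL for t in MISSING_TOKENS})
            vals = vals.astype(str)
            levels = sorted(v for v in vals.unique() if v != _MISSING_LEVEL)
            if (vals == _MISSING_LEVEL).any():
                levels.append(_MISSING_LEVEL)
            for lev in levels:
                blocks.append((vals == lev).to_numpy(dtype=float)[:, None])
                names.append(f"{col}={lev}")
        else:
            numeric = pd.to_numeric(s, errors="coerce")
            bad = numeric.isna() & ~s.isna()
            if bad.any():
                tok = s[bad].iloc[0]
                raise SchemaError(
                    f"continuous column {col!r} contains non-numeric token {tok!r}"
                )
            if numeric.isna().any():
                raise CohortValidationError(
                    f"continuous column {col!r} has missing values; continuous "
                    "covariates must be complete (missing-as-category applies "
                    "to categorical columns only)"
                )
            blocks.append(numeric.to_numpy(dtype=float)[:, None])
            names.append(str(col))
    if not blocks:
        return np.empty((len(raw), 0)), names
    return np.hstack(blocks), names


# ---------------------------------------------------------------------------
# CSV in / out
# ---------------------------------------------------------------------------

def read_cohort(path, schema: CohortSchema | None = None) -> SurvivalCohort:
    """Read a cohort CSV (comma-separated, header row, UTF-8, ``.`` decimal).

    Mandatory columns are named by ``schema``; every other column is a
    covariate. Rows with a missing time, event, or group are rejected.
    """
    schema = schema or CohortSchema()
    df = pd.read_csv(path, na_values=list(MISSING_TOKENS), keep_default_na=False)
    for col in (schema.time_col, schema.event_col, schema.group_col):
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    mandatory = df[[schema.time_col, schema.event_col, schema.group_col]]
    if mandatory.isna().any().any():
        bad = int(np.flatnonzero(mandatory.isna().any(axis=1))[0])
        raise CohortValidationError(
            f"row {bad}: missing time/event/group value; rows with incomplete "
            "outcome or sensitive-attribute data are rejected"
        )
    time = pd.to_numeric(df[schema.time_col]).to_numpy(dtype=float)
    event = pd.to_numeric(df[schema.event_col]).to_numpy()
    raw_group = df[schema.group_col]
    if pd.api.types.is_numeric_dtype(raw_group):
        labels = raw_group.astype(int)
        names = [str(g) for g in sorted(labels.unique())]
        code = {int(g): i + 1 for i, g in enumerate(sorted(labels.unique()))}
        group = labels.map(code).to_numpy()
    else:
        names = sorted(raw_group.astype(str).unique())
        code = {g: i + 1 for i, g in enumerate(names)}
        group = raw_group.astype(str).map(code).to_numpy()
    covariate_df = df.drop(columns=[schema.time_col, schema.event_col, schema.group_col])
    X, feature_names = encode_covariates(covariate_df, schema.categorical_cols)
    return SurvivalCohort(
        time=time,
        event=event,
        group=group,
        covariates=X,
        feature_names=feature_names,
        group_names=names,
    )


def write_cohort(cohort: SurvivalCohort, path, schema: CohortSchema | None = None) -> None:
    """Write a cohort to CSV; ``read_cohort`` on the result round-trips."""
    cohort.to_frame(schema).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_cohort(
    cohort: SurvivalCohort, spec: SplitSpec
) -> tuple[SurvivalCohort, SurvivalCohort]:
    """Partition a cohort into train/validation, stratified on event status.

    Within each event stratum the subjects are shuffled with the spec's seed
    and split at ``round(train_fraction * n_stratum)``, so the event rates of
    the two partitions match the cohort rate up to integer rounding.
    """
    if cohort.n_events < 2 or (cohort.n - cohort.n_events) < 2:
        raise CohortValidationError(
            "cohort too small to stratify: need >=2 events and >=2 censored subjects"
        )
    rng = np.random.default_rng(spec.seed)
    train_idx: list[np.ndarray] = []
    valid_idx: list[np.ndarray] = []
    strata = (
        [cohort.event == 1, cohort.event == 0]
        if spec.stratify_on_event
        else [np.ones(cohort.n, dtype=bool)]
    )
    for mask in strata:
        idx = rng.permutation(np.flatnonzero(mask))
        cut = int(round(spec.train_fraction * idx.size))
        cut = min(max(cut, 1), idx.size - 1)  # both sides non-empty per stratum
        train_idx.append(idx[:cut])
        valid_idx.append(idx[cut:])
    train = np.sort(np.concatenate(train_idx))
    valid = np.sort(np.concatenate(valid_idx))
    return cohort.subset(train), cohort.subset(valid)


# ---------------------------------------------------------------------------
# Standardization (training statistics only; applied to validation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Standardizer:
    """Z-scoring of continuous columns, fit on the training split only."""

    columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    feature_names: tuple[str, ...] = field(default=())

    def apply(self, cohort: SurvivalCohort) -> SurvivalCohort:
        if cohort.feature_names != self.feature_names:
            raise CohortValidationError("feature names differ from the fit cohort")
        X = cohort.covariates.copy()
        cols = [cohort.feature_names.index(c) for c in self.columns]
        X[:, cols] = (X[:, cols] - self.means) / self.sds
        return replace(cohort, covariates=X)

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(
            columns=tuple(d["columns"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            feature_names=tuple(d["feature_names"]),
        )


def fit_standardizer(
    train: SurvivalCohort, columns: list[str] | None = None
) -> Standardizer:
    """Fit a z-scorer on the training split.

    ``columns=None`` selects every column that is not a pure 0/1 indicator.
    Constant columns keep sd 1 to stay finite.
    """
    if columns is None:
        X = train.covariates
        is_indicator = np.all(np.isin(X, (0.0, 1.0)), axis=0)
        columns = [n for n, ind in zip(train.feature_names, is_indicator) if not ind]
    cols = [train.feature_names.index(c) for c in columns]
    means = train.covariates[:, cols].mean(axis=0)
    sds = train.covariates[:, cols].std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    logger.info(
        "standardizer fit on %d continuous columns: means=%s sds=%s",
        len(columns), np.round(means, 4).tolist(), np.round(sds, 4).tolist(),
    )
    return Standardizer(
        columns=tuple(columns),
        means=means,
        sds=sds,
        feature_names=train.feature_names,
    )
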