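"""Missingness filters, mean imputation and standardization.

The pipeline order is fixed: drop samples with too many missing feature
values, drop features with too high a missing rate, then impute the rest
with feature means and standardize every column (and the response) to
mean 0, variance 1.  Scaling parameters are retained so held-out data
can be transformed on the training scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CohortPair

__all__ = [
    "RawTable",
    "ColumnScaler",
    "ResponseScaler",
    "ProcessedTable",
    "filter_samples",
    "filter_features",
    "impute_and_standardize",
    "standardize_response",
    "flag_response_outliers",
    "preprocess_cohort",
    "make_cohort_pair",
    "CohortData",
]

COLUMN_KINDS = ("mutation", "expression", "copy_number", "tissue")


@dataclass(frozen=True)
class RawTable:
    """A feature matrix with possible missing entries (NaN).

    ``col_kind`` tags every column as mutation / expression /
    copy_number / tissue; tissue columns must be one-hot indicators.
    """

    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    col_kind: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        row_ids = tuple(str(r) for r in self.row_ids)
        col_ids = tuple(str(c) for c in self.col_ids)
        col_kind = tuple(str(k) for k in self.col_kind)
        if len(row_ids) != values.shape[0]:
            raise ValueError("row_ids length must match the number of rows")
        if len(col_ids) != values.shape[1]:
            raise ValueError("col_ids length must match the number of columns")
        if len(col_kind) != values.shape[1]:
            raise ValueError("col_kind length must match the number of columns")
        if len(set(row_ids)) != len(row_ids):
            raise ValueError("row_ids must be unique")
        if len(set(col_ids)) != len(col_ids):
            raise ValueError("col_ids must be unique")
        bad = set(col_kind) - set(COLUMN_KINDS)
        if bad:
            raise ValueError(f"unknown column kinds: {sorted(bad)}")
        tissue = [j for j, k in enumerate(col_kind) if k == "tissue"]
        if tissue:
            tv = values[:, tissue]
            observed = tv[~np.isnan(tv)]
            if observed.size and not np.all(np.isin(observed, (0.0, 1.0))):
                raise ValueError("tissue columns must be one-hot indicators")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", row_ids)
        object.__setattr__(self, "col_ids", col_ids)
        object.__setattr__(self, "col_kind", col_kind)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def take_rows(self, idx) -> "RawTable":
        idx = np.asarray(idx, dtype=int)
        return RawTable(
            self.values[idx],
            tuple(self.row_ids[i] for i in idx),
            self.col_ids,
            self.col_kind,
        )

    def take_cols(self, idx) -> "RawTable":
        idx = np.asarray(idx, dtype=int)
        return RawTable(
            self.values[:, idx],
            self.row_ids,
            tuple(self.col_ids[i] for i in idx),
            tuple(self.col_kind[i] for i in idx),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_ids), columns=list(self.col_ids)
        )


def filter_samples(
    table: RawTable, max_missing_count: int = 10_000
) -> tuple[RawTable, list[str]]:
    """Drop rows whose missing-entry count exceeds the threshold (strict >)."""
    counts = np.isnan(table.values).sum(axis=1)
    keep = np.flatnonzero(counts <= max_missing_count)
    removed = [table.row_ids[i] for i in np.flatnonzero(counts > max_missing_count)]
    if keep.size == 0:
        raise ValueError(
            f"all {table.shape[0]} samples exceed {max_missing_count} missing values"
        )
    return table.take_rows(keep), removed


def filter_features(
    table: RawTable, max_missing_rate: float = 0.3
) -> tuple[RawTable, list[str]]:
    """Drop columns whose missing fraction exceeds the threshold (strict >)."""
    n = table.shape[0]
    rates = np.isnan(table.values).sum(axis=0) / max(n, 1)
    keep = np.flatnonzero(rates <= max_missing_rate)
    removed = [table.col_ids[j] for j in np.flatnonzero(rates > max_missing_rate)]
    if keep.size == 0:
        raise ValueError(
            f"all {table.shape[1]} features exceed missing rate {max_missing_rate}"
        )
    return table.take_cols(keep), removed


@dataclass(frozen=True)
class ColumnScaler:
    """Training-scale imputation and standardization parameters."""

    col_ids: tuple[str, ...]
    impute_mean: np.ndarray
    center: np.ndarray
    scale: np.ndarray

    def transform(self, values: np.ndarray, col_ids) -> np.ndarray:
        """Impute and standardize new rows using the training parameters."""
        values = np.asarray(values, dtype=float)
        col_ids = [str(c) for c in col_ids]
        pos = {c: j for j, c in enumerate(col_ids)}
        missing = [c for c in self.col_ids if c not in pos]
        if missing:
            raise ValueError(f"columns absent from new data: {missing[:5]}")
        idx = [pos[c] for c in self.col_ids]
        out = values[:, idx].copy()
        nan = np.isnan(out)
        if nan.any():
            out[nan] = np.broadcast_to(self.impute_mean, out.shape)[nan]
        return (out - self.center) / self.scale


@dataclass(frozen=True)
class ResponseScaler:
    center: float
    scale: float

    def transform(self, y) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.center) / self.scale

    def inverse(self, y) -> np.ndarray:
        return np.asarray(y, dtype=float) * self.scale + self.center


@dataclass(frozen=True)
class ProcessedTable:
    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    col_kind: tuple[str, ...]
    scaler: ColumnScaler


def impute_and_standardize(table: RawTable) -> ProcessedTable:
    """Mean-impute remaining gaps and scale columns to mean 0, variance 1.

    Variances use the population (1/n) convention so the output is
    exactly mean-0/variance-1.  Columns that are constant after
    imputation carry no information and are dropped with a warning.
    """
    values = table.values.copy()
    n, p = values.shape
    col_means = np.nanmean(
        np.where(np.isnan(values), np.nan, values), axis=0
    )
    if np.isnan(col_means).any():
        raise ValueError(
            "some columns are entirely missing; run filter_features first"
        )
    nan = np.isnan(values)
    if nan.any():
        values[nan] = np.broadcast_to(col_means, values.shape)[nan]
    center = values.mean(axis=0)
    scale = values.std(axis=0)  # ddof=0
    keep = np.flatnonzero(scale > 0)
    if keep.size < p:
        dropped = [table.col_ids[j] for j in np.flatnonzero(scale == 0)]
        warnings.warn(
            f"dropping {p - keep.size} zero-variance column(s): {dropped[:5]}",
            stacklevel=2,
        )
    values = (values[:, keep] - center[keep]) / scale[keep]
    col_ids = tuple(table.col_ids[j] for j in keep)
    scaler = ColumnScaler(
        col_ids=col_ids,
        impute_mean=col_means[keep],
        center=center[keep],
        scale=scale[keep],
    )
    return ProcessedTable(
        values=values,
        row_ids=table.row_ids,
        col_ids=col_ids,
        col_kind=tuple(table.col_kind[j] for j in keep),
        scaler=scaler,
    )


def standardize_response(y) -> tuple[np.ndarray, ResponseScaler]:
    y = np.asarray(y, dtype=float).ravel()
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    center = float(y.mean())
    scale = float(y.std())
    if scale == 0:
        raise ValueError("degenerate data: response has zero variance")
    scaler = ResponseScaler(center=center, scale=scale)
    return scaler.transform(y), scaler


def flag_response_outliers(y, z_threshold: float) -> np.ndarray:
    """Optional quality-control hook: robust z-score rule on the response.

    Returns a boolean mask of rows flagged as outliers
    (|y - median| / (MAD / 0.6745) > z_threshold).  Disabled by default
    in the pipeline; the original study's outlier criterion is not
    specified, so this is an explicit, configurable stand-in.
    """
    y = np.asarray(y, dtype=float).ravel()
    med = np.median(y)
    mad = np.median(np.abs(y - med))
    if mad == 0:
        return np.zeros(y.size, dtype=bool)
    z = 0.6745 * np.abs(y - med) / mad
    return z > z_threshold


@dataclass(frozen=True)
class CohortData:
    """One cohort after the full preprocessing pipeline."""

    X: np.ndarray
    y: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    col_kind: tuple[str, ...]
    feature_scaler: ColumnScaler
    response_scaler: ResponseScaler
    log: dict = field(default_factory=dict)


def preprocess_cohort(
    features: RawTable,
    response: np.ndarray,
    *,
    max_missing_count: int = 10_000,
    max_missing_rate: float = 0.3,
    outlier_z: float | None = None,
    include_kinds: tuple[str, ...] | None = None,
) -> CohortData:
    """Run the fixed pipeline on one cohort.

    ``response`` must align with ``features.row_ids``.  ``include_kinds``
    optionally restricts the feature set (e.g. excluding copy-number
    columns).  ``outlier_z`` enables the optional robust-z response QC
    hook (off by default).
    """
    response = np.asarray(response, dtype=float).ravel()
    if response.size != features.shape[0]:
        raise ValueError("response length must match the number of feature rows")
    log: dict = {}
    if include_kinds is not None:
        keep = [j for j, k in enumerate(features.col_kind) if k in include_kinds]
        log["excluded_kinds"] = sorted(set(features.col_kind) - set(include_kinds))
        features = features.take_cols(keep)
    table, removed_rows = filter_samples(features, max_missing_count)
    keep_rows = [i for i, rid in enumerate(features.row_ids) if rid in set(table.row_ids)]
    response = response[keep_rows]
    log["removed_samples"] = removed_rows
    table, removed_cols = filter_features(table, max_missing_rate)
    log["removed_features"] = removed_cols
    if outlier_z is not None:
        mask = flag_response_outliers(response, outlier_z)
        if mask.any():
            keep = np.flatnonzero(~mask)
            log["removed_outliers"] = [table.row_ids[i] for i in np.flatnonzero(mask)]
            table = table.take_rows(keep)
            response = response[keep]
        else:
            log["removed_outliers"] = []
    processed = impute_and_standardize(table)
    y_std, response_scaler = standardize_response(response)
    return CohortData(
        X=processed.values,
        y=y_std,
        row_ids=processed.row_ids,
        col_ids=processed.col_ids,
        col_kind=processed.col_kind,
        feature_scaler=processed.scaler,
        response_scaler=response_scaler,
        log=log,
    )


def make_cohort_pair(g: CohortData, c: CohortData) -> CohortPair:
    """Assemble a CohortPair on the feature columns shared by both cohorts."""
    common = [cid for cid in g.col_ids if cid in set(c.col_ids)]
    if not common:
        raise ValueError("cohorts share no feature columns after preprocessing")
    g_pos = {cid: j for j, cid in enumerate(g.col_ids)}
    c_pos = {cid: j for j, cid in enumerate(c.col_ids)}
    gi = [g_pos[cid] for cid in common]
    ci = [c_pos[cid] for cid in common]
    return CohortPair(
        g.X[:, gi], g.y, c.X[:, ci], c.y, feature_names=tuple(common)
    )
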