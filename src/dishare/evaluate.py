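"""Test-error evaluation, boxplot summaries and the median/spread statistic.

Two test-error distributions are compared through their boxplots: the
distance between medians (DBM) is expressed as a fraction of the overall
visible spread (OVS), the distance from the lower quartile of one box to
the upper quartile of the other.  Disjoint interquartile ranges are
treated as automatically significant; otherwise a ratio above 0.20 (at
n around 100) flags a likely meaningful difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import core, screening
from .core import CohortPair, FitOptions, Formulation, SharedFit

__all__ = [
    "FiveNumberSummary",
    "BdmOvs",
    "MethodComparison",
    "mean_prediction_error",
    "five_number_summary",
    "bdm_ovs",
    "compare_methods",
    "training_split_sizes",
    "SIGNIFICANCE_RATIO",
]

SIGNIFICANCE_RATIO = 0.20


@dataclass(frozen=True)
class FiveNumberSummary:
    """Boxplot statistics: min, lower quartile, median, upper quartile, max."""

    min: float
    q1: float
    median: float
    q3: float
    max: float

    def __post_init__(self):
        vals = (self.min, self.q1, self.median, self.q3, self.max)
        if any(not np.isfinite(v) for v in vals):
            raise ValueError("summary values must be finite")
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError(f"summary is not monotone: {vals}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.min, self.q1, self.median, self.q3, self.max)


class BdmOvs(NamedTuple):
    ratio: float
    iqr_disjoint: bool


def mean_prediction_error(fit: SharedFit, X, y, mode: str = "as_G") -> float:
    """Mean squared prediction error on test rows (training scale)."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty test set")
    pred = core.predict_shared(fit, X, mode=mode)
    if pred.size != y.size:
        raise ValueError("X and y have different numbers of rows")
    return float(np.mean((y - pred) ** 2))


def five_number_summary(values) -> FiveNumberSummary:
    """Five-number summary with linear-interpolation quartiles."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("five_number_summary requires at least one value")
    if np.isnan(v).any():
        raise ValueError("values contain NaN")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return FiveNumberSummary(
        min=float(v.min()), q1=float(q1), median=float(med),
        q3=float(q3), max=float(v.max()),
    )


def bdm_ovs(
    summary_shared: FiveNumberSummary, summary_other: FiveNumberSummary
) -> BdmOvs:
    """Median distance over visible spread, with a disjoint-IQR flag.

    DBM = median(other) - median(shared); OVS = max of the two upper
    quartiles minus min of the two lower quartiles.  The ratio is
    rounded to 3 decimals.  Swapping the arguments flips the sign.
    """
    dbm = summary_other.median - summary_shared.median
    ovs = max(summary_shared.q3, summary_other.q3) - min(
        summary_shared.q1, summary_other.q1
    )
    if ovs == 0:
        raise ValueError("degenerate distributions: overall visible spread is zero")
    disjoint = (
        summary_shared.q3 < summary_other.q1
        or summary_other.q3 < summary_shared.q1
    )
    return BdmOvs(ratio=round(dbm / ovs, 3), iqr_disjoint=bool(disjoint))


def training_split_sizes(
    n: int, withheld_fraction: float = 0.2, scenario: int = 2
) -> tuple[int, int]:
    """(test size, training size) for the withheld cohort, floor rounding.

    Scenario 1 trains on 70% of the non-withheld portion; scenario 2 on
    all of it.
    """
    if scenario not in (1, 2):
        raise ValueError("scenario must be 1 or 2")
    n_test = int(np.floor(withheld_fraction * n))
    n_rest = n - n_test
    n_train = int(np.floor(0.7 * n_rest)) if scenario == 1 else n_rest
    return n_test, n_train


@dataclass(frozen=True)
class MethodComparison:
    """Per-split test errors, summaries and pairwise boxplot comparisons."""

    errors: pd.DataFrame  # one row per split, one column per method
    summaries: dict[str, FiveNumberSummary]
    comparisons: pd.DataFrame  # shared_beta vs each other method
    scenario: int
    test_cohort: str

    def method_names(self) -> list[str]:
        return list(self.errors.columns)


def _stratified_sample(rng, labels, size: int) -> np.ndarray:
    """Sample ``size`` indices, proportionally within label groups."""
    n = len(labels)
    labels = np.asarray(labels)
    chosen: list[int] = []
    groups = {}
    for lab in pd.unique(labels):
        idx = np.flatnonzero(labels == lab)
        groups[lab] = rng.permutation(idx)
        take = int(np.floor(size * idx.size / n))
        chosen.extend(groups[lab][:take].tolist())
        groups[lab] = groups[lab][take:]
    leftover = rng.permutation(np.concatenate(list(groups.values()))) if size - len(chosen) else []
    need = size - len(chosen)
    chosen.extend(np.asarray(leftover)[:need].astype(int).tolist())
    return np.array(sorted(chosen), dtype=int)


def compare_methods(
    data: CohortPair,
    withheld_fraction: float = 0.2,
    scenario: int = 2,
    n_splits: int = 200,
    seed=None,
    *,
    test_cohort: str = "G",
    screen_k: int | None = None,
    tissue_labels=None,
    formulation: Formulation | str = Formulation.F1,
    options: FitOptions | None = None,
) -> MethodComparison:
    """Repeated-split comparison of the shared model against baselines.

    Each split withholds ``withheld_fraction`` of the designated cohort
    as test data (stratified by ``tissue_labels`` when given), applies
    the scenario's training-size rule to the remainder, optionally
    screens features on the training data only, then fits the shared
    model and three baselines (withheld cohort alone, other cohort
    alone, pooled).  Test errors are recorded for the shared model in
    both prediction modes and for every baseline.
    """
    if test_cohort not in ("G", "C"):
        raise ValueError("test_cohort must be 'G' or 'C'")
    options = options or FitOptions()
    formulation = Formulation(formulation)
    if test_cohort == "G":
        X_t, y_t = data.X_G, data.y_G
        X_o, y_o = data.X_C, data.y_C
    else:
        X_t, y_t = data.X_C, data.y_C
        X_o, y_o = data.X_G, data.y_G
    n = X_t.shape[0]
    n_test, n_train = training_split_sizes(n, withheld_fraction, scenario)
    if n_test < 1 or n_train < 1:
        raise ValueError(
            f"cohort of size {n} is too small for a {withheld_fraction:.0%} split"
        )
    if tissue_labels is not None and len(tissue_labels) != n:
        raise ValueError("tissue_labels must match the withheld cohort size")

    ss = np.random.SeedSequence(seed)
    split_seeds = ss.spawn(n_splits)
    methods = ["shared_beta", "shared_beta_delta", "own_alone", "other_alone", "pooled"]
    rows = []
    for s in range(n_splits):
        child = split_seeds[s]
        rng = np.random.default_rng(child)
        if tissue_labels is not None:
            test_idx = _stratified_sample(rng, tissue_labels, n_test)
        else:
            test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
        rest = np.setdiff1d(np.arange(n), test_idx)
        if scenario == 1:
            train_idx = np.sort(rng.choice(rest, size=n_train, replace=False))
        else:
            train_idx = rest
        pair = CohortPair(
            X_t[train_idx], y_t[train_idx], X_o, y_o,
            feature_names=data.feature_names,
        )
        X_test, y_test = X_t[test_idx], y_t[test_idx]
        if screen_k is not None:
            scr = screening.sis_union_screen(pair, screen_k)
            pair = scr.screened
            X_test_s = X_test[:, scr.selected_indices]
        else:
            scr = None
            X_test_s = X_test
        fit_seeds = child.spawn(4)

        def _opts(i):
            return core.FitOptions(
                **{**options.__dict__, "seed": int(fit_seeds[i].generate_state(1)[0])}
            )

        shared = core.fit_shared(pair, formulation=formulation, options=_opts(0))
        own = core.fit_shared(
            _single_pair(pair, "G"), formulation=Formulation.F1, options=_opts(1)
        )
        other = core.fit_shared(
            _single_pair(pair, "C"), formulation=Formulation.F1, options=_opts(2)
        )
        pooled = core.fit_shared(
            _pooled_pair(pair), formulation=Formulation.F1, options=_opts(3)
        )
        rows.append(
            {
                "shared_beta": mean_prediction_error(shared, X_test_s, y_test, "as_G"),
                "shared_beta_delta": mean_prediction_error(
                    shared, X_test_s, y_test, "as_C"
                ),
                "own_alone": mean_prediction_error(own, X_test_s, y_test, "as_G"),
                "other_alone": mean_prediction_error(other, X_test_s, y_test, "as_G"),
                "pooled": mean_prediction_error(pooled, X_test_s, y_test, "as_G"),
            }
        )
    errors = pd.DataFrame(rows, columns=methods)
    summaries = {m: five_number_summary(errors[m].to_numpy()) for m in methods}
    comp_rows = []
    for m in methods:
        if m == "shared_beta":
            continue
        stat = bdm_ovs(summaries["shared_beta"], summaries[m])
        comp_rows.append(
            {
                "method": m,
                "bdm_ovs": stat.ratio,
                "iqr_disjoint": stat.iqr_disjoint,
                "significant": stat.iqr_disjoint
                or abs(stat.ratio) > SIGNIFICANCE_RATIO,
            }
        )
    comparisons = pd.DataFrame(comp_rows)
    return MethodComparison(
        errors=errors,
        summaries=summaries,
        comparisons=comparisons,
        scenario=scenario,
        test_cohort=test_cohort,
    )


def _single_pair(pair: CohortPair, side: str) -> CohortPair:
    """A one-cohort problem built from one side of a pair."""
    p = pair.p
    empty_X = np.zeros((0, p))
    empty_y = np.zeros(0)
    if side == "G":
        return CohortPair(
            pair.X_G, pair.y_G, empty_X, empty_y, feature_names=pair.feature_names
        )
    return CohortPair(
        pair.X_C, pair.y_C, empty_X, empty_y, feature_names=pair.feature_names
    )


def _pooled_pair(pair: CohortPair) -> CohortPair:
    """Both cohorts merged into a single dataset (no discrepancy term)."""
    X = np.vstack([pair.X_G, pair.X_C])
    y = np.concatenate([pair.y_G, pair.y_C])
    return CohortPair(
        X, y, np.zeros((0, pair.p)), np.zeros(0), feature_names=pair.feature_names
    )
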