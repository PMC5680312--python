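"""Penalty selection by ten-fold cross-validation over a lambda grid."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import core
from .core import CohortPair, Formulation, PenaltySpec

__all__ = ["CVResult", "make_lambda_grid", "cross_validate"]


@dataclass(frozen=True)
class CVResult:
    """Cross-validation surface over a (lambda1, lambda2) grid.

    ``best`` attains the minimum mean squared prediction error; exact
    ties are broken toward larger lambda1, then larger lambda2 (the
    sparser model).
    """

    grid: tuple[tuple[float, float], ...]
    cv_error: np.ndarray
    cv_se: np.ndarray
    best: tuple[float, float]
    fold_assignments: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda1": [g[0] for g in self.grid],
                "lambda2": [g[1] for g in self.grid],
                "cv_error": self.cv_error,
                "cv_se": self.cv_se,
            }
        )


def make_lambda_grid(
    data: CohortPair,
    n_lambda1: int = 20,
    lambda2_values=(0.001, 0.01, 0.1, 1.0),
    *,
    penalty: PenaltySpec | None = None,
    formulation: Formulation | str = Formulation.F1,
    loss: str = "symmetric",
    lambda1_min_ratio: float = 1e-3,
) -> list[tuple[float, float]]:
    """Log-spaced lambda1 path crossed with a fixed lambda2 set.

    lambda1 runs from ``lambda_max`` (the smallest value giving an
    all-zero solution under the current L1 weights) down to
    ``lambda1_min_ratio * lambda_max``.  The grid is ordered by lambda2
    group with lambda1 strictly decreasing within each group.
    """
    if n_lambda1 < 1:
        raise ValueError("n_lambda1 must be >= 1")
    y_all = np.concatenate([data.y_G, data.y_C])
    if y_all.size == 0 or np.ptp(y_all) == 0:
        raise ValueError("degenerate data: response has zero variance")
    formulation = Formulation(formulation)
    if penalty is None:
        penalty = PenaltySpec(0.0, 0.0)
    design = core.build_stacked_design(data, formulation, loss=loss)
    l1_w, _ = design.weight_vectors(penalty)
    lam_max = core.lambda_max_value(design.Z, design.y, l1_w)
    if not np.isfinite(lam_max) or lam_max <= 0:
        raise ValueError(
            "cannot build lambda grid: lambda_max is zero or infinite "
            "(check L1 weights)"
        )
    if n_lambda1 == 1:
        lam1 = np.array([lam_max])
    else:
        lam1 = np.geomspace(lam_max, lambda1_min_ratio * lam_max, n_lambda1)
    grid = [(float(l1), float(l2)) for l2 in lambda2_values for l1 in lam1]
    return grid


def _assign_folds(n_G: int, n_C: int, k: int, rng: np.random.Generator):
    """Per-cohort stratified folds; sizes differ by at most one."""
    if n_G + n_C < k:
        raise ValueError(f"k={k} exceeds the number of observations {n_G + n_C}")
    nonempty = [n for n in (n_G, n_C) if n > 0]
    if min(nonempty) < k and len(nonempty) == 2:
        warnings.warn(
            f"k={k} exceeds the smaller cohort size; "
            "falling back to non-stratified folds",
            stacklevel=3,
        )
        folds_all = np.empty(n_G + n_C, dtype=int)
        perm = rng.permutation(n_G + n_C)
        folds_all[perm] = np.arange(n_G + n_C) % k
        return folds_all[:n_G], folds_all[n_G:]
    out = []
    for n in (n_G, n_C):
        f = np.empty(n, dtype=int)
        if n:
            perm = rng.permutation(n)
            f[perm] = np.arange(n) % k
        out.append(f)
    return out[0], out[1]


def _path_predictions_sq_err(
    train: CohortPair,
    holdout: CohortPair,
    grid_by_l2,
    penalty: PenaltySpec,
    formulation: Formulation,
    loss: str,
    tol: float,
    kkt_tol: float,
    max_sweeps: int,
):
    """Sum of squared held-out errors for every grid pair, one fold."""
    design = core.build_stacked_design(train, formulation, loss=loss)
    l1_w, l2_w = design.weight_vectors(
        PenaltySpec(1.0, 1.0, r=penalty.r, omega=penalty.omega,
                    psi=penalty.psi, psi_G=penalty.psi_G, psi_C=penalty.psi_C)
    )
    active = np.isfinite(l1_w)
    Za = np.asfortranarray(design.Z[:, active])
    l1_a, l2_a = l1_w[active], l2_w[active]
    p = train.p
    results = {}
    for l2, l1_list in grid_by_l2.items():
        coef_a = np.zeros(Za.shape[1])
        for l1 in l1_list:
            sol = core.solve_weighted_enet(
                Za, design.y, l1_a, l2_a,
                lambda1=l1, lambda2=l2,
                tol=tol, kkt_tol=kkt_tol, max_sweeps=max_sweeps,
                coef_init=coef_a,
            )
            coef_a = sol.coef
            full = np.zeros(l1_w.size)
            full[active] = coef_a
            blocks = design.split_coef(full)
            if formulation == Formulation.F1:
                coef_G = blocks["beta"]
                coef_C = blocks["beta"] + blocks["delta"]
            else:
                coef_G = blocks["beta"] + blocks["delta_G"]
                coef_C = blocks["beta"] + blocks["delta_C"]
            sq = 0.0
            cnt = 0
            if holdout.n_G:
                res = holdout.y_G - holdout.X_G @ coef_G
                sq += float(res @ res)
                cnt += res.size
            if holdout.n_C:
                res = holdout.y_C - holdout.X_C @ coef_C
                sq += float(res @ res)
                cnt += res.size
            results[(l1, l2)] = (sq, cnt)
    return results


def cross_validate(
    data: CohortPair,
    grid,
    k: int = 10,
    seed=None,
    *,
    penalty: PenaltySpec | None = None,
    formulation: Formulation | str = Formulation.F1,
    loss: str = "symmetric",
    tol: float = 1e-7,
    kkt_tol: float = 1e-6,
    max_sweeps: int = 10_000,
) -> CVResult:
    """K-fold CV of the weighted elastic net over a penalty grid.

    Folds are drawn separately within each cohort so every fold keeps the
    global G:C proportion (both beta and delta stay estimable in each
    training split).  Held-out G rows are predicted with the G-side
    coefficients, held-out C rows with the C-side coefficients; the CV
    error pools squared errors over all held-out rows.
    """
    formulation = Formulation(formulation)
    grid = [(float(a), float(b)) for a, b in grid]
    if not grid:
        raise ValueError("empty penalty grid")
    if penalty is None:
        penalty = PenaltySpec(0.0, 0.0)
    rng = np.random.default_rng(seed)
    folds_G, folds_C = _assign_folds(data.n_G, data.n_C, k, rng)

    grid_by_l2: dict[float, list[float]] = {}
    for l1, l2 in grid:
        grid_by_l2.setdefault(l2, []).append(l1)
    for l2 in grid_by_l2:  # descend lambda1 for warm starts
        grid_by_l2[l2] = sorted(set(grid_by_l2[l2]), reverse=True)

    sq_sum = {pair: 0.0 for pair in grid}
    counts = {pair: 0 for pair in grid}
    fold_means = {pair: [] for pair in grid}
    for f in range(k):
        g_hold = np.flatnonzero(folds_G == f)
        c_hold = np.flatnonzero(folds_C == f)
        if g_hold.size + c_hold.size == 0:
            continue
        g_train = np.flatnonzero(folds_G != f)
        c_train = np.flatnonzero(folds_C != f)
        train = data.take_rows(g_train, c_train)
        holdout = data.take_rows(g_hold, c_hold)
        res = _path_predictions_sq_err(
            train, holdout, grid_by_l2, penalty, formulation, loss,
            tol, kkt_tol, max_sweeps,
        )
        for pair in grid:
            sq, cnt = res[pair]
            sq_sum[pair] += sq
            counts[pair] += cnt
            fold_means[pair].append(sq / cnt if cnt else np.nan)

    cv_error = np.array([sq_sum[pair] / counts[pair] for pair in grid])
    cv_se = np.array(
        [
            np.std(fold_means[pair], ddof=1) / np.sqrt(len(fold_means[pair]))
            if len(fold_means[pair]) > 1
            else np.nan
            for pair in grid
        ]
    )
    best_err = cv_error.min()
    tied = [grid[i] for i in np.flatnonzero(cv_error == best_err)]
    best = max(tied)  # larger lambda1 first, then larger lambda2

    assignments = pd.DataFrame(
        {
            "cohort": ["G"] * data.n_G + ["C"] * data.n_C,
            "row": list(range(data.n_G)) + list(range(data.n_C)),
            "fold": np.concatenate([folds_G, folds_C]).astype(int),
        }
    )
    return CVResult(
        grid=tuple(grid),
        cv_error=cv_error,
        cv_se=cv_se,
        best=best,
        fold_assignments=assignments,
    )
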