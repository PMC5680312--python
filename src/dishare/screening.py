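"""Sure independence screening applied per cohort, with union of the picks."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import CohortPair

__all__ = ["ScreenResult", "sis_union_screen"]


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of per-cohort marginal-correlation screening.

    ``selected_indices`` is the union of the per-cohort top-k sets in
    ascending feature order; ``per_cohort_rank`` holds the absolute
    Pearson correlation of every feature with each cohort's response
    (rows: G, C).  ``screened`` is the input pair restricted to the
    selected columns.
    """

    selected_indices: np.ndarray
    per_cohort_rank: np.ndarray
    screened: CohortPair


def _abs_marginal_corr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson correlation| per column; zero-variance columns get 0."""
    p = X.shape[1]
    if X.shape[0] < 2:
        return np.zeros(p)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    sy = np.sqrt(yc @ yc)
    out = np.zeros(p)
    ok = (sx > 0) & (sy > 0)
    if np.any(ok):
        out[ok] = np.abs(Xc[:, ok].T @ yc) / (sx[ok] * sy)
    return out


def _top_k(abs_corr: np.ndarray, k: int) -> np.ndarray:
    # ties at the k-th rank break toward the smaller feature index
    order = np.lexsort((np.arange(abs_corr.size), -abs_corr))
    return order[:k]


def sis_union_screen(data: CohortPair, k: int) -> ScreenResult:
    """Keep the union of each cohort's k most response-correlated features.

    Within each non-empty cohort, features are ranked by absolute Pearson
    correlation with that cohort's response (zero-variance features rank
    last with correlation 0); the per-cohort top-k sets are unioned,
    preserving ascending feature-index order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    p = data.p
    if k > p:
        warnings.warn(
            f"screening k={k} exceeds the number of features p={p}; "
            "selecting all features",
            stacklevel=2,
        )
        k = p
    rank = np.zeros((2, p))
    sel: set[int] = set()
    if data.n_G:
        rank[0] = _abs_marginal_corr(data.X_G, data.y_G)
        sel.update(_top_k(rank[0], k).tolist())
    if data.n_C:
        rank[1] = _abs_marginal_corr(data.X_C, data.y_C)
        sel.update(_top_k(rank[1], k).tolist())
    selected = np.array(sorted(sel), dtype=int)
    return ScreenResult(
        selected_indices=selected,
        per_cohort_rank=rank,
        screened=data.select_features(selected),
    )
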