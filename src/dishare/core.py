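"""Two-cohort penalized regression with shared and discrepancy coefficients.

Cohort G is modeled as ``y = X beta + eps`` and cohort C as
``y = X (beta + delta) + eps`` (formulation F1).  The alternative
formulation F2 gives each cohort its own offset from a common baseline:
``y = X (beta + delta_G) + eps`` on G and ``y = X (beta + delta_C) + eps``
on C.  Estimation minimizes a weighted elastic-net objective

    1/2 [RSS_G + RSS_C]
      + lambda1 (sum_j omega_j |beta_j| + r sum_j psi_j |delta_j|)
      + lambda2 (||beta||_2^2 + r ||delta||_2^2)

by cyclical coordinate descent on a stacked design.  Adaptive weights
(omega, psi) are reciprocals of absolute pilot elastic-net estimates; a
pilot estimate of exactly zero excludes the coordinate (infinite weight).

The optional ``loss="g_half_only"`` convention halves only the G residual
sum; the default halves both (symmetric).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

RSQRT2 = float(1.0 / np.sqrt(2.0))

__all__ = [
    "RSQRT2",
    "Formulation",
    "CohortPair",
    "PenaltySpec",
    "SharedFit",
    "NoiseModel",
    "FitOptions",
    "StackedDesign",
    "EnetSolution",
    "evaluate_objective",
    "objective_terms",
    "build_stacked_design",
    "solve_weighted_enet",
    "lambda_max_value",
    "kkt_violation",
    "fit_shared",
    "transform_formulations",
    "predict_shared",
]


class Formulation(str, enum.Enum):
    """Which parameterization of the two-cohort model is used."""

    F1 = "F1"  # beta shared by G; C carries beta + delta
    F2 = "F2"  # common baseline beta; cohort offsets delta_G, delta_C


def _as_float_matrix(x, name: str) -> np.ndarray:
    a = np.atleast_2d(np.asarray(x, dtype=float))
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got ndim={a.ndim}")
    return a


def _as_float_vector(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    return a


@dataclass(frozen=True)
class CohortPair:
    """Aligned design matrices and responses for cohorts G and C.

    Both matrices must share the same columns (features, identical order).
    One cohort may be empty (zero rows) to represent a single-dataset
    problem; at least one cohort must be non-empty.  Inputs must be free
    of missing values -- run preprocessing first.
    """

    X_G: np.ndarray
    y_G: np.ndarray
    X_C: np.ndarray
    y_C: np.ndarray
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self):
        X_G = _as_float_matrix(self.X_G, "X_G")
        X_C = _as_float_matrix(self.X_C, "X_C")
        y_G = _as_float_vector(self.y_G, "y_G")
        y_C = _as_float_vector(self.y_C, "y_C")
        if X_G.shape[0] == 0 and X_G.shape[1] == 0 and X_C.shape[1] > 0:
            X_G = X_G.reshape(0, X_C.shape[1])
        if X_C.shape[0] == 0 and X_C.shape[1] == 0 and X_G.shape[1] > 0:
            X_C = X_C.reshape(0, X_G.shape[1])
        if X_G.shape[1] != X_C.shape[1]:
            raise ValueError(
                f"X_G and X_C must have the same number of columns "
                f"(got {X_G.shape[1]} vs {X_C.shape[1]})"
            )
        if X_G.shape[0] != y_G.size:
            raise ValueError(
                f"X_G has {X_G.shape[0]} rows but y_G has {y_G.size} entries"
            )
        if X_C.shape[0] != y_C.size:
            raise ValueError(
                f"X_C has {X_C.shape[0]} rows but y_C has {y_C.size} entries"
            )
        if X_G.shape[0] == 0 and X_C.shape[0] == 0:
            raise ValueError("at least one cohort must contain observations")
        for name, arr in (("X_G", X_G), ("y_G", y_G), ("X_C", X_C), ("y_C", y_C)):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError(
                    f"{name} contains missing or non-finite values; "
                    "preprocessing must run first"
                )
        p = X_G.shape[1]
        names = self.feature_names
        if names is None:
            names = tuple(f"f{j}" for j in range(p))
        else:
            names = tuple(str(n) for n in names)
            if len(names) != p:
                raise ValueError(
                    f"feature_names has length {len(names)}, expected {p}"
                )
            if len(set(names)) != len(names):
                raise ValueError("feature_names must be unique")
        object.__setattr__(self, "X_G", X_G)
        object.__setattr__(self, "y_G", y_G)
        object.__setattr__(self, "X_C", X_C)
        object.__setattr__(self, "y_C", y_C)
        object.__setattr__(self, "feature_names", names)

    @property
    def p(self) -> int:
        return self.X_G.shape[1]

    @property
    def n_G(self) -> int:
        return self.X_G.shape[0]

    @property
    def n_C(self) -> int:
        return self.X_C.shape[0]

    def take_rows(self, g_idx, c_idx) -> "CohortPair":
        """Row-subset both cohorts (indices local to each cohort)."""
        g_idx = np.asarray(g_idx, dtype=int)
        c_idx = np.asarray(c_idx, dtype=int)
        return CohortPair(
            self.X_G[g_idx], self.y_G[g_idx],
            self.X_C[c_idx], self.y_C[c_idx],
            feature_names=self.feature_names,
        )

    def select_features(self, idx) -> "CohortPair":
        """Column-subset both cohorts to the given feature indices."""
        idx = np.asarray(idx, dtype=int)
        names = tuple(self.feature_names[j] for j in idx)
        return CohortPair(
            self.X_G[:, idx], self.y_G, self.X_C[:, idx], self.y_C,
            feature_names=names,
        )


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty strengths and per-coordinate L1 weights.

    ``omega`` weights the beta L1 term, ``psi`` the delta term (scaled by
    ``r``).  Entries may be ``inf``, which excludes the coordinate (its
    estimate is forced to zero).  ``psi_G``/``psi_C`` default to ``psi``
    for formulation F2.
    """

    lambda1: float
    lambda2: float
    r: float = RSQRT2
    omega: np.ndarray | None = None
    psi: np.ndarray | None = None
    psi_G: np.ndarray | None = None
    psi_C: np.ndarray | None = None

    def __post_init__(self):
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be nonnegative")
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be nonnegative")
        if not self.r > 0:
            raise ValueError("r must be positive")
        for name in ("omega", "psi", "psi_G", "psi_C"):
            w = getattr(self, name)
            if w is not None:
                w = np.asarray(w, dtype=float).ravel()
                if np.any(w < 0) or np.any(np.isnan(w)):
                    raise ValueError(f"{name} must be nonnegative")
                object.__setattr__(self, name, w)

    def _resolve(self, name: str, p: int) -> np.ndarray:
        w = getattr(self, name)
        if w is None and name in ("psi_G", "psi_C"):
            w = self.psi
        if w is None:
            return np.ones(p)
        if w.size != p:
            raise ValueError(f"{name} has length {w.size}, expected p={p}")
        return w


@dataclass(frozen=True)
class NoiseModel:
    """Additive-noise description: i.i.d. zero-mean errors of given variance."""

    variance: float = 1.0

    def __post_init__(self):
        if not self.variance > 0:
            raise ValueError("variance must be positive")


@dataclass(frozen=True)
class SharedFit:
    """Fitted coefficients of the two-cohort model.

    F1 carries ``beta``/``delta``; F2 carries ``beta``/``delta_G``/
    ``delta_C``.  ``objective_value`` is the penalized objective at the
    solution (on the formulation's own scale).
    """

    beta: np.ndarray
    delta: np.ndarray | None = None
    delta_G: np.ndarray | None = None
    delta_C: np.ndarray | None = None
    formulation: Formulation = Formulation.F1
    objective_value: float = np.nan
    converged: bool = True
    n_sweeps: int = 0
    lambda1: float | None = None
    lambda2: float | None = None
    r: float = RSQRT2
    feature_names: tuple[str, ...] | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=float).ravel()
        object.__setattr__(self, "beta", beta)
        p = beta.size
        if self.formulation == Formulation.F1:
            delta = self.delta
            if delta is None:
                raise ValueError("F1 fit requires delta")
            if self.delta_G is not None or self.delta_C is not None:
                raise ValueError("F1 fit must not carry delta_G/delta_C")
            delta = np.asarray(delta, dtype=float).ravel()
            if delta.size != p:
                raise ValueError("delta length must equal p")
            object.__setattr__(self, "delta", delta)
        elif self.formulation == Formulation.F2:
            if self.delta is not None:
                raise ValueError("F2 fit must not carry delta")
            if self.delta_G is None or self.delta_C is None:
                raise ValueError("F2 fit requires delta_G and delta_C")
            dG = np.asarray(self.delta_G, dtype=float).ravel()
            dC = np.asarray(self.delta_C, dtype=float).ravel()
            if dG.size != p or dC.size != p:
                raise ValueError("delta_G/delta_C length must equal p")
            object.__setattr__(self, "delta_G", dG)
            object.__setattr__(self, "delta_C", dC)
        else:  # pragma: no cover - enum guards this
            raise ValueError(f"unknown formulation {self.formulation!r}")

    @property
    def p(self) -> int:
        return self.beta.size

    @property
    def coef_G(self) -> np.ndarray:
        """Effective coefficient vector for cohort-G predictions."""
        if self.formulation == Formulation.F1:
            return self.beta
        return self.beta + self.delta_G

    @property
    def coef_C(self) -> np.ndarray:
        """Effective coefficient vector for cohort-C predictions."""
        if self.formulation == Formulation.F1:
            return self.beta + self.delta
        return self.beta + self.delta_C


# ---------------------------------------------------------------------------
# objective


def _check_loss(loss: str) -> str:
    if loss not in ("symmetric", "g_half_only"):
        raise ValueError(f"unknown loss convention {loss!r}")
    return loss


def _l1_block(weights: np.ndarray, coef: np.ndarray, label: str) -> float:
    infinite = ~np.isfinite(weights)
    if np.any(infinite & (coef != 0.0)):
        j = int(np.argmax(infinite & (coef != 0.0)))
        raise ValueError(
            f"coordinate {j} of {label} has infinite weight but nonzero value"
        )
    finite = ~infinite
    return float(np.sum(weights[finite] * np.abs(coef[finite])))


def objective_terms(
    data: CohortPair,
    penalty: PenaltySpec,
    *,
    beta,
    delta=None,
    delta_G=None,
    delta_C=None,
    loss: str = "symmetric",
) -> dict:
    """Additive decomposition of the penalized objective.

    Returns ``{"loss": ..., "l1": ..., "l2": ...}``.  Pass ``delta`` for
    formulation F1 or both ``delta_G``/``delta_C`` for F2.
    """
    _check_loss(loss)
    p = data.p
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.size != p:
        raise ValueError(f"beta has length {beta.size}, expected p={p}")
    if delta is not None and (delta_G is not None or delta_C is not None):
        raise ValueError("pass either delta (F1) or delta_G/delta_C (F2)")
    omega = penalty._resolve("omega", p)
    r = penalty.r
    if delta is not None:
        delta = np.asarray(delta, dtype=float).ravel()
        if delta.size != p:
            raise ValueError(f"delta has length {delta.size}, expected p={p}")
        coef_G, coef_C = beta, beta + delta
        psi = penalty._resolve("psi", p)
        l1 = _l1_block(omega, beta, "beta") + r * _l1_block(psi, delta, "delta")
        l2 = float(beta @ beta + r * (delta @ delta))
    elif delta_G is not None and delta_C is not None:
        dG = np.asarray(delta_G, dtype=float).ravel()
        dC = np.asarray(delta_C, dtype=float).ravel()
        if dG.size != p or dC.size != p:
            raise ValueError("delta_G/delta_C length must equal p")
        coef_G, coef_C = beta + dG, beta + dC
        psi_G = penalty._resolve("psi_G", p)
        psi_C = penalty._resolve("psi_C", p)
        l1 = (
            _l1_block(omega, beta, "beta")
            + r * _l1_block(psi_G, dG, "delta_G")
            + r * _l1_block(psi_C, dC, "delta_C")
        )
        l2 = float(beta @ beta + r * (dG @ dG + dC @ dC))
    else:
        raise ValueError("pass either delta (F1) or both delta_G and delta_C (F2)")
    res_G = data.y_G - data.X_G @ coef_G
    res_C = data.y_C - data.X_C @ coef_C
    rss_G = float(res_G @ res_G)
    rss_C = float(res_C @ res_C)
    if loss == "symmetric":
        loss_val = 0.5 * (rss_G + rss_C)
    else:
        loss_val = 0.5 * rss_G + rss_C
    return {
        "loss": loss_val,
        "l1": penalty.lambda1 * l1,
        "l2": penalty.lambda2 * l2,
    }


def evaluate_objective(
    data: CohortPair,
    penalty: PenaltySpec,
    *,
    beta,
    delta=None,
    delta_G=None,
    delta_C=None,
    loss: str = "symmetric",
) -> float:
    """Value of the penalized objective at the given coefficients."""
    terms = objective_terms(
        data, penalty, beta=beta, delta=delta, delta_G=delta_G,
        delta_C=delta_C, loss=loss,
    )
    return terms["loss"] + terms["l1"] + terms["l2"]


# ---------------------------------------------------------------------------
# stacked design


@dataclass(frozen=True)
class StackedDesign:
    """Single weighted least-squares reduction of the two-cohort model.

    ``Z`` stacks both cohorts; columns are grouped into coefficient
    blocks recorded in ``blocks`` (role -> column slice).  ``roles`` maps
    every column to its penalty role, ``feature_index`` to the original
    feature.  For the asymmetric loss convention C rows of ``Z``/``y``
    are pre-scaled by sqrt(2), recorded in ``row_scale``.
    """

    Z: np.ndarray
    y: np.ndarray
    formulation: Formulation
    p: int
    blocks: Mapping[str, slice]
    roles: tuple[str, ...]
    feature_index: np.ndarray
    row_scale: np.ndarray

    def weight_vectors(self, penalty: PenaltySpec) -> tuple[np.ndarray, np.ndarray]:
        """Per-column (L1, L2) weight vectors induced by a PenaltySpec."""
        p, r = self.p, penalty.r
        l1_parts, l2_parts = [], []
        for role in self.blocks:
            if role == "beta":
                l1_parts.append(penalty._resolve("omega", p))
                l2_parts.append(np.ones(p))
            elif role == "delta":
                l1_parts.append(r * penalty._resolve("psi", p))
                l2_parts.append(np.full(p, r))
            elif role == "delta_G":
                l1_parts.append(r * penalty._resolve("psi_G", p))
                l2_parts.append(np.full(p, r))
            elif role == "delta_C":
                l1_parts.append(r * penalty._resolve("psi_C", p))
                l2_parts.append(np.full(p, r))
        return np.concatenate(l1_parts), np.concatenate(l2_parts)

    def split_coef(self, coef: np.ndarray) -> dict[str, np.ndarray]:
        coef = np.asarray(coef, dtype=float).ravel()
        return {role: coef[sl].copy() for role, sl in self.blocks.items()}


def build_stacked_design(
    data: CohortPair,
    formulation: Formulation | str = Formulation.F1,
    loss: str = "symmetric",
) -> StackedDesign:
    """Reduce the two-cohort model to one penalized least-squares problem.

    F1 stacks ``[[X_G, 0], [X_C, X_C]]`` over coefficient blocks
    (beta, delta); F2 stacks ``[[X_G, X_G, 0], [X_C, 0, X_C]]`` over
    (beta, delta_G, delta_C).  The response is ``(y_G, y_C)``.
    """
    formulation = Formulation(formulation)
    _check_loss(loss)
    p, n_G, n_C = data.p, data.n_G, data.n_C
    zero_G = np.zeros((n_G, p))
    zero_C = np.zeros((n_C, p))
    if formulation == Formulation.F1:
        top = np.hstack([data.X_G, zero_G])
        bot = np.hstack([data.X_C, data.X_C])
        blocks = {"beta": slice(0, p), "delta": slice(p, 2 * p)}
    else:
        top = np.hstack([data.X_G, data.X_G, zero_G])
        bot = np.hstack([data.X_C, zero_C, data.X_C])
        blocks = {
            "beta": slice(0, p),
            "delta_G": slice(p, 2 * p),
            "delta_C": slice(2 * p, 3 * p),
        }
    Z = np.vstack([top, bot])
    y = np.concatenate([data.y_G, data.y_C])
    row_scale = np.ones(n_G + n_C)
    if loss == "g_half_only":
        # 1/2 RSS_G + RSS_C == 1/2 (RSS_G + ||sqrt(2) res_C||^2)
        row_scale[n_G:] = np.sqrt(2.0)
        Z = Z * row_scale[:, None]
        y = y * row_scale
    roles = []
    for role, sl in blocks.items():
        roles.extend([role] * (sl.stop - sl.start))
    feature_index = np.tile(np.arange(p), len(blocks))
    return StackedDesign(
        Z=np.asfortranarray(Z),
        y=y,
        formulation=formulation,
        p=p,
        blocks=blocks,
        roles=tuple(roles),
        feature_index=feature_index,
        row_scale=row_scale,
    )


# ---------------------------------------------------------------------------
# coordinate-descent solver

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@_njit(cache=True)
def _cd_kernel(Z, y, e1, e2, coef, tol, kkt_tol, max_sweeps):  # pragma: no cover
    n, m = Z.shape
    a = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        a[j] = s
    r = y - Z @ coef
    sweeps = 0
    converged = False
    cur_tol = tol
    while sweeps < max_sweeps:
        sweeps += 1
        max_change = 0.0
        for j in range(m):
            if not np.isfinite(e1[j]):
                continue
            denom = a[j] + 2.0 * e2[j]
            if denom <= 0.0:
                continue
            old = coef[j]
            rho = old * a[j]
            for i in range(n):
                rho += Z[i, j] * r[i]
            t = e1[j]
            if rho > t:
                new = (rho - t) / denom
            elif rho < -t:
                new = (rho + t) / denom
            else:
                new = 0.0
            if new != old:
                d = old - new
                for i in range(n):
                    r[i] += Z[i, j] * d
                coef[j] = new
                ad = abs(d)
                if ad > max_change:
                    max_change = ad
        if max_change <= cur_tol:
            if kkt_tol <= 0.0:
                converged = True
                break
            viol = 0.0
            for j in range(m):
                if not np.isfinite(e1[j]):
                    continue
                g = 2.0 * e2[j] * coef[j]
                for i in range(n):
                    g -= Z[i, j] * r[i]
                if coef[j] > 0.0:
                    v = abs(g + e1[j])
                elif coef[j] < 0.0:
                    v = abs(g - e1[j])
                else:
                    v = abs(g) - e1[j]
                    if v < 0.0:
                        v = 0.0
                if v > viol:
                    viol = v
            if viol <= kkt_tol:
                converged = True
                break
            cur_tol *= 0.1
            if cur_tol < 1e-15:
                break
    return sweeps, converged


def _soft(rho: float, t: float) -> float:
    if rho > t:
        return rho - t
    if rho < -t:
        return rho + t
    return 0.0


def _cd_python(Z, y, e1, e2, coef, tol, kkt_tol, max_sweeps, history=None):
    """Reference implementation mirroring the compiled kernel.

    Optionally records the stacked objective after every sweep.
    """
    n, m = Z.shape
    a = np.einsum("ij,ij->j", Z, Z)
    active = np.isfinite(e1)
    r = y - Z @ coef
    sweeps = 0
    converged = False
    cur_tol = tol

    def _obj():
        pen1 = float(np.sum(e1[active] * np.abs(coef[active])))
        pen2 = float(np.sum(e2 * coef**2))
        return 0.5 * float(r @ r) + pen1 + pen2

    while sweeps < max_sweeps:
        sweeps += 1
        max_change = 0.0
        for j in range(m):
            if not active[j]:
                continue
            denom = a[j] + 2.0 * e2[j]
            if denom <= 0.0:
                continue
            old = coef[j]
            rho = old * a[j] + Z[:, j] @ r
            new = _soft(rho, e1[j]) / denom
            if new != old:
                r += Z[:, j] * (old - new)
                coef[j] = new
                max_change = max(max_change, abs(old - new))
        if history is not None:
            history.append(_obj())
        if max_change <= cur_tol:
            if kkt_tol <= 0.0:
                converged = True
                break
            if kkt_violation_resid(Z, r, coef, e1, e2) <= kkt_tol:
                converged = True
                break
            cur_tol *= 0.1
            if cur_tol < 1e-15:
                break
    return sweeps, converged


def kkt_violation_resid(Z, resid, coef, e1, e2) -> float:
    """Max stationarity violation given a residual vector ``y - Z coef``."""
    active = np.isfinite(e1)
    g = -(Z[:, active].T @ resid) + 2.0 * e2[active] * coef[active]
    c = coef[active]
    t = e1[active]
    viol = np.where(
        c > 0, np.abs(g + t),
        np.where(c < 0, np.abs(g - t), np.maximum(np.abs(g) - t, 0.0)),
    )
    return float(viol.max()) if viol.size else 0.0


def kkt_violation(Z, y, coef, l1_weights, l2_weights, lambda1, lambda2) -> float:
    """Max stationarity violation of a candidate solution."""
    e1, e2 = _effective_weights(l1_weights, l2_weights, lambda1, lambda2)
    resid = y - Z @ coef
    return kkt_violation_resid(np.asarray(Z, dtype=float), resid, coef, e1, e2)


def _effective_weights(l1_weights, l2_weights, lambda1, lambda2):
    l1_weights = np.asarray(l1_weights, dtype=float).ravel()
    l2_weights = np.asarray(l2_weights, dtype=float).ravel()
    if np.any(l1_weights < 0) or np.any(l2_weights < 0):
        raise ValueError("penalty weights must be nonnegative")
    # lambda1 * inf must stay inf (excluded coordinate), not NaN
    e1 = np.where(np.isinf(l1_weights), np.inf, lambda1 * l1_weights)
    e2 = lambda2 * l2_weights
    return e1, e2


@dataclass(frozen=True)
class EnetSolution:
    coef: np.ndarray
    n_sweeps: int
    converged: bool
    history: tuple[float, ...] | None = None


def solve_weighted_enet(
    Z,
    y,
    l1_weights,
    l2_weights,
    *,
    lambda1: float,
    lambda2: float,
    tol: float = 1e-7,
    kkt_tol: float = 1e-6,
    max_sweeps: int = 10_000,
    coef_init=None,
    engine: str = "auto",
    return_history: bool = False,
) -> EnetSolution:
    """Cyclical coordinate descent for the weighted elastic net.

    Minimizes ``1/2 ||y - Z t||^2 + lambda1 sum_j w_j |t_j|
    + lambda2 sum_j v_j t_j^2``.  Coordinates with infinite L1 weight are
    excluded (held at zero).  Each update is the exact one-dimensional
    minimizer (soft-threshold form), so the objective never increases.
    Convergence requires the max coefficient change per sweep to fall
    below ``tol`` and, when ``kkt_tol > 0``, the stationarity conditions
    to hold within ``kkt_tol``.  Non-convergence is flagged, not raised.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if Z.ndim != 2 or Z.shape[0] != y.size:
        raise ValueError("Z and y have incompatible shapes")
    if np.isnan(Z).any() or np.isnan(y).any():
        raise ValueError("NaN in solver inputs")
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("lambda1 and lambda2 must be nonnegative")
    e1, e2 = _effective_weights(l1_weights, l2_weights, lambda1, lambda2)
    if e1.size != Z.shape[1] or e2.size != Z.shape[1]:
        raise ValueError("weight vectors must have one entry per column of Z")
    if coef_init is None:
        coef = np.zeros(Z.shape[1])
    else:
        coef = np.array(coef_init, dtype=float).ravel().copy()
        if coef.size != Z.shape[1]:
            raise ValueError("coef_init has wrong length")
        coef[~np.isfinite(e1)] = 0.0
    history: list[float] | None = [] if return_history else None
    use_numba = _HAVE_NUMBA and engine in ("auto", "numba") and not return_history
    if engine == "numba" and not _HAVE_NUMBA:
        raise RuntimeError("numba engine requested but numba is unavailable")
    if use_numba:
        Zf = np.asfortranarray(Z)
        n_sweeps, converged = _cd_kernel(
            Zf, y, e1, e2, coef, tol, kkt_tol, max_sweeps
        )
    else:
        n_sweeps, converged = _cd_python(
            Z, y, e1, e2, coef, tol, kkt_tol, max_sweeps, history=history
        )
    return EnetSolution(
        coef=coef,
        n_sweeps=int(n_sweeps),
        converged=bool(converged),
        history=tuple(history) if history is not None else None,
    )


def lambda_max_value(Z, y, l1_weights) -> float:
    """Smallest lambda1 for which the all-zero solution is stationary."""
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    w = np.asarray(l1_weights, dtype=float).ravel()
    grad = np.abs(Z.T @ y)
    finite = np.isfinite(w)
    vals = []
    if np.any(finite & (w > 0)):
        m = finite & (w > 0)
        vals.append(np.max(grad[m] / w[m]))
    if np.any(finite & (w == 0) & (grad > 0)):
        return float("inf")
    if not vals:
        return 0.0
    # tiny upward guard so the all-zero solution survives roundoff in
    # |Z'y| - lambda * w at the maximizing coordinate
    return float(max(vals)) * (1.0 + 1e-10)


# ---------------------------------------------------------------------------
# two-stage adaptive fit


@dataclass(frozen=True)
class FitOptions:
    """Knobs for the two-stage adaptive fit and its internal CV."""

    r: float = RSQRT2
    loss: str = "symmetric"
    cv_folds: int = 10
    n_lambda1: int = 20
    lambda2_values: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)
    lambda1_min_ratio: float = 1e-3
    pilot_lambdas: tuple[float, float] | None = None
    weight_floor: float | None = None
    tol: float = 1e-7
    kkt_tol: float = 1e-6
    max_sweeps: int = 10_000
    seed: int | None = None


def _adaptive_weights(pilot: np.ndarray, floor: float | None) -> np.ndarray:
    absval = np.abs(pilot)
    if floor is not None:
        absval = np.maximum(absval, floor)
    with np.errstate(divide="ignore"):
        return np.where(absval > 0, 1.0 / absval, np.inf)


def _solve_design(design, penalty, options, coef_init=None):
    l1_w, l2_w = design.weight_vectors(penalty)
    return solve_weighted_enet(
        design.Z, design.y, l1_w, l2_w,
        lambda1=penalty.lambda1, lambda2=penalty.lambda2,
        tol=options.tol, kkt_tol=options.kkt_tol,
        max_sweeps=options.max_sweeps, coef_init=coef_init,
    )


def _zero_fit(data, formulation, penalty, options, warns):
    p = data.p
    kwargs = dict(
        beta=np.zeros(p),
        formulation=formulation,
        converged=True,
        n_sweeps=0,
        lambda1=penalty.lambda1,
        lambda2=penalty.lambda2,
        r=penalty.r,
        feature_names=data.feature_names,
        warnings=tuple(warns),
    )
    if formulation == Formulation.F1:
        kwargs["delta"] = np.zeros(p)
        obj = evaluate_objective(
            data, penalty, beta=kwargs["beta"], delta=kwargs["delta"],
            loss=options.loss,
        )
    else:
        kwargs["delta_G"] = np.zeros(p)
        kwargs["delta_C"] = np.zeros(p)
        obj = evaluate_objective(
            data, penalty, beta=kwargs["beta"], delta_G=kwargs["delta_G"],
            delta_C=kwargs["delta_C"], loss=options.loss,
        )
    return SharedFit(objective_value=obj, **kwargs)


def fit_shared(
    data: CohortPair,
    lambda1: float | None = None,
    lambda2: float | None = None,
    *,
    formulation: Formulation | str = Formulation.F1,
    options: FitOptions | None = None,
) -> SharedFit:
    """Two-stage adaptive weighted elastic-net fit of the shared model.

    Stage one fits a non-adaptive elastic net (all L1 weights one) with
    its own cross-validated or supplied penalties; stage two forms
    adaptive weights as reciprocal absolute pilot estimates (exact zeros
    are excluded) and solves at ``(lambda1, lambda2)``.  When the final
    penalties are not supplied they are themselves chosen by
    cross-validation under the adaptive weights.

    An empty cohort degenerates to a single-dataset fit with zero
    discrepancy and a recorded warning.
    """
    from . import tuning  # local import: tuning depends on this module

    formulation = Formulation(formulation)
    options = options or FitOptions()
    if (lambda1 is None) != (lambda2 is None):
        raise ValueError("supply both lambda1 and lambda2 or neither")
    warns: list[str] = []

    exclude_delta = False
    if data.n_C == 0:
        warns.append("cohort C is empty; single-dataset fit with zero discrepancy")
        exclude_delta = True
    elif data.n_G == 0:
        warns.append("cohort G is empty; single-dataset fit with zero discrepancy")
        exclude_delta = True

    p = data.p
    inf_vec = np.full(p, np.inf)
    ones = np.ones(p)

    def _penalty(l1, l2, omega, psi_like):
        if formulation == Formulation.F1:
            return PenaltySpec(l1, l2, r=options.r, omega=omega, psi=psi_like)
        return PenaltySpec(
            l1, l2, r=options.r, omega=omega, psi_G=psi_like, psi_C=psi_like
        )

    seeds = np.random.SeedSequence(options.seed).spawn(2)

    # --- stage one: pilot (unit weights) -----------------------------------
    pilot_psi = inf_vec if exclude_delta else ones
    if options.pilot_lambdas is not None:
        l1p, l2p = options.pilot_lambdas
    else:
        pilot_pen = _penalty(0.0, 0.0, ones, pilot_psi)
        grid = tuning.make_lambda_grid(
            data,
            n_lambda1=options.n_lambda1,
            lambda2_values=options.lambda2_values,
            penalty=pilot_pen,
            formulation=formulation,
            loss=options.loss,
            lambda1_min_ratio=options.lambda1_min_ratio,
        )
        cv = tuning.cross_validate(
            data, grid, k=options.cv_folds,
            seed=seeds[0].generate_state(1)[0],
            penalty=pilot_pen, formulation=formulation, loss=options.loss,
            tol=options.tol, kkt_tol=options.kkt_tol,
            max_sweeps=options.max_sweeps,
        )
        l1p, l2p = cv.best
    design = build_stacked_design(data, formulation, loss=options.loss)
    pilot_pen = _penalty(l1p, l2p, ones, pilot_psi)
    pilot = _solve_design(design, pilot_pen, options)
    pilot_blocks = design.split_coef(pilot.coef)

    # --- adaptive weights ---------------------------------------------------
    omega = _adaptive_weights(pilot_blocks["beta"], options.weight_floor)
    if formulation == Formulation.F1:
        psi_like = (
            inf_vec if exclude_delta
            else _adaptive_weights(pilot_blocks["delta"], options.weight_floor)
        )
        psi_pair = (psi_like,)
    else:
        if exclude_delta:
            psi_pair = (inf_vec, inf_vec)
        else:
            psi_pair = (
                _adaptive_weights(pilot_blocks["delta_G"], options.weight_floor),
                _adaptive_weights(pilot_blocks["delta_C"], options.weight_floor),
            )

    def _final_penalty(l1, l2):
        if formulation == Formulation.F1:
            return PenaltySpec(l1, l2, r=options.r, omega=omega, psi=psi_pair[0])
        return PenaltySpec(
            l1, l2, r=options.r, omega=omega,
            psi_G=psi_pair[0], psi_C=psi_pair[1],
        )

    all_excluded = not np.any(np.isfinite(omega)) and all(
        not np.any(np.isfinite(w)) for w in psi_pair
    )
    if all_excluded:
        warns.append("all pilot estimates are zero; returning all-zero fit")
        penalty = _final_penalty(l1p if lambda1 is None else lambda1,
                                 l2p if lambda2 is None else lambda2)
        return _zero_fit(data, formulation, penalty, options, warns)

    # --- stage two: adaptive fit -------------------------------------------
    if lambda1 is None:
        template = _final_penalty(0.0, 0.0)
        grid = tuning.make_lambda_grid(
            data,
            n_lambda1=options.n_lambda1,
            lambda2_values=options.lambda2_values,
            penalty=template,
            formulation=formulation,
            loss=options.loss,
            lambda1_min_ratio=options.lambda1_min_ratio,
        )
        cv = tuning.cross_validate(
            data, grid, k=options.cv_folds,
            seed=seeds[1].generate_state(1)[0],
            penalty=template, formulation=formulation, loss=options.loss,
            tol=options.tol, kkt_tol=options.kkt_tol,
            max_sweeps=options.max_sweeps,
        )
        lambda1, lambda2 = cv.best
    penalty = _final_penalty(lambda1, lambda2)
    sol = _solve_design(design, penalty, options)
    blocks = design.split_coef(sol.coef)
    if not sol.converged:
        warns.append(f"solver did not converge within {options.max_sweeps} sweeps")
    common = dict(
        beta=blocks["beta"],
        formulation=formulation,
        converged=sol.converged,
        n_sweeps=sol.n_sweeps,
        lambda1=float(lambda1),
        lambda2=float(lambda2),
        r=options.r,
        feature_names=data.feature_names,
        warnings=tuple(warns),
    )
    if formulation == Formulation.F1:
        obj = evaluate_objective(
            data, penalty, beta=blocks["beta"], delta=blocks["delta"],
            loss=options.loss,
        )
        return SharedFit(delta=blocks["delta"], objective_value=obj, **common)
    obj = evaluate_objective(
        data, penalty, beta=blocks["beta"], delta_G=blocks["delta_G"],
        delta_C=blocks["delta_C"], loss=options.loss,
    )
    return SharedFit(
        delta_G=blocks["delta_G"], delta_C=blocks["delta_C"],
        objective_value=obj, **common,
    )


def transform_formulations(fit: SharedFit) -> SharedFit:
    """Convert a fit between the two model parameterizations.

    F2 -> F1 uses the identities ``beta_1 = beta_2 + delta_G`` and
    ``delta = delta_C - delta_G``.  The reverse direction is not unique;
    the ``delta_G = 0`` convention is used.  Fitted values on both
    cohorts are preserved exactly.  ``objective_value`` is carried over
    unchanged (it refers to the source formulation's penalty).
    """
    if fit.formulation == Formulation.F2:
        return replace(
            fit,
            beta=fit.beta + fit.delta_G,
            delta=fit.delta_C - fit.delta_G,
            delta_G=None,
            delta_C=None,
            formulation=Formulation.F1,
        )
    return replace(
        fit,
        beta=fit.beta.copy(),
        delta=None,
        delta_G=np.zeros(fit.p),
        delta_C=fit.delta.copy(),
        formulation=Formulation.F2,
    )


def predict_shared(fit: SharedFit, X, mode: str = "as_G") -> np.ndarray:
    """Predict responses for new rows using cohort-G or cohort-C effects.

    ``as_G`` applies the G-side coefficients (beta, or beta + delta_G for
    F2); ``as_C`` applies the C-side coefficients (beta + delta, or
    beta + delta_C).  Inputs must be on the training scale; there is no
    intercept.
    """
    if mode not in ("as_G", "as_C"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    X = _as_float_matrix(X, "X")
    if X.shape[1] != fit.p:
        raise ValueError(
            f"X has {X.shape[1]} columns but the fit has p={fit.p}"
        )
    coef = fit.coef_G if mode == "as_G" else fit.coef_C
    return X @ coef
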