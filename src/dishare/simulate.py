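"""Synthetic two-cohort data generator and the replicated comparison study.

Features are multivariate normal with AR(1) correlation; the shared
coefficient vector is block-sparse, the discrepancy vector is sparse
with support split between the shared support and its complement.
Cohort G follows ``y = x' beta + eps``, cohort C follows
``y = x' (beta + delta) + eps``; test data are drawn from the G-side
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import core, evaluate
from .core import CohortPair, FitOptions, NoiseModel
from .evaluate import FiveNumberSummary

__all__ = [
    "NoiseModel",
    "SimulationConfig",
    "SimulationTruth",
    "TestSet",
    "StudyResult",
    "ar1_covariance",
    "ar1_cholesky",
    "draw_truth",
    "generate_cohorts",
    "run_simulation_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are a reduced desk scale (p=200, 50 replicates); use
    :meth:`paper_scale` for the full-size setting (p=1000, 200
    replicates).  ``value_convention`` selects whether the second
    argument of the normal laws for coefficient values is read as a
    variance (default) or a standard deviation.
    """

    p: int = 200
    rho: float = 0.75
    n_blocks: int = 16
    block_size: int = 3
    beta_value_mean: float = 1.5
    beta_value_var: float = 1.0
    n_delta_on_support: int = 20
    n_delta_off_support: int = 10
    delta_value_mean: float = 0.0
    delta_value_var: float = 0.5
    noise_variance: float = 1.0
    n_G: int = 100
    n_C: int = 300
    n_test: int = 100
    n_replicates: int = 50
    seed: int = 0
    value_convention: str = "variance"  # or "sd"
    block_placement: str = "random"  # or "spaced"
    redraw_truth: bool = True
    # tuning knobs for the fits inside the study (desk-scale budget:
    # 5-fold CV and a short lambda path; paper_scale restores 10-fold)
    cv_folds: int = 5
    n_lambda1: int = 15
    lambda2_values: tuple[float, ...] = (0.01, 0.1)
    lambda1_min_ratio: float = 1e-3
    methods: tuple[str, ...] = ("shared", "individual_G", "individual_C", "pooled")

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.n_blocks * self.block_size > self.p:
            raise ValueError("beta support exceeds p")
        support = self.n_blocks * self.block_size
        if self.n_delta_on_support > support:
            raise ValueError("n_delta_on_support exceeds the beta support size")
        if self.n_delta_off_support > self.p - support:
            raise ValueError("n_delta_off_support exceeds the beta zero set")
        for name in ("beta_value_var", "delta_value_var", "noise_variance"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.value_convention not in ("variance", "sd"):
            raise ValueError("value_convention must be 'variance' or 'sd'")
        if self.block_placement not in ("random", "spaced"):
            raise ValueError("block_placement must be 'random' or 'spaced'")
        unknown = set(self.methods) - {
            "shared", "individual_G", "individual_C", "pooled"
        }
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def paper_scale(cls, **overrides) -> "SimulationConfig":
        base = dict(
            p=1000, n_replicates=200, cv_folds=10, n_lambda1=20,
            lambda2_values=(0.001, 0.01, 0.1, 1.0), lambda1_min_ratio=1e-3,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(variance=self.noise_variance)

    def _sd(self, var_field: float) -> float:
        return float(np.sqrt(var_field)) if self.value_convention == "variance" else float(var_field)


@dataclass(frozen=True)
class SimulationTruth:
    """True coefficient vectors and the feature-covariance factor."""

    beta_true: np.ndarray
    delta_true: np.ndarray
    covariance_root: np.ndarray
    rho: float

    def __post_init__(self):
        object.__setattr__(
            self, "beta_true", np.asarray(self.beta_true, dtype=float).ravel()
        )
        object.__setattr__(
            self, "delta_true", np.asarray(self.delta_true, dtype=float).ravel()
        )
        if self.beta_true.size != self.delta_true.size:
            raise ValueError("beta_true and delta_true must have equal length")


@dataclass(frozen=True)
class TestSet:
    X: np.ndarray
    y: np.ndarray


def ar1_covariance(p: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix with entries rho^|i-j| and unit diagonal."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def ar1_cholesky(p: int, rho: float) -> np.ndarray:
    """Lower-triangular factor L with L L' equal to the AR(1) covariance.

    Closed form: column 0 is rho^i; later columns are
    sqrt(1 - rho^2) * rho^(i-j).
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    i = np.arange(p)
    L = np.zeros((p, p))
    with np.errstate(invalid="ignore"):
        diff = i[:, None] - i[None, :]
    mask = diff >= 0
    vals = np.where(mask, rho ** np.where(mask, diff, 0), 0.0)
    L[:, 0] = vals[:, 0]
    if p > 1:
        L[:, 1:] = np.sqrt(1.0 - rho**2) * vals[:, 1:]
    return L


def _sample_ar1(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    """Draw n rows of the AR(1) Gaussian via the recursive construction."""
    z = rng.standard_normal((n, p))
    x = np.empty_like(z)
    x[:, 0] = z[:, 0]
    c = np.sqrt(1.0 - rho**2)
    for j in range(1, p):
        x[:, j] = rho * x[:, j - 1] + c * z[:, j]
    return x


def _block_starts(rng, p, n_blocks, block_size, placement) -> np.ndarray:
    if placement == "spaced":
        gap = p // n_blocks
        return np.arange(n_blocks) * gap
    # uniformly random non-overlapping runs: map sorted distinct draws
    free = p - n_blocks * (block_size - 1)
    picks = np.sort(rng.choice(free, size=n_blocks, replace=False))
    return picks + np.arange(n_blocks) * (block_size - 1)


def draw_truth(config: SimulationConfig, seed=None) -> SimulationTruth:
    """Draw block-sparse shared and sparse discrepancy coefficients.

    The beta support consists of ``n_blocks`` non-overlapping runs of
    ``block_size`` consecutive indices at uniformly random positions
    (adjacent runs may merge); nonzero beta values are normal around
    ``beta_value_mean``.  The delta support takes
    ``n_delta_on_support`` indices from the beta support and
    ``n_delta_off_support`` from its complement, with nonzero values
    normal around ``delta_value_mean``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = config.p
    starts = _block_starts(
        rng, p, config.n_blocks, config.block_size, config.block_placement
    )
    support = np.concatenate(
        [np.arange(s, s + config.block_size) for s in starts]
    )
    beta = np.zeros(p)
    beta[support] = rng.normal(
        config.beta_value_mean, config._sd(config.beta_value_var), support.size
    )
    zero_set = np.setdiff1d(np.arange(p), support)
    on = rng.choice(support, size=config.n_delta_on_support, replace=False)
    off = rng.choice(zero_set, size=config.n_delta_off_support, replace=False)
    delta = np.zeros(p)
    didx = np.concatenate([on, off])
    delta[didx] = rng.normal(
        config.delta_value_mean, config._sd(config.delta_value_var), didx.size
    )
    return SimulationTruth(
        beta_true=beta,
        delta_true=delta,
        covariance_root=ar1_cholesky(p, config.rho),
        rho=config.rho,
    )


def generate_cohorts(
    truth: SimulationTruth, config: SimulationConfig, seed=None
) -> tuple[CohortPair, TestSet]:
    """Sample training cohorts and a G-side test set from the truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = truth.beta_true.size
    sd_eps = np.sqrt(config.noise_variance)
    X_G = _sample_ar1(rng, config.n_G, p, truth.rho)
    y_G = X_G @ truth.beta_true + rng.normal(0.0, sd_eps, config.n_G)
    X_C = _sample_ar1(rng, config.n_C, p, truth.rho)
    y_C = X_C @ (truth.beta_true + truth.delta_true) + rng.normal(
        0.0, sd_eps, config.n_C
    )
    X_t = _sample_ar1(rng, config.n_test, p, truth.rho)
    y_t = X_t @ truth.beta_true + rng.normal(0.0, sd_eps, config.n_test)
    return CohortPair(X_G, y_G, X_C, y_C), TestSet(X=X_t, y=y_t)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass(frozen=True)
class StudyResult:
    """Raw per-replicate metrics and per-method summaries."""

    replicates: pd.DataFrame
    mse_summaries: Mapping[str, FiveNumberSummary]
    corr_summaries: Mapping[str, FiveNumberSummary]
    config: SimulationConfig

    def median_mse(self, method: str) -> float:
        return self.mse_summaries[method].median


_MSE_COLUMNS = {
    "shared": ("mse_shared_G", "mse_shared_C"),
    "individual_G": ("mse_individual_G",),
    "individual_C": ("mse_individual_C",),
    "pooled": ("mse_pooled",),
}


def _fit_options(config: SimulationConfig, seed) -> FitOptions:
    return FitOptions(
        cv_folds=config.cv_folds,
        n_lambda1=config.n_lambda1,
        lambda2_values=config.lambda2_values,
        lambda1_min_ratio=config.lambda1_min_ratio,
        seed=int(seed),
    )


def run_simulation_study(config: SimulationConfig, progress: bool = False) -> StudyResult:
    """Replicated comparison of the shared model against baselines.

    Each replicate draws fresh truth (unless ``redraw_truth`` is off)
    and cohorts, fits the shared model plus the requested single-dataset
    and pooled baselines with cross-validated penalties, and records
    test errors and recovery correlations: corr(estimated delta, true
    delta), corr(estimated beta, true beta), and the correlation of the
    difference of individual fits with the true delta.
    """
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = ss.spawn(config.n_replicates)
    fixed_truth = None if config.redraw_truth else draw_truth(config, ss.spawn(1)[0])
    rows = []
    for rep in range(config.n_replicates):
        child = rep_seeds[rep]
        truth_seed, data_seed, *fit_seeds = child.spawn(2 + 4)
        truth = fixed_truth or draw_truth(config, truth_seed)
        pair, test = generate_cohorts(truth, config, data_seed)
        row: dict = {"replicate": rep}
        fits: dict = {}
        if "shared" in config.methods:
            fit = core.fit_shared(
                pair, options=_fit_options(config, fit_seeds[0].generate_state(1)[0])
            )
            fits["shared"] = fit
            row["mse_shared_G"] = evaluate.mean_prediction_error(
                fit, test.X, test.y, "as_G"
            )
            row["mse_shared_C"] = evaluate.mean_prediction_error(
                fit, test.X, test.y, "as_C"
            )
            row["corr_beta_shared"] = _safe_corr(fit.beta, truth.beta_true)
            row["corr_delta_shared"] = _safe_corr(fit.delta, truth.delta_true)
        if "individual_G" in config.methods:
            fit = core.fit_shared(
                evaluate._single_pair(pair, "G"),
                options=_fit_options(config, fit_seeds[1].generate_state(1)[0]),
            )
            fits["individual_G"] = fit
            row["mse_individual_G"] = evaluate.mean_prediction_error(
                fit, test.X, test.y, "as_G"
            )
            row["corr_beta_individual_G"] = _safe_corr(fit.beta, truth.beta_true)
        if "individual_C" in config.methods:
            fit = core.fit_shared(
                evaluate._single_pair(pair, "C"),
                options=_fit_options(config, fit_seeds[2].generate_state(1)[0]),
            )
            fits["individual_C"] = fit
            row["mse_individual_C"] = evaluate.mean_prediction_error(
                fit, test.X, test.y, "as_G"
            )
        if "individual_G" in fits and "individual_C" in fits:
            row["corr_delta_diff"] = _safe_corr(
                fits["individual_C"].beta - fits["individual_G"].beta,
                truth.delta_true,
            )
        if "pooled" in config.methods:
            fit = core.fit_shared(
                evaluate._pooled_pair(pair),
                options=_fit_options(config, fit_seeds[3].generate_state(1)[0]),
            )
            row["mse_pooled"] = evaluate.mean_prediction_error(
                fit, test.X, test.y, "as_G"
            )
        rows.append(row)
        if progress:  # pragma: no cover - cosmetic
            print(f"replicate {rep + 1}/{config.n_replicates} done", flush=True)
    replicates = pd.DataFrame(rows)
    mse_summaries = {}
    for method in config.methods:
        for col in _MSE_COLUMNS[method]:
            if col in replicates:
                mse_summaries[col.removeprefix("mse_")] = evaluate.five_number_summary(
                    replicates[col].to_numpy()
                )
    corr_summaries = {}
    for col in replicates.columns:
        if col.startswith("corr_"):
            vals = replicates[col].to_numpy()
            vals = vals[~np.isnan(vals)]
            if vals.size:
                corr_summaries[col.removeprefix("corr_")] = (
                    evaluate.five_number_summary(vals)
                )
    return StudyResult(
        replicates=replicates,
        mse_summaries=mse_summaries,
        corr_summaries=corr_summaries,
        config=config,
    )
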