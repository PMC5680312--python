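"""Repeated-CV stability analysis and signature extraction.

The cross-validated fit is repeated many times with re-randomized folds;
for every feature the fraction of runs in which it receives a nonzero
estimate (frequency) and the mean coefficient over the runs in which it
appears (average coefficient, the effect size) are recorded.  The most
significant predictors are those with frequency >= 80% and an effect
size beyond two standard deviations from the mean of the list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import core
from .core import CohortPair, FitOptions, Formulation

__all__ = [
    "Ledger",
    "VariableList",
    "SignatureMatrix",
    "run_stability",
    "select_significant",
    "build_signature_matrix",
    "plot_signature",
]


@dataclass(frozen=True)
class Ledger:
    """Selection frequency and average coefficient for one coefficient set."""

    frequency: np.ndarray  # fraction of runs with a nonzero estimate
    avg_coefficient: np.ndarray  # mean over appearing runs; NaN if never

    def __post_init__(self):
        freq = np.asarray(self.frequency, dtype=float).ravel()
        avg = np.asarray(self.avg_coefficient, dtype=float).ravel()
        if freq.size != avg.size:
            raise ValueError("frequency and avg_coefficient lengths differ")
        if np.any((freq < 0) | (freq > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if np.any((freq > 0) & ~np.isfinite(avg)):
            raise ValueError("appearing features must have a finite coefficient")
        object.__setattr__(self, "frequency", freq)
        object.__setattr__(self, "avg_coefficient", avg)


@dataclass(frozen=True)
class VariableList:
    """Per-feature stability ledgers accumulated over repeated fits.

    Ledgers: ``beta``/``delta`` (plus ``delta_G``/``delta_C`` for F2) and
    the cohort effect ledgers ``g`` (G-side coefficients) and ``c``
    (C-side coefficients) used for signature plots.
    """

    feature_names: tuple[str, ...]
    n_runs: int
    ledgers: Mapping[str, Ledger]
    formulation: Formulation = Formulation.F1

    def to_frame(self, ledger: str = "beta") -> pd.DataFrame:
        led = self.ledgers[ledger]
        return pd.DataFrame(
            {
                "feature": list(self.feature_names),
                "frequency": led.frequency,
                "avg_coefficient": led.avg_coefficient,
            }
        )


class _Accumulator:
    def __init__(self, p: int):
        self.count = np.zeros(p)
        self.total = np.zeros(p)

    def add(self, vec: np.ndarray):
        nz = vec != 0.0
        self.count += nz
        self.total += np.where(nz, vec, 0.0)

    def ledger(self, n_runs: int) -> Ledger:
        with np.errstate(invalid="ignore", divide="ignore"):
            avg = np.where(self.count > 0, self.total / self.count, np.nan)
        return Ledger(frequency=self.count / n_runs, avg_coefficient=avg)


def run_stability(
    data: CohortPair,
    n_runs: int = 200,
    seed=None,
    *,
    formulation: Formulation | str = Formulation.F1,
    options: FitOptions | None = None,
) -> VariableList:
    """Repeat the cross-validated fit with re-randomized folds.

    Every run re-selects the penalties by CV (pilot and adaptive stage)
    under a fresh fold assignment and refits; selection frequencies and
    average coefficients are accumulated per feature for each
    coefficient ledger.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    formulation = Formulation(formulation)
    options = options or FitOptions()
    p = data.p
    names = ("beta", "delta", "g", "c") if formulation == Formulation.F1 else (
        "beta", "delta_G", "delta_C", "g", "c"
    )
    acc = {name: _Accumulator(p) for name in names}
    run_seeds = np.random.SeedSequence(seed).spawn(n_runs)
    for i in range(n_runs):
        opts = FitOptions(
            **{**options.__dict__, "seed": int(run_seeds[i].generate_state(1)[0])}
        )
        fit = core.fit_shared(data, formulation=formulation, options=opts)
        acc["beta"].add(fit.beta)
        if formulation == Formulation.F1:
            acc["delta"].add(fit.delta)
        else:
            acc["delta_G"].add(fit.delta_G)
            acc["delta_C"].add(fit.delta_C)
        acc["g"].add(fit.coef_G)
        acc["c"].add(fit.coef_C)
    return VariableList(
        feature_names=data.feature_names,
        n_runs=n_runs,
        ledgers={name: a.ledger(n_runs) for name, a in acc.items()},
        formulation=formulation,
    )


def select_significant(
    vlist: VariableList,
    freq_threshold: float = 0.8,
    sd_multiplier: float = 2.0,
    ledger: str = "beta",
) -> np.ndarray:
    """Markers with high frequency and an extreme effect size.

    The mean and standard deviation (ddof=1) are computed over the
    average coefficients of all features that appeared at least once in
    the chosen ledger; a feature is significant when its frequency is at
    least ``freq_threshold`` and its average coefficient lies strictly
    beyond ``sd_multiplier`` standard deviations from that mean.
    Returns the selected feature names.
    """
    led = vlist.ledgers[ledger]
    appearing = led.frequency > 0
    if appearing.sum() < 2:
        warnings.warn(
            f"fewer than two features appear in ledger {ledger!r}; "
            "no significance call possible",
            stacklevel=2,
        )
        return np.array([], dtype=object)
    vals = led.avg_coefficient[appearing]
    m = float(vals.mean())
    s = float(vals.std(ddof=1))
    hi, lo = m + sd_multiplier * s, m - sd_multiplier * s
    with np.errstate(invalid="ignore"):
        mask = (
            appearing
            & (led.frequency >= freq_threshold)
            & ((led.avg_coefficient > hi) | (led.avg_coefficient < lo))
        )
    return np.array(
        [vlist.feature_names[j] for j in np.flatnonzero(mask)], dtype=object
    )


@dataclass(frozen=True)
class SignatureMatrix:
    """Drug-by-cohort effect-size matrix over the significant markers.

    Rows alternate (drug, 'g') and (drug, 'c'); g rows carry the G-side
    average coefficients, c rows the C-side ones.  ``significant`` marks
    the cells passing the inclusion rule; only markers significant in at
    least one row are kept as columns.
    """

    rows: tuple[tuple[str, str], ...]
    columns: tuple[str, ...]
    values: np.ndarray
    significant: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        index = pd.MultiIndex.from_tuples(self.rows, names=["drug", "cohort"])
        return pd.DataFrame(self.values, index=index, columns=list(self.columns))


def build_signature_matrix(
    results: Mapping[str, VariableList],
    freq_threshold: float = 0.8,
    sd_multiplier: float = 2.0,
) -> SignatureMatrix:
    """Assemble the cross-drug signature matrix from stability outputs.

    For every drug the g row holds the G-side effect sizes and the c row
    the C-side ones (features never selected contribute 0).  The column
    set is the union of markers significant for at least one
    (drug, cohort) row under the frequency / two-standard-deviation
    rule.
    """
    marker_order: list[str] = []
    seen: set[str] = set()
    sig_sets: dict[tuple[str, str], set[str]] = {}
    for drug, vlist in results.items():
        for label in ("g", "c"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sig = select_significant(
                    vlist, freq_threshold, sd_multiplier, ledger=label
                )
            sig_sets[(drug, label)] = set(sig.tolist())
            for name in vlist.feature_names:
                if name in sig_sets[(drug, label)] and name not in seen:
                    seen.add(name)
                    marker_order.append(name)
    if not marker_order:
        warnings.warn("no marker is significant for any drug", stacklevel=2)
    rows = []
    values = []
    sig_mask = []
    for drug, vlist in results.items():
        pos = {n: j for j, n in enumerate(vlist.feature_names)}
        for label in ("g", "c"):
            led = vlist.ledgers[label]
            vals = np.zeros(len(marker_order))
            mask = np.zeros(len(marker_order), dtype=bool)
            for jm, name in enumerate(marker_order):
                if name in pos and led.frequency[pos[name]] > 0:
                    vals[jm] = led.avg_coefficient[pos[name]]
                mask[jm] = name in sig_sets[(drug, label)]
            rows.append((drug, label))
            values.append(vals)
            sig_mask.append(mask)
    return SignatureMatrix(
        rows=tuple(rows),
        columns=tuple(marker_order),
        values=np.array(values) if values else np.zeros((0, 0)),
        significant=np.array(sig_mask) if sig_mask else np.zeros((0, 0), dtype=bool),
    )


def plot_signature(matrix: SignatureMatrix, path) -> None:
    """Render the signature matrix as a diverging heatmap centered at 0."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n_rows = len(matrix.rows)
    n_cols = len(matrix.columns)
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.3 * n_cols + 2), max(3.0, 0.35 * n_rows + 1.5))
    )
    if n_rows and n_cols:
        vmax = np.abs(matrix.values).max() or 1.0
        mesh = ax.pcolormesh(
            matrix.values, cmap="RdBu", vmin=-vmax, vmax=vmax, shading="flat"
        )
        fig.colorbar(mesh, ax=ax, label="effect size")
        ax.set_xticks(np.arange(n_cols) + 0.5)
        ax.set_xticklabels(matrix.columns, rotation=90, fontsize=7)
        ax.set_yticks(np.arange(n_rows) + 0.5)
        ax.set_yticklabels([f"{d} ({c})" for d, c in matrix.rows], fontsize=7)
    else:
        ax.text(0.5, 0.5, "empty signature", ha="center", va="center")
    ax.set_title("signature validation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
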