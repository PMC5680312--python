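"""Synthetic cohort-pair fixture with planted effects and missingness.

Stands in for the real paired drug-screening data: two cohorts of cell
lines with mutation / expression / copy-number / tissue features,
response values for two drugs driven by planted shared coefficients
(plus one deliberately discrepant marker whose shared effect is
cancelled in cohort C), scattered missing entries, and one fully
missing column.  A truth file records the planted coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..preprocess import RawTable
from . import io as dio

__all__ = ["FixtureData", "PRESETS", "make_fixture", "write_fixture"]

PRESETS = {
    # n rows per cohort; feature-kind counts sum to the advertised p
    "small": dict(
        n=60, n_mutation=10, n_expression=262, n_copy_number=20, n_tissue=8,
        missing_rate=0.015, noise_sd=1.0,
    ),
    "tiny": dict(
        n=30, n_mutation=5, n_expression=40, n_copy_number=5, n_tissue=4,
        missing_rate=0.02, noise_sd=1.0,
    ),
}

STRONG_THRESHOLD = 1.5


@dataclass(frozen=True)
class FixtureData:
    features_G: RawTable
    features_C: RawTable
    responses_G: pd.DataFrame
    responses_C: pd.DataFrame
    truth: dict


def _planted_effects(preset: dict) -> dict:
    """Planted coefficients keyed by feature id, per drug.

    Strong markers sit well above the 1.5 threshold; each drug also
    carries a band of weak background effects (as real drug-response
    profiles do), which keeps the stability variable lists long enough
    for the relative two-standard-deviation inclusion rule to behave as
    it does on real data.
    """
    # drugA: three strong concordant markers plus one marker whose
    # shared effect is cancelled in cohort C (washed away)
    drug_a_beta = {
        "expr_0001": 2.0,
        "expr_0002": -2.0,
        "expr_0003": 2.0,
        "expr_0006": 2.4,  # washed away in C
    }
    drug_a_delta = {"expr_0006": -2.4}
    # drugB: two strong expression markers and one strong mutation marker
    # (binary columns have sd ~0.43, so the raw effect is scaled up to be
    # comparable after standardization)
    drug_b_beta = {"expr_0010": 1.8, "expr_0011": -1.8, "mut_0001": 5.0}
    n_regular = preset["n_expression"] - 1  # last expression column is unusable
    weak_per_drug = min(20, max(0, (n_regular - 12) // 2))
    first = 13
    for off, (book, sign) in enumerate(
        [(drug_a_beta, 1), (drug_a_beta, -1)] * (weak_per_drug // 2)
    ):
        book[f"expr_{first + off:04d}"] = 0.25 * sign
    first += weak_per_drug
    for off, (book, sign) in enumerate(
        [(drug_b_beta, 1), (drug_b_beta, -1)] * (weak_per_drug // 2)
    ):
        book[f"expr_{first + off:04d}"] = 0.25 * sign
    return {
        "drugA": {"beta": drug_a_beta, "delta": drug_a_delta},
        "drugB": {"beta": drug_b_beta, "delta": {}},
    }


def _feature_columns(preset: dict) -> tuple[list[str], list[str]]:
    ids: list[str] = []
    kinds: list[str] = []
    for i in range(preset["n_mutation"]):
        ids.append(f"mut_{i + 1:04d}")
        kinds.append("mutation")
    for i in range(preset["n_expression"] - 1):
        ids.append(f"expr_{i + 1:04d}")
        kinds.append("expression")
    ids.append("expr_allmiss")  # deliberately unusable column
    kinds.append("expression")
    for i in range(preset["n_copy_number"]):
        ids.append(f"cnv_{i + 1:04d}")
        kinds.append("copy_number")
    for i in range(preset["n_tissue"]):
        ids.append(f"tissue_{i + 1:02d}")
        kinds.append("tissue")
    return ids, kinds


def _sample_cohort(rng, preset, ids, kinds, label: str) -> tuple[RawTable, np.ndarray]:
    n = preset["n"]
    cols = []
    for cid, kind in zip(ids, kinds):
        if kind == "mutation":
            cols.append(rng.binomial(1, 0.25, n).astype(float))
        elif kind == "copy_number":
            cols.append(rng.normal(0.0, 1.0, n).round(2))
        elif kind == "tissue":
            cols.append(np.zeros(n))
        else:
            cols.append(rng.normal(0.0, 1.0, n))
    values = np.column_stack(cols)
    tissue_idx = [j for j, k in enumerate(kinds) if k == "tissue"]
    assignment = rng.integers(0, len(tissue_idx), n)
    for i, t in enumerate(assignment):
        values[i, tissue_idx[t]] = 1.0
    row_ids = tuple(f"{label}_cell_{i + 1:03d}" for i in range(n))
    table = RawTable(values=values, row_ids=row_ids, col_ids=tuple(ids),
                     col_kind=tuple(kinds))
    return table, values


def _responses(rng, values, ids, effects, cohort: str, noise_sd: float) -> np.ndarray:
    pos = {c: j for j, c in enumerate(ids)}
    y = rng.normal(0.0, noise_sd, values.shape[0])
    for cid, b in effects["beta"].items():
        coef = b + (effects["delta"].get(cid, 0.0) if cohort == "C" else 0.0)
        y = y + coef * values[:, pos[cid]]
    return y


def _inject_missing(rng, table: RawTable, rate: float) -> RawTable:
    values = table.values.copy()
    maskable = [
        j for j, k in enumerate(table.col_kind) if k in ("expression", "copy_number")
    ]
    mask = rng.random((values.shape[0], len(maskable))) < rate
    values[:, maskable] = np.where(mask, np.nan, values[:, maskable])
    allmiss = table.col_ids.index("expr_allmiss")
    values[:, allmiss] = np.nan
    return RawTable(values=values, row_ids=table.row_ids,
                    col_ids=table.col_ids, col_kind=table.col_kind)


def make_fixture(seed: int = 0, preset: str = "small") -> FixtureData:
    """Generate the synthetic paired-cohort fixture."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    rng = np.random.default_rng(seed)
    ids, kinds = _feature_columns(cfg)
    effects = _planted_effects(cfg)
    tables = {}
    responses = {}
    for label in ("G", "C"):
        table, values = _sample_cohort(rng, cfg, ids, kinds, label)
        resp_rows = []
        for drug, eff in effects.items():
            y = _responses(rng, values, ids, eff, label, cfg["noise_sd"])
            for rid, val in zip(table.row_ids, y):
                resp_rows.append(
                    {"cell_line": rid, "drug": drug, "response_value": val}
                )
        tables[label] = _inject_missing(rng, table, cfg["missing_rate"])
        responses[label] = pd.DataFrame(resp_rows)
    truth = {
        "preset": preset,
        "seed": int(seed),
        "strong_threshold": STRONG_THRESHOLD,
        "drugs": effects,
    }
    return FixtureData(
        features_G=tables["G"],
        features_C=tables["C"],
        responses_G=responses["G"],
        responses_C=responses["C"],
        truth=truth,
    )


def write_fixture(fixture: FixtureData, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features_G": outdir / "features_G.tsv",
        "features_C": outdir / "features_C.tsv",
        "responses_G": outdir / "responses_G.tsv",
        "responses_C": outdir / "responses_C.tsv",
        "truth": outdir / "truth.json",
    }
    dio.write_feature_table(fixture.features_G, paths["features_G"])
    dio.write_feature_table(fixture.features_C, paths["features_C"])
    dio.write_response_table(fixture.responses_G, paths["responses_G"])
    dio.write_response_table(fixture.responses_C, paths["responses_C"])
    paths["truth"].write_text(json.dumps(fixture.truth, indent=2, sort_keys=True))
    return paths
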