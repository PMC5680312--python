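"""Delimited-text readers and writers for feature and response tables.

Feature tables: header row of feature ids, first column of cell-line
ids; missing entries are empty fields or "NA".  Column kinds are taken
from the feature-id prefix: ``mut_`` -> mutation, ``cnv_`` ->
copy_number, ``tissue_`` -> tissue, anything else -> expression.
Response tables need the columns cell_line, drug, response_value.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from ..preprocess import RawTable

__all__ = [
    "kind_from_name",
    "read_feature_table",
    "write_feature_table",
    "read_response_table",
    "write_response_table",
    "sha256_of",
]

_PREFIX_KINDS = {"mut_": "mutation", "cnv_": "copy_number", "tissue_": "tissue"}


def kind_from_name(col_id: str) -> str:
    for prefix, kind in _PREFIX_KINDS.items():
        if col_id.startswith(prefix):
            return kind
    return "expression"


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_feature_table(path) -> RawTable:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=_sep_for(path), index_col=0,
            na_values=["NA"], keep_default_na=True,
        )
    except Exception as exc:
        raise ValueError(f"cannot parse feature table {path}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    col_ids = [str(c) for c in df.columns]
    return RawTable(
        values=values,
        row_ids=tuple(str(r) for r in df.index),
        col_ids=tuple(col_ids),
        col_kind=tuple(kind_from_name(c) for c in col_ids),
    )


def write_feature_table(table: RawTable, path) -> None:
    path = Path(path)
    df = table.to_frame()
    df.index.name = "cell_line"
    df.to_csv(path, sep=_sep_for(path), na_rep="NA", float_format="%.6g")


def read_response_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except Exception as exc:
        raise ValueError(f"cannot parse response table {path}: {exc}") from exc
    required = {"cell_line", "drug", "response_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"response table {path} is missing columns: {sorted(missing)}"
        )
    df["cell_line"] = df["cell_line"].astype(str)
    df["drug"] = df["drug"].astype(str)
    df["response_value"] = df["response_value"].astype(float)
    return df


def write_response_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.6g")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
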