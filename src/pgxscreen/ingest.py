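"""Readers for the four tabular inputs (CCLE/DepMap- and GDSC-style CSV/TSV).

Column layouts vary between data releases, so each reader takes a small
*dialect* descriptor (column names, matrix orientation, delimiter) instead of
hard-coding one release. Identifier matching downstream is by exact normalized
identifier only — gene symbols are upper-cased and identifiers stripped of
surrounding whitespace, nothing fuzzier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CellLineMetadata,
    DrugCatalog,
    DrugResponseTable,
    ExpressionMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionDialect",
    "ResponseDialect",
    "TableDialect",
    "read_expression",
    "read_drug_response",
    "read_drug_catalog",
    "read_cell_line_metadata",
    "write_expression",
    "write_drug_response",
    "write_drug_catalog",
    "write_cell_line_metadata",
]


@dataclass(frozen=True)
class ExpressionDialect:
    """How an expression file is laid out.

    ``genes_in_rows=False`` matches DepMap's lines-x-genes orientation.
    ``delimiter=None`` auto-detects comma vs tab.
    """

    genes_in_rows: bool = True
    delimiter: str | None = None


@dataclass(frozen=True)
class ResponseDialect:
    drug_column: str = "drug_id"
    cell_line_column: str = "cell_line_id"
    auc_column: str = "auc"
    delimiter: str | None = None


@dataclass(frozen=True)
class TableDialect:
    """Generic delimited-table dialect (catalog / metadata readers)."""

    delimiter: str | None = None


def _read_delimited(path, delimiter: str | None, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if delimiter is None:
        return pd.read_csv(path, sep=None, engine="python", **kwargs)
    return pd.read_csv(path, sep=delimiter, **kwargs)


def _norm_id(value) -> str:
    return str(value).strip()


def read_expression(
    path, dialect: ExpressionDialect = ExpressionDialect()
) -> ExpressionMatrix:
    """Read a genes x cell-lines (or transposed) expression matrix.

    Gene symbols are normalized to upper case and cell-line identifiers
    stripped of whitespace. Duplicate identifiers and non-numeric or negative
    cells are hard errors naming the offending entry.
    """
    df = _read_delimited(path, dialect.delimiter, index_col=0)
    if not dialect.genes_in_rows:
        df = df.T
    df.index = [_norm_id(g).upper() for g in df.index]
    df.columns = [_norm_id(c) for c in df.columns]
    # locate non-numeric cells before the container casts
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = coerced.isna() & ~raw_na
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValidationError(
                f"non-numeric expression value {df[col].iloc[i]!r} at "
                f"gene {df.index[i]!r} (row {i + 1}), cell line {col!r} (column {j + 1})"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise ValidationError("expression matrix contains missing values")
    return ExpressionMatrix(df.astype(float))


def read_drug_response(
    path, dialect: ResponseDialect = ResponseDialect()
) -> DrugResponseTable:
    """Read a long-format drug-response file (drug, cell line, AUC).

    Rows with missing AUC are dropped and counted in the log; out-of-range
    AUC and duplicate (drug, cell line) pairs are hard errors.
    """
    df = _read_delimited(path, dialect.delimiter)
    mapping = {
        dialect.drug_column: "drug_id",
        dialect.cell_line_column: "cell_line_id",
        dialect.auc_column: "auc",
    }
    missing = [c for c in mapping if c not in df.columns]
    if missing:
        raise ValidationError(f"drug response file missing column(s): {missing}")
    df = df[list(mapping)].rename(columns=mapping)
    df["drug_id"] = df["drug_id"].map(_norm_id)
    df["cell_line_id"] = df["cell_line_id"].map(_norm_id)
    df["auc"] = pd.to_numeric(df["auc"], errors="coerce")
    n_missing = int(df["auc"].isna().sum())
    if n_missing:
        log.info("dropped %d response row(s) with missing AUC", n_missing)
        df = df.dropna(subset=["auc"])
    return DrugResponseTable(df.reset_index(drop=True))


_CATALOG_COLUMNS = ("drug_id", "drug_name", "targets", "category")
_META_COLUMNS = ("cell_line_id", "tissue", "subtype")


def _read_annotated(path, dialect, required, kind: str) -> pd.DataFrame:
    df = _read_delimited(path, dialect.delimiter)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{kind} file missing mandatory column(s): {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        log.warning("%s file: ignoring unknown column(s) %s", kind, extra)
    df = df[list(required)].copy()
    for col in required:
        df[col] = df[col].fillna("").map(_norm_id)
    return df


def read_drug_catalog(path, dialect: TableDialect = TableDialect()) -> DrugCatalog:
    """Read drug annotations (id, name, targets, target-pathway category)."""
    return DrugCatalog(_read_annotated(path, dialect, _CATALOG_COLUMNS, "drug catalog"))


def read_cell_line_metadata(
    path, dialect: TableDialect = TableDialect()
) -> CellLineMetadata:
    """Read cell line -> tissue / subtype assignments.

    Subtype labels are taken verbatim (e.g. ``Lung_Nsclc_SCC``); only
    surrounding whitespace is stripped.
    """
    return CellLineMetadata(
        _read_annotated(path, dialect, _META_COLUMNS, "cell-line metadata")
    )


# -- canonical writers (round-trip with the default dialects) ----------------


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, index_label="gene")


def write_drug_response(table: DrugResponseTable, path) -> None:
    table.data.to_csv(path, index=False)


def write_drug_catalog(catalog: DrugCatalog, path) -> None:
    catalog.data.to_csv(path, index=False)


def write_cell_line_metadata(meta: CellLineMetadata, path) -> None:
    meta.data.to_csv(path, index=False)
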