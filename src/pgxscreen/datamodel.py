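"""Validated in-memory containers for the four pipeline inputs.

All containers wrap a :class:`pandas.DataFrame` and enforce their invariants
at construction time, so downstream stages can assume clean data:

* :class:`ExpressionMatrix` — basal log2-scale expression, genes x cell lines.
* :class:`DrugResponseTable` — one AUC record per (drug, cell line).
* :class:`DrugCatalog` — drug annotations incl. target-pathway category.
* :class:`CellLineMetadata` — cell line -> (tissue, tissue subtype).

AUC is the area under the dose-response curve on (0, 1]; higher AUC means
the cell line is more resistant to the drug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "DrugResponseTable",
    "DrugCatalog",
    "CellLineMetadata",
]


class ValidationError(ValueError):
    """An input table violates one of the data-model invariants."""


def _duplicates(values) -> list:
    s = pd.Series(list(values))
    return sorted(s[s.duplicated()].unique().tolist())


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-expression matrix, genes (rows) x cell lines (columns).

    Values are log2-scale expression (log2(TPM+1) convention): finite and
    non-negative. Gene symbols and cell-line identifiers are unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        dup_g = _duplicates(df.index)
        if dup_g:
            raise ValidationError(f"duplicate gene symbol(s): {dup_g}")
        dup_c = _duplicates(df.columns)
        if dup_c:
            raise ValidationError(f"duplicate cell-line identifier(s): {dup_c}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                "negative expression value at gene "
                f"{df.index[bad[0]]!r}, cell line {df.columns[bad[1]]!r} "
                "(log2(TPM+1) values must be >= 0)"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class DrugResponseTable:
    """Long-format drug response: one AUC per (drug, cell line)."""

    data: pd.DataFrame  # columns: drug_id, cell_line_id, auc

    REQUIRED = ("drug_id", "cell_line_id", "auc")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"drug response table missing column(s): {missing}")
        auc = df["auc"].to_numpy(dtype=float)
        if not np.isfinite(auc).all():
            raise ValidationError("drug response table contains non-finite AUC")
        if (auc <= 0).any() or (auc > 1).any():
            bad = df.loc[(auc <= 0) | (auc > 1)].iloc[0]
            raise ValidationError(
                f"AUC out of range (0, 1]: {bad['auc']} for drug "
                f"{bad['drug_id']!r}, cell line {bad['cell_line_id']!r}"
            )
        dup = df.duplicated(subset=["drug_id", "cell_line_id"])
        if dup.any():
            pair = df.loc[dup, ["drug_id", "cell_line_id"]].iloc[0]
            raise ValidationError(
                f"duplicate response record for (drug {pair['drug_id']!r}, "
                f"cell line {pair['cell_line_id']!r})"
            )

    def __len__(self) -> int:
        return len(self.data)

    def auc_wide(self) -> pd.DataFrame:
        """Pivot to drugs x cell lines (NaN where untested)."""
        return self.data.pivot(index="drug_id", columns="cell_line_id", values="auc")


@dataclass(frozen=True)
class DrugCatalog:
    """Drug annotations: identifier, name, nominal targets, category.

    ``targets`` is stored as a semicolon-joined string; ``category`` is the
    curated target-pathway category (may be empty before curation).
    """

    data: pd.DataFrame  # columns: drug_id, drug_name, targets, category

    REQUIRED = ("drug_id", "drug_name", "targets", "category")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"drug catalog missing column(s): {missing}")
        dup = _duplicates(df["drug_id"])
        if dup:
            raise ValidationError(f"duplicate drug identifier(s): {dup}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.data["drug_id"])

    def category_of(self) -> pd.Series:
        return self.data.set_index("drug_id")["category"]

    def category_sizes(self) -> dict[str, int]:
        return self.data.groupby("category").size().to_dict()


@dataclass(frozen=True)
class CellLineMetadata:
    """Cell line -> tissue and tissue subtype (cancer lineage stratum)."""

    data: pd.DataFrame  # columns: cell_line_id, tissue, subtype

    REQUIRED = ("cell_line_id", "tissue", "subtype")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"cell-line metadata missing column(s): {missing}")
        dup = _duplicates(df["cell_line_id"])
        if dup:
            raise ValidationError(
                f"cell line(s) listed more than once: {dup} "
                "(each cell line belongs to exactly one subtype)"
            )
        tissues_per_subtype = df.groupby("subtype")["tissue"].nunique()
        bad = tissues_per_subtype[tissues_per_subtype > 1]
        if len(bad):
            raise ValidationError(
                f"subtype(s) mapped to multiple tissues: {sorted(bad.index.tolist())}"
            )

    def __len__(self) -> int:
        return len(self.data)

    def subtype_of(self) -> pd.Series:
        return self.data.set_index("cell_line_id")["subtype"]
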