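"""Cohort curation: drug-category merging and filtering, tissue exclusion,
and assembly of per-(drug, subtype) analysis groups.

The defaults encode the screen's curation rules: categories with similar
target pathways merged (EGFR signaling -> ErbBs signaling, IGF1R signaling ->
RTK signaling, "Other, kinases" -> Kinases); drugs with no category or an
"Other"/"Unclassified" one removed; categories kept only with >= 10 drugs;
cell lines from blood, bone and soft tissue excluded (solid tumors only);
and per-(drug, subtype) groups kept only with >= 10 cell lines that carry
both an AUC and an expression profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .datamodel import (
    CellLineMetadata,
    DrugCatalog,
    DrugResponseTable,
    ExpressionMatrix,
)

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CATEGORY_MERGES",
    "DEFAULT_EXCLUDED_TISSUES",
    "UNCATEGORIZED_LABELS",
    "AnalysisCohort",
    "merge_drug_categories",
    "filter_drug_categories",
    "exclude_tissues",
    "build_cohort",
]

DEFAULT_CATEGORY_MERGES: tuple[tuple[str, str], ...] = (
    ("EGFR signaling", "ErbBs signaling"),
    ("IGF1R signaling", "RTK signaling"),
    ("Other, kinases", "Kinases"),
)

DEFAULT_EXCLUDED_TISSUES: tuple[str, ...] = ("blood", "bone", "soft tissue")

#: category labels that mean "no usable category" (compared case-insensitively)
UNCATEGORIZED_LABELS: tuple[str, ...] = ("", "other", "unclassified")


@dataclass(frozen=True)
class AnalysisCohort:
    """The curated analysis cohort.

    ``groups`` maps (drug_id, subtype) to the tuple of cell-line identifiers
    that have both an AUC for the drug and an expression column; every group
    has at least ``min_lines`` members. ``subtype_count`` is the number of
    distinct subtypes appearing in at least one retained group — the S in the
    global-score denominator, fixed once per run.
    """

    groups: dict[tuple[str, str], tuple[str, ...]]
    catalog: DrugCatalog
    subtype_count: int
    min_lines: int = 10
    _category_of: pd.Series = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_category_of", self.catalog.category_of())

    @property
    def subtypes(self) -> list[str]:
        return sorted({s for _, s in self.groups})

    @property
    def drug_ids(self) -> list[str]:
        return sorted({d for d, _ in self.groups})

    def category(self, drug_id: str) -> str:
        return self._category_of[drug_id]

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "drug_id": d,
                "subtype": s,
                "category": self._category_of.get(d, ""),
                "n_lines": len(lines),
            }
            for (d, s), lines in sorted(self.groups.items())
        ]
        return pd.DataFrame(rows, columns=["drug_id", "subtype", "category", "n_lines"])


def merge_drug_categories(
    catalog: DrugCatalog,
    mapping: tuple[tuple[str, str], ...] = DEFAULT_CATEGORY_MERGES,
) -> DrugCatalog:
    """Rename drug categories per ``mapping`` (source -> destination pairs).

    Chained renames (a source that is another rule's destination) are
    rejected so the result does not depend on rule order.
    """
    sources = {src for src, _ in mapping}
    destinations = {dst for _, dst in mapping}
    chained = sources & destinations
    if chained:
        raise ValueError(
            f"category merge rules chain through {sorted(chained)}; "
            "merge rules must be a flat source -> destination mapping"
        )
    rename = dict(mapping)
    df = catalog.data.copy()
    df["category"] = df["category"].map(lambda c: rename.get(c, c))
    return DrugCatalog(df)


def filter_drug_categories(catalog: DrugCatalog, min_drugs: int = 10) -> DrugCatalog:
    """Drop uncategorized drugs and categories with fewer than ``min_drugs``.

    Drugs whose category is missing, "Other" or "Unclassified" are removed
    first; remaining categories must contain at least ``min_drugs`` drugs.
    """
    if min_drugs < 1:
        raise ValueError("min_drugs must be >= 1")
    df = catalog.data
    categorized = df[
        ~df["category"].str.strip().str.lower().isin(UNCATEGORIZED_LABELS)
    ]
    sizes = categorized.groupby("category")["drug_id"].transform("size")
    kept = categorized[sizes >= min_drugs].reset_index(drop=True)
    if kept.empty:
        raise ValueError(
            f"no drug category has >= {min_drugs} drugs after curation; "
            "lower min_drugs or supply a larger catalog"
        )
    n_dropped = len(df) - len(kept)
    if n_dropped:
        log.info(
            "category filter removed %d of %d drugs (kept %d categories)",
            n_dropped,
            len(df),
            kept["category"].nunique(),
        )
    return DrugCatalog(kept)


def exclude_tissues(
    metadata: CellLineMetadata,
    excluded: tuple[str, ...] = DEFAULT_EXCLUDED_TISSUES,
) -> CellLineMetadata:
    """Remove cell lines from excluded tissues (case-insensitive match)."""
    excluded_norm = {t.strip().lower() for t in excluded}
    df = metadata.data
    kept = df[~df["tissue"].str.strip().str.lower().isin(excluded_norm)]
    if kept.empty:
        log.warning("tissue exclusion removed every cell line")
    return CellLineMetadata(kept.reset_index(drop=True))


def build_cohort(
    expr: ExpressionMatrix,
    resp: DrugResponseTable,
    catalog: DrugCatalog,
    meta: CellLineMetadata,
    min_lines: int = 10,
) -> AnalysisCohort:
    """Assemble per-(drug, subtype) groups from the curated inputs.

    For each drug, cell lines without an expression column are excluded;
    the remaining lines are stratified by tissue subtype and any
    (drug, subtype) group smaller than ``min_lines`` is dropped.
    """
    if min_lines < 1:
        raise ValueError("min_lines must be >= 1")
    expr_lines = set(expr.cell_line_ids)
    subtype_of = meta.subtype_of()

    df = resp.data
    df = df[df["drug_id"].isin(set(catalog.drug_ids))]
    n_no_meta = int((~df["cell_line_id"].isin(subtype_of.index)).sum())
    df = df[df["cell_line_id"].isin(subtype_of.index)]
    n_no_expr = int((~df["cell_line_id"].isin(expr_lines)).sum())
    df = df[df["cell_line_id"].isin(expr_lines)]
    if n_no_meta or n_no_expr:
        log.info(
            "build_cohort dropped %d response record(s) without metadata and "
            "%d without expression",
            n_no_meta,
            n_no_expr,
        )

    df = df.assign(subtype=df["cell_line_id"].map(subtype_of))
    groups: dict[tuple[str, str], tuple[str, ...]] = {}
    for (drug, subtype), sub in df.groupby(["drug_id", "subtype"], sort=True):
        if len(sub) >= min_lines:
            groups[(str(drug), str(subtype))] = tuple(sorted(sub["cell_line_id"]))
    if not groups:
        raise ValueError(
            f"no (drug, subtype) group has >= {min_lines} cell lines with both "
            "AUC and expression; check identifier matching or lower min_lines"
        )
    subtype_count = len({s for _, s in groups})
    log.info(
        "cohort: %d (drug, subtype) groups across %d subtypes",
        len(groups),
        subtype_count,
    )
    return AnalysisCohort(
        groups=groups, catalog=catalog, subtype_count=subtype_count, min_lines=min_lines
    )
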