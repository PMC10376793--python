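"""Per-(gene, drug, subtype) Pearson correlations and z-transformed scores.

For each gene and each (drug, subtype) group, the screen computes Pearson's
r between basal expression and AUC across the group's cell lines, then
applies the variance-stabilized Fisher transformation

    z = atanh(r) * sqrt(n - 3)

so that z is approximately standard normal under the null regardless of the
group's size n, and a single cutoff (default ±1.7) is comparable across
groups. A positive z flags a resistance association (high expression, high
AUC); a negative z flags sensitivity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import AnalysisCohort
from .datamodel import DrugResponseTable, ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_Z_CUTOFF",
    "CorrelationTable",
    "pearson_r",
    "fisher_z",
    "correlation_table",
    "write_correlation_tsv",
]

DEFAULT_Z_CUTOFF = 1.7

#: clamp applied to r before atanh so |r| = 1 maps to a large finite z
_R_CLAMP = 1.0 - 1e-7

RECORD_COLUMNS = [
    "gene",
    "drug_id",
    "category",
    "subtype",
    "n",
    "r",
    "z",
    "sig_pos",
    "sig_neg",
]


def pearson_r(x: Iterable[float], y: Iterable[float]) -> float:
    """Product-moment correlation of two equal-length vectors.

    Returns NaN (rather than raising) when either vector has zero variance;
    the tabulation layer keeps such records with both significance flags
    false.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return float("nan")
    r = float(xc @ yc) / denom
    return max(-1.0, min(1.0, r))


def fisher_z(r: float, n: int) -> float:
    """Variance-stabilized Fisher transform: atanh(r) * sqrt(n - 3).

    r is clamped to +/-(1 - 1e-7) so perfect correlations give a large
    finite z instead of an infinity. Antisymmetric in r, increasing in |r|
    and (for r != 0) in n.
    """
    if n < 4:
        raise ValueError(f"fisher_z requires n >= 4, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation out of range [-1, 1]: {r}")
    return math.atanh(max(-_R_CLAMP, min(_R_CLAMP, r))) * math.sqrt(n - 3)


def _group_correlations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of X against y; NaN where variance is zero."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc * Xc).sum(axis=1))
    sy = math.sqrt(float(yc @ yc))
    denom = sx * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / denom
    r[denom == 0.0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _z_from_r(r: np.ndarray, n: int) -> np.ndarray:
    if n < 4:
        return np.full_like(r, np.nan)
    return np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP)) * math.sqrt(n - 3)


@dataclass(frozen=True)
class CorrelationTable:
    """One record per (gene, drug, subtype) with r, z and significance flags.

    ``category_sizes`` (drugs per curated category) and ``n_subtypes`` are
    carried along because the global-score denominator needs the *full*
    category size and the run-wide subtype count, not just what appears in
    the records.
    """

    records: pd.DataFrame  # RECORD_COLUMNS
    cutoff: float
    category_sizes: Mapping[str, int]
    n_subtypes: int

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())

    @property
    def categories(self) -> list[str]:
        return sorted(self.category_sizes)


def correlation_table(
    cohort: AnalysisCohort,
    expr: ExpressionMatrix,
    resp: DrugResponseTable,
    genes: Iterable[str] | None = None,
    cutoff: float = DEFAULT_Z_CUTOFF,
) -> CorrelationTable:
    """Correlate every requested gene with every (drug, subtype) group.

    Genes absent from the expression matrix are reported and skipped.
    Groups where the gene's expression or the AUC vector is constant yield a
    record with NaN r and z and both flags false (the drug still counts
    toward the score denominator as "tested but not significant").
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if genes is None:
        gene_list = list(expr.gene_ids)
    else:
        gene_list = [str(g).strip().upper() for g in genes]
        known = set(expr.gene_ids)
        absent = [g for g in gene_list if g not in known]
        if absent:
            log.warning("skipping %d gene(s) absent from expression: %s",
                        len(absent), absent[:10])
            gene_list = [g for g in gene_list if g in known]
    if not gene_list:
        raise ValueError("no requested gene is present in the expression matrix")

    X_all = expr.data.loc[gene_list].to_numpy(dtype=float)
    col_index = {c: i for i, c in enumerate(expr.cell_line_ids)}
    auc_wide = resp.auc_wide()

    frames = []
    genes_arr = np.asarray(gene_list, dtype=object)
    for (drug, subtype), lines in sorted(cohort.groups.items()):
        idx = [col_index[c] for c in lines]
        y = auc_wide.loc[drug, list(lines)].to_numpy(dtype=float)
        n = len(lines)
        r = _group_correlations(X_all[:, idx], y)
        z = _z_from_r(r, n)
        with np.errstate(invalid="ignore"):
            sig_pos = z >= cutoff
            sig_neg = z <= -cutoff
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes_arr,
                    "drug_id": drug,
                    "category": cohort.category(drug),
                    "subtype": subtype,
                    "n": n,
                    "r": r,
                    "z": z,
                    "sig_pos": sig_pos,
                    "sig_neg": sig_neg,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]
    return CorrelationTable(
        records=records,
        cutoff=cutoff,
        category_sizes=cohort.catalog.category_sizes(),
        n_subtypes=cohort.subtype_count,
    )


def write_correlation_tsv(table: CorrelationTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False)
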