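"""Global scores per (gene, drug category, direction) and subtype contributions.

For each gene and drug category the screen counts significant correlations
(z beyond the cutoff, separately for the sensitivity and resistance
directions) across all subtypes and normalizes:

    Score_global = 100 * n_sig / (n_drugs_in_category * n_subtypes)

The denominator is unconditional — untested (drug, subtype) combinations
count as non-significant — so scores are conservative percentages in
[0, 100]. Score significance is called against the upper tail (default 5%)
of the score distribution over all genes x categories for that direction.
Subtype contributions report, within each subtype, the percentage of the
category's *tested* drugs (valid correlation) that are significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

from .correlate import CorrelationTable

log = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "GlobalScore",
    "ScoreMatrix",
    "global_score",
    "score_matrix",
    "score_significance_cutoff",
    "subtype_contribution",
    "contribution_table",
]

DEFAULT_SCORE_TAIL = 0.05


class Direction(str, Enum):
    """Association direction: sensitivity (z <= -cutoff) or resistance
    (z >= +cutoff)."""

    SENSITIVITY = "sensitivity"
    RESISTANCE = "resistance"

    @property
    def flag_column(self) -> str:
        return "sig_neg" if self is Direction.SENSITIVITY else "sig_pos"


def _as_direction(direction) -> Direction:
    return Direction(direction)


@dataclass(frozen=True)
class GlobalScore:
    gene: str
    category: str
    direction: Direction
    score: float  # percentage in [0, 100]
    n_sig: int
    n_drugs: int
    n_subtypes: int
    significant: bool | None = None  # unset until a score cutoff is applied


def global_score(
    table: CorrelationTable,
    gene: str,
    category: str,
    direction,
    n_subtypes: int | None = None,
) -> GlobalScore:
    """Score one (gene, category, direction) cell.

    ``n_subtypes`` defaults to the run-wide subtype count carried by the
    table. Raises if the gene has no records at all.
    """
    direction = _as_direction(direction)
    if n_subtypes is None:
        n_subtypes = table.n_subtypes
    if n_subtypes < 1:
        raise ValueError("n_subtypes must be >= 1")
    if category not in table.category_sizes:
        raise KeyError(f"unknown drug category: {category!r}")
    rec = table.records
    mine = rec[rec["gene"] == gene]
    if mine.empty:
        raise KeyError(f"gene {gene!r} absent from the correlation table")
    n_drugs = int(table.category_sizes[category])
    n_sig = int(mine.loc[mine["category"] == category, direction.flag_column].sum())
    score = 100.0 * n_sig / (n_drugs * n_subtypes)
    return GlobalScore(
        gene=gene,
        category=category,
        direction=direction,
        score=score,
        n_sig=n_sig,
        n_drugs=n_drugs,
        n_subtypes=n_subtypes,
    )


@dataclass(frozen=True)
class ScoreMatrix:
    """Genes x categories grid of global scores for one direction."""

    direction: Direction
    scores: pd.DataFrame  # genes x categories, percentages
    n_sig: pd.DataFrame  # genes x categories, integer numerators
    n_subtypes: int
    score_cutoff: float | None = None

    @property
    def significant(self) -> pd.DataFrame:
        """Boolean grid; a score is significant iff strictly above the cutoff."""
        if self.score_cutoff is None:
            raise ValueError("no score cutoff set; call with_cutoff() first")
        return self.scores > self.score_cutoff

    def with_cutoff(self, score_cutoff: float) -> "ScoreMatrix":
        return replace(self, score_cutoff=float(score_cutoff))

    def flat_scores(self) -> np.ndarray:
        return self.scores.to_numpy().ravel()


def score_matrix(
    table: CorrelationTable,
    genes: Iterable[str] | None = None,
    categories: Iterable[str] | None = None,
    direction=Direction.SENSITIVITY,
) -> ScoreMatrix:
    """Grid of global scores for one direction (vectorized counting)."""
    direction = _as_direction(direction)
    genes = list(genes) if genes is not None else table.genes
    categories = list(categories) if categories is not None else table.categories
    unknown = [c for c in categories if c not in table.category_sizes]
    if unknown:
        raise KeyError(f"unknown drug categor(ies): {unknown}")

    rec = table.records
    counts = (
        rec[rec[direction.flag_column]]
        .groupby(["gene", "category"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=genes, columns=categories, fill_value=0)
        .fillna(0)
        .astype(int)
    )
    denom = np.array([table.category_sizes[c] for c in categories], dtype=float)
    scores = 100.0 * counts.to_numpy() / (denom[None, :] * table.n_subtypes)
    return ScoreMatrix(
        direction=direction,
        scores=pd.DataFrame(scores, index=genes, columns=categories),
        n_sig=counts,
        n_subtypes=table.n_subtypes,
    )


def score_significance_cutoff(
    scores: Iterable[float], tail_fraction: float = DEFAULT_SCORE_TAIL
) -> float:
    """Threshold at the upper ``tail_fraction`` of the score distribution.

    Linear-interpolation quantile at (1 - tail_fraction); a score is called
    significant iff strictly greater than the threshold (so an all-equal
    distribution yields nothing significant).
    """
    if not 0.0 < tail_fraction < 1.0:
        raise ValueError("tail_fraction must be in (0, 1)")
    values = np.asarray(list(scores), dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty score distribution")
    if values.size < 20:
        log.warning(
            "score cutoff computed from only %d values; quantile is unstable",
            values.size,
        )
    return float(np.quantile(values, 1.0 - tail_fraction))


def subtype_contribution(
    table: CorrelationTable, gene: str, category: str, direction
) -> pd.DataFrame:
    """Per-subtype breakdown of a global score.

    For each subtype: the percentage of the category's drugs *tested* in
    that subtype (valid, finite correlation for the gene) that carry the
    matching significance flag. Summing ``n_sig_subtype`` over subtypes
    recovers the global score's numerator.
    """
    direction = _as_direction(direction)
    if category not in table.category_sizes:
        raise KeyError(f"unknown drug category: {category!r}")
    rec = table.records
    mine = rec[(rec["gene"] == gene) & (rec["category"] == category)]
    if rec[rec["gene"] == gene].empty:
        raise KeyError(f"gene {gene!r} absent from the correlation table")
    rows = []
    for subtype, sub in mine.groupby("subtype", sort=True):
        tested = sub[np.isfinite(sub["r"].to_numpy(dtype=float))]
        n_tested = len(tested)
        n_sig = int(tested[direction.flag_column].sum())
        rows.append(
            {
                "gene": gene,
                "category": category,
                "direction": direction.value,
                "subtype": subtype,
                "n_sig_subtype": n_sig,
                "n_drugs_tested": n_tested,
                "percent": 100.0 * n_sig / n_tested if n_tested else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "category",
            "direction",
            "subtype",
            "n_sig_subtype",
            "n_drugs_tested",
            "percent",
        ],
    )


def contribution_table(
    table: CorrelationTable,
    genes: Iterable[str],
    categories: Iterable[str] | None = None,
    directions: Iterable[Direction] = (Direction.SENSITIVITY, Direction.RESISTANCE),
) -> pd.DataFrame:
    """Long-format subtype contributions for many (gene, category, direction)."""
    categories = list(categories) if categories is not None else None
    frames = []
    for gene in genes:
        cats = categories if categories is not None else sorted(table.category_sizes)
        for category in cats:
            for direction in directions:
                frames.append(subtype_contribution(table, gene, category, direction))
    if not frames:
        return pd.DataFrame(
            columns=[
                "gene",
                "category",
                "direction",
                "subtype",
                "n_sig_subtype",
                "n_drugs_tested",
                "percent",
            ]
        )
    return pd.concat(frames, ignore_index=True)
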