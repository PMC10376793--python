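"""Empirical null calibration for the z cutoff.

The default operating cutoff is the fixed ±1.7 the screen is built around;
this module provides the optional validation step: shuffle AUC values within
each (drug, subtype) group (expression fixed), recompute z, and read a
cutoff off the empirical |z| distribution at a chosen tail mass. Shuffling
within the group preserves each group's expression structure and AUC
marginal while breaking any gene-drug association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .cohort import AnalysisCohort
from .correlate import _group_correlations, _z_from_r
from .datamodel import DrugResponseTable, ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = ["NullDistribution", "permutation_null", "empirical_cutoff"]

#: below this many null values a quantile-based cutoff is unstable
MIN_STABLE_NULL = 1000


@dataclass(frozen=True)
class NullDistribution:
    """z scores computed on permuted data; reproducible given the seed."""

    z_values: np.ndarray
    n_perm: int
    seed: int

    def __len__(self) -> int:
        return len(self.z_values)


def permutation_null(
    cohort: AnalysisCohort,
    expr: ExpressionMatrix,
    resp: DrugResponseTable,
    genes: Iterable[str] | None = None,
    n_perm: int = 10,
    seed: int = 0,
) -> NullDistribution:
    """Null z distribution from within-group AUC shuffles.

    For every (gene, group) pair and each of ``n_perm`` permutations the
    group's AUC vector is shuffled across its cell lines and r, z recomputed
    exactly as in the observed analysis. The result holds
    ``n_perm * n_genes * n_groups`` values (NaN where a vector is constant).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    if genes is None:
        gene_list = list(expr.gene_ids)
    else:
        known = set(expr.gene_ids)
        gene_list = [g for g in (str(x).strip().upper() for x in genes) if g in known]
    X_all = expr.data.loc[gene_list].to_numpy(dtype=float)
    col_index = {c: i for i, c in enumerate(expr.cell_line_ids)}
    auc_wide = resp.auc_wide()

    chunks = []
    for (drug, _subtype), lines in sorted(cohort.groups.items()):
        idx = [col_index[c] for c in lines]
        X = X_all[:, idx]
        y = auc_wide.loc[drug, list(lines)].to_numpy(dtype=float)
        n = len(lines)
        for _ in range(n_perm):
            z = _z_from_r(_group_correlations(X, rng.permutation(y)), n)
            chunks.append(z)
    z_values = np.concatenate(chunks) if chunks else np.empty(0)
    if len(z_values) < MIN_STABLE_NULL:
        log.warning(
            "only %d null z values (< %d); empirical cutoff may be unstable",
            len(z_values),
            MIN_STABLE_NULL,
        )
    return NullDistribution(z_values=z_values, n_perm=n_perm, seed=seed)


def empirical_cutoff(null: NullDistribution | Iterable[float], tail_mass: float) -> float:
    """Cutoff leaving ``tail_mass`` in each tail of the null z distribution.

    Returns the (1 - 2*tail_mass) quantile of |z| (linear interpolation), a
    positive real; with a standard-normal null and tail_mass 0.0446 this is
    ~1.70.
    """
    if not 0.0 < tail_mass < 0.5:
        raise ValueError("tail_mass must be in (0, 0.5)")
    z = null.z_values if isinstance(null, NullDistribution) else np.asarray(list(null), float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("empty null distribution")
    cutoff = float(np.quantile(np.abs(z), 1.0 - 2.0 * tail_mass))
    if cutoff == 0.0:
        log.warning("degenerate null distribution: empirical cutoff is 0")
    return cutoff
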