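"""Hierarchical clustering of score and z matrices.

Rows and columns are clustered independently with Euclidean distance and
unweighted average linkage (UPGMA) — the common clustermap defaults; both
are configurable. Missing cells (e.g. a drug untested in a subtype) are
filled with 0 for the distance computation only: zero means "no evidence"
and keeps the full subtype roster in the picture. Labels are sorted before
linkage so the result is invariant to the input's row/column order, with
ties broken by label order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["ClusterResult", "hierarchical_order"]


@dataclass(frozen=True)
class ClusterResult:
    row_order: tuple[str, ...]
    col_order: tuple[str, ...]
    row_linkage: np.ndarray  # scipy linkage matrix over sorted row labels
    col_linkage: np.ndarray

    def reorder(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return matrix.loc[list(self.row_order), list(self.col_order)]


def _axis_linkage(values: np.ndarray, metric: str, method: str) -> np.ndarray:
    return hierarchy.linkage(pdist(values, metric=metric), method=method)


def hierarchical_order(
    matrix: pd.DataFrame,
    fill_missing: float = 0.0,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Cluster rows and columns of a labelled numeric grid.

    All-missing rows/columns are dropped first; at least a 2 x 2 grid must
    remain. Returns leaf orders plus the two linkage matrices (heights are
    non-decreasing along every merge path for UPGMA).
    """
    m = matrix.dropna(axis=0, how="all").dropna(axis=1, how="all")
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError(
            f"need at least 2 rows and 2 columns to cluster, got {m.shape}"
        )
    # deterministic: sort labels so equal-distance ties break by label order
    m = m.sort_index(axis=0).sort_index(axis=1)
    values = m.fillna(fill_missing).to_numpy(dtype=float)

    row_linkage = _axis_linkage(values, metric, method)
    col_linkage = _axis_linkage(values.T, metric, method)
    row_order = tuple(m.index[i] for i in hierarchy.leaves_list(row_linkage))
    col_order = tuple(m.columns[i] for i in hierarchy.leaves_list(col_linkage))
    return ClusterResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_linkage,
        col_linkage=col_linkage,
    )
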