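"""Report artifacts: bi-directional bar charts, bubble plots, clustermaps.

Every image gets a TSV twin holding exactly the plotted numbers, so all
figures are reproducible from text outputs alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cluster import ClusterResult
from .scoring import ScoreMatrix

log = logging.getLogger(__name__)

__all__ = ["render_reports"]

_SEN_COLOR = "#3b6fb6"  # blue: sensitivity
_RES_COLOR = "#c23b3b"  # red: resistance


def _safe(name: str) -> str:
    return "".join(c if (c.isalnum() or c in "-_.") else "_" for c in str(name))


def _bar_chart(gene: str, sen: ScoreMatrix, res: ScoreMatrix, out_dir: Path,
               fmt: str) -> list[Path]:
    categories = list(sen.scores.columns)
    sen_vals = sen.scores.loc[gene, categories].to_numpy(dtype=float)
    res_vals = res.scores.loc[gene, categories].to_numpy(dtype=float)
    y = np.arange(len(categories))

    fig, ax = plt.subplots(figsize=(6, max(2.0, 0.35 * len(categories))))
    ax.barh(y, -sen_vals, color=_SEN_COLOR, label="Sen-Score_global")
    ax.barh(y, res_vals, color=_RES_COLOR, label="Res-Score_global")
    if sen.score_cutoff is not None:
        ax.axvline(-sen.score_cutoff, color="black", linestyle=":", linewidth=1)
    if res.score_cutoff is not None:
        ax.axvline(res.score_cutoff, color="black", linestyle=":", linewidth=1)
    ax.axvline(0, color="black", linewidth=0.8)
    ax.set_yticks(y, categories, fontsize=7)
    ax.set_xlabel("Score_global (%)  (left: sensitivity, right: resistance)")
    ax.set_title(gene)
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    img = out_dir / f"scores_{_safe(gene)}.{fmt}"
    fig.savefig(img, dpi=150)
    plt.close(fig)

    tsv = out_dir / f"scores_{_safe(gene)}.tsv"
    pd.DataFrame(
        {"category": categories, "sen_score": sen_vals, "res_score": res_vals}
    ).to_csv(tsv, sep="\t", index=False)
    return [img, tsv]


def _bubble_plot(contrib: pd.DataFrame, direction: str, out_dir: Path,
                 fmt: str) -> list[Path]:
    sub = contrib[contrib["direction"] == direction].copy()
    img = out_dir / f"bubble_{direction}.{fmt}"
    tsv = out_dir / f"bubble_{direction}.tsv"
    sub.to_csv(tsv, sep="\t", index=False)

    cats = sorted(sub["category"].unique()) if len(sub) else []
    subtypes = sorted(sub["subtype"].unique()) if len(sub) else []
    fig, ax = plt.subplots(
        figsize=(max(3.0, 0.5 * len(cats) + 2), max(2.5, 0.35 * len(subtypes) + 1))
    )
    if len(sub):
        xi = {c: i for i, c in enumerate(cats)}
        yi = {s: i for i, s in enumerate(subtypes)}
        color = _SEN_COLOR if direction == "sensitivity" else _RES_COLOR
        ax.scatter(
            sub["category"].map(xi),
            sub["subtype"].map(yi),
            s=4.0 * sub["percent"].to_numpy(dtype=float) + 1.0,
            c=color,
            alpha=0.7,
        )
        ax.set_xticks(range(len(cats)), cats, rotation=60, ha="right", fontsize=7)
        ax.set_yticks(range(len(subtypes)), subtypes, fontsize=7)
    ax.set_title(f"% significant drugs per subtype ({direction})")
    fig.tight_layout()
    fig.savefig(img, dpi=150)
    plt.close(fig)
    return [img, tsv]


def _clustermap(name: str, matrix: pd.DataFrame, clusters: ClusterResult,
                out_dir: Path, fmt: str) -> list[Path]:
    ordered = clusters.reorder(matrix)
    tsv = out_dir / f"clustermap_{_safe(name)}.tsv"
    ordered.to_csv(tsv, sep="\t")

    fig, ax = plt.subplots(
        figsize=(
            max(3.0, 0.3 * ordered.shape[1] + 2),
            max(2.5, 0.3 * ordered.shape[0] + 1),
        )
    )
    values = ordered.to_numpy(dtype=float)
    vmax = np.nanmax(np.abs(values)) if np.isfinite(values).any() else 1.0
    mesh = ax.pcolormesh(
        np.nan_to_num(values), cmap="RdBu_r", vmin=-vmax, vmax=vmax
    )
    ax.set_xticks(
        np.arange(ordered.shape[1]) + 0.5, ordered.columns, rotation=90, fontsize=6
    )
    ax.set_yticks(np.arange(ordered.shape[0]) + 0.5, ordered.index, fontsize=6)
    ax.set_title(name, fontsize=8)
    fig.colorbar(mesh, ax=ax, shrink=0.7)
    fig.tight_layout()
    img = out_dir / f"clustermap_{_safe(name)}.{fmt}"
    fig.savefig(img, dpi=150)
    plt.close(fig)
    return [img, tsv]


def render_reports(
    sen: ScoreMatrix,
    res: ScoreMatrix,
    contributions: pd.DataFrame,
    out_dir,
    clustermaps: dict[str, tuple[pd.DataFrame, ClusterResult]] | None = None,
    fmt: str = "png",
) -> list[Path]:
    """Render all report artifacts into ``out_dir``; returns written paths.

    Per gene: a bi-directional bar chart (sensitivity left in blue,
    resistance right in red, dotted score-cutoff lines). Per direction: a
    bubble plot of subtype contributions. Plus one clustermap per entry of
    ``clustermaps`` (name -> (labelled matrix, precomputed cluster result)).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for gene in sen.scores.index:
            written += _bar_chart(gene, sen, res, out_dir, fmt)
        for direction in ("sensitivity", "resistance"):
            written += _bubble_plot(contributions, direction, out_dir, fmt)
        for name, (matrix, clusters) in (clustermaps or {}).items():
            written += _clustermap(name, matrix, clusters, out_dir, fmt)
    except OSError as exc:
        raise OSError(f"failed writing report artifact under {out_dir}: {exc}") from exc
    return written
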