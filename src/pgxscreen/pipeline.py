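"""End-to-end orchestration: ingest -> curation -> correlations ->
(optional calibration) -> global scores -> contributions -> clustering ->
reports. Writes all tabular outputs, a manifest and a copy of the config
into ``out_dir``; identical config + inputs give identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import calibrate as cal
from . import cluster as clu
from . import cohort as coh
from . import ingest
from . import report as rep
from . import scoring as sco
from .config import RunConfig
from .correlate import correlation_table, write_correlation_tsv
from .scoring import Direction

log = logging.getLogger(__name__)

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the culprit."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - deliberately broad
                raise PipelineError(name, exc) from exc

        return inner

    return wrap


@_stage("ingest")
def _ingest(config: RunConfig):
    expr = ingest.read_expression(
        config.expression,
        ingest.ExpressionDialect(
            genes_in_rows=config.expression_genes_in_rows,
            delimiter=config.delimiter,
        ),
    )
    resp = ingest.read_drug_response(
        config.response,
        ingest.ResponseDialect(
            drug_column=config.response_drug_column,
            cell_line_column=config.response_cell_line_column,
            auc_column=config.response_auc_column,
            delimiter=config.delimiter,
        ),
    )
    catalog = ingest.read_drug_catalog(
        config.catalog, ingest.TableDialect(config.delimiter)
    )
    meta = ingest.read_cell_line_metadata(
        config.metadata, ingest.TableDialect(config.delimiter)
    )
    return expr, resp, catalog, meta


@_stage("cohort_filter")
def _curate(config: RunConfig, expr, resp, catalog, meta):
    catalog = coh.merge_drug_categories(
        catalog, tuple(tuple(m) for m in config.category_merges)
    )
    catalog = coh.filter_drug_categories(catalog, config.min_drugs_per_category)
    meta = coh.exclude_tissues(meta, tuple(config.excluded_tissues))
    cohort = coh.build_cohort(expr, resp, catalog, meta, config.min_lines_per_group)
    return catalog, cohort


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full screen; returns the manifest (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    config.to_yaml(out_dir / "run_config.yaml")

    expr, resp, catalog, meta = _ingest(config)
    catalog, cohort = _curate(config, expr, resp, catalog, meta)

    # correlations (optionally with a permutation-calibrated cutoff)
    try:
        z_cutoff = config.z_cutoff
        calibration = None
        if config.calibrate:
            null = cal.permutation_null(
                cohort,
                expr,
                resp,
                genes=expr.gene_ids[: config.calibration_genes],
                n_perm=config.n_perm,
                seed=config.seed,
            )
            z_cutoff = cal.empirical_cutoff(null, config.tail_mass)
            calibration = {
                "n_null": len(null),
                "tail_mass": config.tail_mass,
                "empirical_cutoff": z_cutoff,
            }
            log.info("calibrated z cutoff: %.4f (%d null values)", z_cutoff, len(null))
        table = correlation_table(
            cohort, expr, resp, genes=config.gene_list(), cutoff=z_cutoff
        )
    except Exception as exc:
        raise PipelineError("correlation_engine", exc) from exc

    try:
        sen = sco.score_matrix(table, direction=Direction.SENSITIVITY)
        res = sco.score_matrix(table, direction=Direction.RESISTANCE)
        sen = sen.with_cutoff(
            sco.score_significance_cutoff(sen.flat_scores(), config.score_tail)
        )
        res = res.with_cutoff(
            sco.score_significance_cutoff(res.flat_scores(), config.score_tail)
        )
        # contributions for genes carrying at least one significant score
        hit_genes = sorted(
            set(sen.scores.index[sen.significant.any(axis=1)])
            | set(res.scores.index[res.significant.any(axis=1)])
        )
        contributions = sco.contribution_table(table, hit_genes)
    except Exception as exc:
        raise PipelineError("global_scoring", exc) from exc

    try:
        clustermaps = _build_clustermaps(table, sen, res, config.max_clustermaps)
        cluster_orders = {
            name: {"row_order": list(c.row_order), "col_order": list(c.col_order)}
            for name, (_, c) in clustermaps.items()
        }
        # cluster the score matrices themselves when large enough
        for label, mat in (("sen_scores", sen.scores), ("res_scores", res.scores)):
            if mat.shape[0] >= 2 and mat.shape[1] >= 2:
                c = clu.hierarchical_order(mat)
                cluster_orders[label] = {
                    "row_order": list(c.row_order),
                    "col_order": list(c.col_order),
                }
    except Exception as exc:
        raise PipelineError("cluster_report", exc) from exc

    outputs = {
        "correlations": out_dir / "correlations.tsv",
        "sen_scores": out_dir / "scores_sensitivity.tsv",
        "res_scores": out_dir / "scores_resistance.tsv",
        "contributions": out_dir / "contributions.tsv",
        "cluster_orders": out_dir / "cluster_orders.json",
        "manifest": out_dir / "manifest.json",
    }
    write_correlation_tsv(table, outputs["correlations"])
    sen.scores.to_csv(outputs["sen_scores"], sep="\t", index_label="gene")
    res.scores.to_csv(outputs["res_scores"], sep="\t", index_label="gene")
    contributions.to_csv(outputs["contributions"], sep="\t", index=False)
    outputs["cluster_orders"].write_text(json.dumps(cluster_orders, indent=2))

    images: list[str] = []
    if config.make_plots:
        try:
            written = rep.render_reports(
                sen,
                res,
                contributions,
                out_dir / "figures",
                clustermaps=clustermaps,
                fmt=config.plot_format,
            )
            images = [str(p) for p in written]
        except Exception as exc:
            raise PipelineError("cluster_report", exc) from exc

    manifest = {
        "n_genes": len(table.genes),
        "n_groups": len(cohort.groups),
        "n_subtypes": cohort.subtype_count,
        "n_categories": len(table.category_sizes),
        "n_records": len(table),
        "z_cutoff": float(table.cutoff),
        "score_cutoff_sensitivity": sen.score_cutoff,
        "score_cutoff_resistance": res.score_cutoff,
        "calibration": calibration,
        "significant_genes": hit_genes,
        "outputs": {k: str(v) for k, v in outputs.items()},
        "figures": images,
        "seed": config.seed,
    }
    outputs["manifest"].write_text(json.dumps(manifest, indent=2))
    return manifest


def _build_clustermaps(table, sen, res, max_maps: int):
    """Z-matrix (drugs x subtypes) clustermaps for significant (gene, category)
    pairs, capped at ``max_maps``."""
    pairs = []
    for mat in (sen, res):
        sig = mat.significant
        for gene in sig.index:
            for category in sig.columns:
                if sig.loc[gene, category]:
                    pairs.append((gene, category))
    seen, ordered = set(), []
    for p in pairs:
        if p not in seen:
            seen.add(p)
            ordered.append(p)
    clustermaps = {}
    rec = table.records
    for gene, category in ordered[:max_maps]:
        sub = rec[(rec["gene"] == gene) & (rec["category"] == category)]
        z = sub.pivot(index="drug_id", columns="subtype", values="z")
        if z.shape[0] < 2 or z.shape[1] < 2:
            continue
        try:
            clusters = clu.hierarchical_order(z)
        except ValueError:
            continue
        clustermaps[f"{gene}_{category}"] = (z, clusters)
    return clustermaps
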