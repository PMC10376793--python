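"""Synthetic CCLE/GDSC-shaped data with known planted structure.

The generator emits the four pipeline inputs (expression matrix, AUC
response table, drug catalog, cell-line metadata) at configurable sizes,
with optional *planted effects*: population-level Pearson correlations of
chosen sign and magnitude between one gene's expression and the AUC of a
fraction of one category's drugs in chosen subtypes.

Effects are planted at the correlation level: within an affected
(drug, subtype) group the latent AUC signal is

    u = target_r * standardize(expression of the gene) + sqrt(1 - target_r^2) * noise

so the population correlation equals ``target_r`` before the affine map
into AUC scale and clipping to (0, 1]. Negative ``target_r`` plants a
sensitivity association (high expression, low AUC), positive plants
resistance. Drug-to-category assignment is a deterministic block partition,
so :func:`planted_truth` derives the affected (gene, drug, subtype) triples
from the config alone.

Defaults emulate a GDSC-like solid-tumor panel: AUC base mean 0.85, s.d.
0.08 (resistant-skewed), expression means uniform in [1, 8] log2 units with
unit s.d., six subtypes of 25 lines, three 20-drug categories.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .datamodel import (
    CellLineMetadata,
    DrugCatalog,
    DrugResponseTable,
    ExpressionMatrix,
)
from . import ingest

log = logging.getLogger(__name__)

__all__ = [
    "PlantedEffect",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dataset",
    "planted_truth",
    "write_dataset",
]

_AUC_FLOOR = 1e-6  # AUC is strictly positive


@dataclass(frozen=True)
class PlantedEffect:
    """One planted gene-category association.

    ``drug_fraction`` of the category's drugs (rounded down) are affected in
    each listed subtype; ``target_r`` is the population Pearson correlation
    (negative = sensitivity, positive = resistance).
    """

    gene: str
    category: str
    subtypes: tuple[str, ...]
    drug_fraction: float = 1.0
    target_r: float = -0.6

    def __post_init__(self) -> None:
        if not -1.0 < self.target_r < 1.0:
            raise ValueError("target_r must lie strictly inside (-1, 1)")
        if not 0.0 < self.drug_fraction <= 1.0:
            raise ValueError("drug_fraction must be in (0, 1]")
        if not self.subtypes:
            raise ValueError("planted effect needs at least one subtype")


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 200
    n_drugs: int = 60
    n_categories: int = 3
    n_subtypes: int = 6
    lines_per_subtype: int = 25
    auc_base_mean: float = 0.85
    auc_base_sd: float = 0.08
    expr_mean_low: float = 1.0
    expr_mean_high: float = 8.0
    expr_sd: float = 1.0
    planted: tuple[PlantedEffect, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_drugs, self.n_categories, self.n_subtypes,
               self.lines_per_subtype) < 1:
            raise ValueError("all size parameters must be >= 1")
        if self.n_categories > self.n_drugs:
            raise ValueError("more categories than drugs")

    # -- deterministic naming / partitioning (no RNG involved) --------------

    @property
    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def drug_names(self) -> list[str]:
        width = max(3, len(str(self.n_drugs)))
        return [f"D{i + 1:0{width}d}" for i in range(self.n_drugs)]

    @property
    def subtype_names(self) -> list[str]:
        return [f"SUBTYPE{i + 1}" for i in range(self.n_subtypes)]

    @property
    def cell_line_names(self) -> list[str]:
        total = self.n_subtypes * self.lines_per_subtype
        width = max(4, len(str(total)))
        return [f"CL{i + 1:0{width}d}" for i in range(total)]

    def category_blocks(self) -> dict[str, list[str]]:
        """Deterministic near-equal block partition of drugs into categories."""
        drugs = self.drug_names
        base, extra = divmod(self.n_drugs, self.n_categories)
        blocks: dict[str, list[str]] = {}
        start = 0
        for i in range(self.n_categories):
            size = base + (1 if i < extra else 0)
            blocks[f"CAT{i + 1}"] = drugs[start : start + size]
            start += size
        return blocks

    def subtype_lines(self) -> dict[str, list[str]]:
        lines = self.cell_line_names
        k = self.lines_per_subtype
        return {
            s: lines[i * k : (i + 1) * k] for i, s in enumerate(self.subtype_names)
        }


class SyntheticDataset(NamedTuple):
    expression: ExpressionMatrix
    response: DrugResponseTable
    catalog: DrugCatalog
    metadata: CellLineMetadata


def planted_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Ground truth: every affected (gene, drug, subtype) with expected sign."""
    blocks = config.category_blocks()
    rows = []
    for effect in config.planted:
        drugs = _affected_drugs(effect, blocks)
        sign = -1 if effect.target_r < 0 else 1
        for subtype in effect.subtypes:
            for drug in drugs:
                rows.append(
                    {
                        "gene": effect.gene,
                        "drug_id": drug,
                        "subtype": subtype,
                        "expected_sign": sign,
                        "target_r": effect.target_r,
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene", "drug_id", "subtype", "expected_sign", "target_r"]
    )


def _affected_drugs(effect: PlantedEffect, blocks: dict[str, list[str]]) -> list[str]:
    if effect.category not in blocks:
        raise ValueError(f"planted effect references unknown category "
                         f"{effect.category!r}")
    members = blocks[effect.category]
    exact = effect.drug_fraction * len(members)
    n_affected = math.floor(exact)
    if n_affected != exact:
        warnings.warn(
            f"drug_fraction {effect.drug_fraction} of {len(members)} drugs is "
            f"fractional; rounding down to {n_affected}",
            stacklevel=3,
        )
    if n_affected < 1:
        raise ValueError("planted effect affects zero drugs; raise drug_fraction")
    return members[:n_affected]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset; byte-identical for identical configs (same seed)."""
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names
    drugs = config.drug_names
    lines = config.cell_line_names
    blocks = config.category_blocks()
    by_subtype = config.subtype_lines()

    _validate_planted(config, blocks, by_subtype)

    # expression: per-gene mean ~ U[low, high], Normal noise, truncated at 0
    means = rng.uniform(config.expr_mean_low, config.expr_mean_high, config.n_genes)
    expr_values = rng.normal(
        means[:, None], config.expr_sd, (config.n_genes, len(lines))
    ).clip(min=0.0)
    expr = ExpressionMatrix(pd.DataFrame(expr_values, index=genes, columns=lines))

    # latent standard-normal AUC signal per (drug, line); planted groups get
    # a blend of the gene's standardized expression and the existing noise
    u = rng.standard_normal((config.n_drugs, len(lines)))
    line_index = {c: i for i, c in enumerate(lines)}
    drug_index = {d: i for i, d in enumerate(drugs)}
    gene_index = {g: i for i, g in enumerate(genes)}
    for effect in config.planted:
        affected = _affected_drugs(effect, blocks)
        gi = gene_index[effect.gene]
        w = math.sqrt(1.0 - effect.target_r**2)
        for subtype in effect.subtypes:
            idx = np.array([line_index[c] for c in by_subtype[subtype]])
            g = expr_values[gi, idx]
            sd = g.std()
            gs = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)
            for drug in affected:
                di = drug_index[drug]
                u[di, idx] = effect.target_r * gs + w * u[di, idx]

    auc = config.auc_base_mean + config.auc_base_sd * u
    clipped = (auc <= _AUC_FLOOR) | (auc > 1.0)
    frac_clipped = float(clipped.mean())
    if frac_clipped >= 0.01:
        warnings.warn(
            f"{100 * frac_clipped:.1f}% of AUC values clipped into (0, 1]; "
            "planted correlations may be attenuated",
            stacklevel=2,
        )
    auc = auc.clip(_AUC_FLOOR, 1.0)

    response = DrugResponseTable(
        pd.DataFrame(
            {
                "drug_id": np.repeat(drugs, len(lines)),
                "cell_line_id": np.tile(lines, config.n_drugs),
                "auc": auc.ravel(),
            }
        )
    )

    catalog = DrugCatalog(
        pd.DataFrame(
            [
                {
                    "drug_id": d,
                    "drug_name": f"drug-{d.lower()}",
                    "targets": f"TGT{(drug_index[d] % 7) + 1}",
                    "category": cat,
                }
                for cat, members in blocks.items()
                for d in members
            ]
        )
    )

    # two subtypes per tissue keeps the tissue layer non-trivial
    metadata = CellLineMetadata(
        pd.DataFrame(
            [
                {
                    "cell_line_id": c,
                    "tissue": f"TISSUE{(i // 2) + 1}",
                    "subtype": s,
                }
                for i, s in enumerate(config.subtype_names)
                for c in by_subtype[s]
            ]
        )
    )
    return SyntheticDataset(expr, response, catalog, metadata)


def _validate_planted(config, blocks, by_subtype) -> None:
    gene_set = set(config.gene_names)
    claimed: set[tuple[str, str]] = set()
    for effect in config.planted:
        if effect.gene not in gene_set:
            raise ValueError(f"planted effect references unknown gene {effect.gene!r}")
        unknown = set(effect.subtypes) - set(by_subtype)
        if unknown:
            raise ValueError(f"planted effect references unknown subtype(s) {sorted(unknown)}")
        for drug in _affected_drugs(effect, blocks):
            for subtype in effect.subtypes:
                key = (drug, subtype)
                if key in claimed:
                    raise ValueError(
                        f"two planted effects claim (drug {drug!r}, subtype "
                        f"{subtype!r}); overlapping effects are ambiguous"
                    )
                claimed.add(key)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write the four inputs as CSV in the default ingest dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.csv",
        "response": out_dir / "response.csv",
        "catalog": out_dir / "drug_catalog.csv",
        "metadata": out_dir / "cell_line_metadata.csv",
    }
    ingest.write_expression(dataset.expression, paths["expression"])
    ingest.write_drug_response(dataset.response, paths["response"])
    ingest.write_drug_catalog(dataset.catalog, paths["catalog"])
    ingest.write_cell_line_metadata(dataset.metadata, paths["metadata"])
    return paths
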