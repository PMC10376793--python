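"""Run configuration: one serializable object holding every knob.

All screen constants (z cutoff 1.7, min 10 drugs/category, min 10 cell
lines/group, 5% score tail, the default category merges and tissue
exclusions) live here as config defaults, never as literals in the
pipeline code, so both the real-data reproduction and synthetic runs can
override them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .cohort import DEFAULT_CATEGORY_MERGES, DEFAULT_EXCLUDED_TISSUES

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # input paths
    expression: str = ""
    response: str = ""
    catalog: str = ""
    metadata: str = ""
    out_dir: str = "pgxscreen_out"

    # gene panel: "all" or an explicit list of symbols
    genes: str | list[str] = "all"

    # ingest dialects
    expression_genes_in_rows: bool = True
    response_drug_column: str = "drug_id"
    response_cell_line_column: str = "cell_line_id"
    response_auc_column: str = "auc"
    delimiter: str | None = None

    # curation
    min_drugs_per_category: int = 10
    min_lines_per_group: int = 10
    excluded_tissues: list[str] = field(
        default_factory=lambda: list(DEFAULT_EXCLUDED_TISSUES)
    )
    category_merges: list[list[str]] = field(
        default_factory=lambda: [list(m) for m in DEFAULT_CATEGORY_MERGES]
    )

    # correlation / significance
    z_cutoff: float = 1.7
    calibrate: bool = False  # replace z_cutoff with the permutation cutoff
    n_perm: int = 20
    tail_mass: float = 0.0446
    calibration_genes: int = 50  # genes sampled for the permutation null

    # scoring
    score_tail: float = 0.05

    # reporting
    make_plots: bool = True
    max_clustermaps: int = 20
    plot_format: str = "png"

    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def gene_list(self) -> list[str] | None:
        """None means 'all genes in the expression matrix'."""
        if isinstance(self.genes, str):
            if self.genes.lower() == "all":
                return None
            return [self.genes]
        return list(self.genes)
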