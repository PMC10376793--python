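"""Shared fixtures: toy tables and small synthetic datasets.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write into tmp_path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pgxscreen as px
from pgxscreen.cohort import build_cohort


def make_catalog(category_sizes: dict[str, int], start: int = 1) -> px.DrugCatalog:
    """Toy catalog with ``category_sizes`` drugs per category."""
    rows = []
    i = start
    for category, size in category_sizes.items():
        for _ in range(size):
            rows.append(
                {
                    "drug_id": f"D{i:03d}",
                    "drug_name": f"drug-{i}",
                    "targets": "TGT1",
                    "category": category,
                }
            )
            i += 1
    return px.DrugCatalog(pd.DataFrame(rows))


def make_metadata(subtype_tissues: dict[str, tuple[str, int]]) -> px.CellLineMetadata:
    """Toy metadata: subtype -> (tissue, n_lines)."""
    rows = []
    i = 1
    for subtype, (tissue, n) in subtype_tissues.items():
        for _ in range(n):
            rows.append({"cell_line_id": f"CL{i:03d}", "tissue": tissue, "subtype": subtype})
            i += 1
    return px.CellLineMetadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def tiny_dataset():
    """5 genes x 4 drugs x 2 subtypes, 12 lines each, no planted effects."""
    cfg = px.SyntheticConfig(
        n_genes=5,
        n_drugs=4,
        n_categories=2,
        n_subtypes=2,
        lines_per_subtype=12,
        seed=11,
    )
    return cfg, px.generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_dataset):
    _, ds = tiny_dataset
    return build_cohort(ds.expression, ds.response, ds.catalog, ds.metadata, min_lines=10)


@pytest.fixture(scope="session")
def tiny_table(tiny_dataset, tiny_cohort):
    _, ds = tiny_dataset
    return px.correlation_table(tiny_cohort, ds.expression, ds.response)


@pytest.fixture(scope="session")
def planted_config():
    """Recovery scenario: r = -0.6 between G0001 and 80% of CAT1's 20 drugs
    in 3 of 6 subtypes, 25 lines per subtype."""
    return px.SyntheticConfig(
        n_genes=200,
        n_drugs=60,
        n_categories=3,
        n_subtypes=6,
        lines_per_subtype=25,
        planted=(
            px.PlantedEffect(
                gene="G0001",
                category="CAT1",
                subtypes=("SUBTYPE1", "SUBTYPE2", "SUBTYPE3"),
                drug_fraction=0.8,
                target_r=-0.6,
            ),
        ),
        seed=3,
    )


def brute_force_records(cohort, expr, resp, genes, cutoff):
    """Independent recomputation of the correlation table with plain loops
    and explicit product-moment / atanh formulas."""
    import math

    auc = resp.data.set_index(["drug_id", "cell_line_id"])["auc"]
    rows = []
    for (drug, subtype), lines in sorted(cohort.groups.items()):
        y = [float(auc[(drug, c)]) for c in lines]
        n = len(y)
        my = sum(y) / n
        for gene in genes:
            x = [float(expr.data.at[gene, c]) for c in lines]
            mx = sum(x) / n
            sxx = sum((v - mx) ** 2 for v in x)
            syy = sum((v - my) ** 2 for v in y)
            sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
            if sxx == 0.0 or syy == 0.0:
                r = z = float("nan")
                sig_pos = sig_neg = False
            else:
                r = sxy / math.sqrt(sxx * syy)
                r = max(-1.0, min(1.0, r))
                rc = max(-(1 - 1e-7), min(1 - 1e-7, r))
                z = math.atanh(rc) * math.sqrt(n - 3)
                sig_pos = z >= cutoff
                sig_neg = z <= -cutoff
            rows.append(
                {
                    "gene": gene,
                    "drug_id": drug,
                    "subtype": subtype,
                    "n": n,
                    "r": r,
                    "z": z,
                    "sig_pos": sig_pos,
                    "sig_neg": sig_neg,
                }
            )
    return pd.DataFrame(rows)
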