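"""Synthetic-data generator: determinism, validity, planted structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pgxscreen as px
from pgxscreen.simulate import (
    PlantedEffect,
    SyntheticConfig,
    generate_dataset,
    planted_truth,
)


class TestConfigValidation:
    def test_bad_target_r_rejected(self):
        with pytest.raises(ValueError, match="target_r"):
            PlantedEffect(gene="G1", category="C", subtypes=("S",), target_r=1.0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="drug_fraction"):
            PlantedEffect(gene="G1", category="C", subtypes=("S",), drug_fraction=0.0)

    def test_unknown_gene_rejected(self):
        cfg = SyntheticConfig(
            n_genes=5, n_drugs=10, n_categories=1, n_subtypes=2,
            lines_per_subtype=10,
            planted=(PlantedEffect(gene="NOPE", category="CAT1", subtypes=("SUBTYPE1",)),),
        )
        with pytest.raises(ValueError, match="unknown gene"):
            generate_dataset(cfg)

    def test_overlapping_effects_rejected(self):
        effects = (
            PlantedEffect(gene="G0001", category="CAT1", subtypes=("SUBTYPE1",)),
            PlantedEffect(gene="G0002", category="CAT1", subtypes=("SUBTYPE1",)),
        )
        cfg = SyntheticConfig(
            n_genes=5, n_drugs=10, n_categories=1, n_subtypes=2,
            lines_per_subtype=10, planted=effects,
        )
        with pytest.raises(ValueError, match="overlapping"):
            generate_dataset(cfg)

    def test_fractional_drug_count_rounded_down_with_warning(self):
        cfg = SyntheticConfig(
            n_genes=5, n_drugs=10, n_categories=1, n_subtypes=2,
            lines_per_subtype=10,
            planted=(
                PlantedEffect(
                    gene="G0001", category="CAT1", subtypes=("SUBTYPE1",),
                    drug_fraction=0.75,  # 7.5 of 10 drugs
                ),
            ),
        )
        with pytest.warns(UserWarning, match="rounding down to 7"):
            truth = planted_truth(cfg)
        assert truth["drug_id"].nunique() == 7


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(n_genes=10, n_drugs=12, n_categories=2,
                              n_subtypes=2, lines_per_subtype=10, seed=5)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        px.write_dataset(a, tmp_path / "a")
        px.write_dataset(b, tmp_path / "b")
        for name in ("expression.csv", "response.csv", "drug_catalog.csv",
                     "cell_line_metadata.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seed_differs(self):
        base = dict(n_genes=10, n_drugs=12, n_categories=2, n_subtypes=2,
                    lines_per_subtype=10)
        a = generate_dataset(SyntheticConfig(seed=1, **base))
        b = generate_dataset(SyntheticConfig(seed=2, **base))
        assert not a.expression.data.equals(b.expression.data)


def test_outputs_pass_ingest_validators(tmp_path, tiny_dataset):
    """Generated files re-read through the ingest layer unmodified."""
    _, ds = tiny_dataset
    paths = px.write_dataset(ds, tmp_path)
    px.read_expression(paths["expression"])
    px.read_drug_response(paths["response"])
    px.read_drug_catalog(paths["catalog"])
    px.read_cell_line_metadata(paths["metadata"])


def test_default_noise_clipping_fraction_warned():
    """The resistant-skewed default AUC scale (mean 0.85, sd 0.08) pushes a
    few percent of draws past 1.0; the generator must say so."""
    cfg = SyntheticConfig(n_genes=5, n_drugs=20, n_categories=2, n_subtypes=3,
                          lines_per_subtype=20, seed=2)
    with pytest.warns(UserWarning, match="clipped"):
        ds = generate_dataset(cfg)
    auc = ds.response.data["auc"]
    assert ((auc > 0) & (auc <= 1)).all()


def test_no_effect_mean_abs_correlation_matches_sampling_noise():
    """With no planted effects the mean |r| across pairs is pure sampling
    noise: E|r| ~= sqrt(2 / (pi * (n - 1))) for group size n, and nowhere
    near planted effect magnitudes."""
    n = 20
    cfg = SyntheticConfig(n_genes=200, n_drugs=10, n_categories=1,
                          n_subtypes=4, lines_per_subtype=n, seed=13)
    ds = generate_dataset(cfg)
    cohort = px.build_cohort(ds.expression, ds.response, ds.catalog, ds.metadata, 10)
    table = px.correlation_table(cohort, ds.expression, ds.response)
    observed = table.records["r"].abs().mean()
    expected = np.sqrt(2 / (np.pi * (n - 1)))  # half-normal mean, sd 1/sqrt(n-1)
    assert observed == pytest.approx(expected, abs=0.02)
    assert observed < 0.25


def test_planted_effect_recovered_in_empirical_r():
    """Planted r = -0.6 at n = 25: empirical r within +/-0.25 of the target
    for >= 80% of affected (drug, subtype) pairs, pooled over seeds."""
    hits = total = 0
    for seed in range(5):
        cfg = SyntheticConfig(
            n_genes=20, n_drugs=20, n_categories=1, n_subtypes=3,
            lines_per_subtype=25,
            planted=(
                PlantedEffect(gene="G0001", category="CAT1",
                              subtypes=("SUBTYPE1", "SUBTYPE2"),
                              drug_fraction=1.0, target_r=-0.6),
            ),
            seed=100 + seed,
        )
        ds = generate_dataset(cfg)
        cohort = px.build_cohort(ds.expression, ds.response, ds.catalog,
                                 ds.metadata, 10)
        table = px.correlation_table(cohort, ds.expression, ds.response,
                                     genes=["G0001"])
        truth = planted_truth(cfg)
        merged = truth.merge(table.records, on=["gene", "drug_id", "subtype"])
        assert len(merged) == len(truth)
        hits += int((merged["r"].sub(-0.6).abs() < 0.25).sum())
        total += len(merged)
    assert hits / total >= 0.8


class TestPlantedTruth:
    def test_cardinality(self):
        cfg = SyntheticConfig(
            n_genes=5, n_drugs=20, n_categories=1, n_subtypes=3,
            lines_per_subtype=10,
            planted=(
                PlantedEffect(gene="G0001", category="CAT1",
                              subtypes=("SUBTYPE1", "SUBTYPE2"),
                              drug_fraction=0.5),
            ),
        )
        truth = planted_truth(cfg)
        assert len(truth) == 10 * 2  # 10 drugs x 2 subtypes
        assert (truth["expected_sign"] == -1).all()

    def test_empty_when_nothing_planted(self):
        assert planted_truth(SyntheticConfig()).empty

    def test_truth_contained_in_generated_groups(self, planted_config):
        ds = generate_dataset(planted_config)
        cohort = px.build_cohort(ds.expression, ds.response, ds.catalog,
                                 ds.metadata, 10)
        truth = planted_truth(planted_config)
        groups = set(cohort.groups)
        assert all(
            (row.drug_id, row.subtype) in groups for row in truth.itertuples()
        )
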