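"""Global scores, score-significance cutoff, subtype contributions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pgxscreen as px
from pgxscreen.correlate import CorrelationTable
from pgxscreen.scoring import (
    Direction,
    contribution_table,
    global_score,
    score_matrix,
    score_significance_cutoff,
    subtype_contribution,
)


def make_table(rows, category_sizes, n_subtypes, cutoff=1.7) -> CorrelationTable:
    """Hand-built correlation table: rows of
    (gene, drug, category, subtype, r, z)."""
    records = pd.DataFrame(
        rows, columns=["gene", "drug_id", "category", "subtype", "r", "z"]
    )
    records["n"] = 20
    records["sig_pos"] = records["z"].ge(cutoff).fillna(False)
    records["sig_neg"] = records["z"].le(-cutoff).fillna(False)
    return CorrelationTable(
        records=records,
        cutoff=cutoff,
        category_sizes=category_sizes,
        n_subtypes=n_subtypes,
    )


def counting_fixture():
    """20-drug category, 5 subtypes, 10 significant sensitivity records ->
    score exactly 10.0."""
    rows = []
    for s in range(5):
        for d in range(20):
            z = -2.5 if (s < 2 and d < 5) else 0.1  # 2*5 = 10 significant
            rows.append(("TRAP1", f"D{d:02d}", "Mitosis", f"S{s}", np.tanh(z), z))
    return make_table(rows, {"Mitosis": 20}, n_subtypes=5)


class TestGlobalScore:
    def test_enumerated_count(self):
        gs = global_score(counting_fixture(), "TRAP1", "Mitosis", "sensitivity")
        assert gs.n_sig == 10
        assert gs.score == pytest.approx(100 * 10 / (20 * 5))  # exactly 10.0
        assert gs.score == 10.0

    def test_zero_significant(self):
        gs = global_score(counting_fixture(), "TRAP1", "Mitosis", "resistance")
        assert gs.n_sig == 0 and gs.score == 0.0

    def test_full_saturation_is_100(self):
        rows = [
            ("G1", f"D{d}", "C", f"S{s}", -0.9, -5.0)
            for d in range(3)
            for s in range(2)
        ]
        table = make_table(rows, {"C": 3}, n_subtypes=2)
        assert global_score(table, "G1", "C", "sensitivity").score == 100.0

    def test_absent_gene_rejected(self):
        with pytest.raises(KeyError, match="NOPE"):
            global_score(counting_fixture(), "NOPE", "Mitosis", "sensitivity")

    def test_untested_combinations_count_in_denominator(self):
        # only 1 of 2 subtypes tested: denominator still n_drugs * n_subtypes
        rows = [("G1", "D1", "C", "S1", -0.9, -5.0)]
        table = make_table(rows, {"C": 2}, n_subtypes=2)
        assert global_score(table, "G1", "C", "sensitivity").score == 25.0


class TestScoreMatrix:
    def test_cardinality(self, tiny_table):
        m = score_matrix(tiny_table, genes=["G0001", "G0002", "G0003"],
                         direction="sensitivity")
        assert m.scores.shape == (3, 2)

    def test_matches_per_cell_global_score(self, tiny_table):
        m = score_matrix(tiny_table, direction=Direction.RESISTANCE)
        for gene in tiny_table.genes:
            for category in tiny_table.categories:
                gs = global_score(tiny_table, gene, category, "resistance")
                assert m.scores.loc[gene, category] == pytest.approx(gs.score)
                assert m.n_sig.loc[gene, category] == gs.n_sig

    def test_directions_independent(self, tiny_table):
        sen = score_matrix(tiny_table, direction="sensitivity")
        res = score_matrix(tiny_table, direction="resistance")
        rec = tiny_table.records
        assert sen.n_sig.to_numpy().sum() == int(rec["sig_neg"].sum())
        assert res.n_sig.to_numpy().sum() == int(rec["sig_pos"].sum())


class TestScoreCutoff:
    def test_linear_interpolation_quantile(self):
        scores = list(range(100))
        assert score_significance_cutoff(scores, 0.05) == pytest.approx(94.05)

    def test_all_equal_nothing_significant(self):
        m = px.ScoreMatrix(
            direction=Direction.SENSITIVITY,
            scores=pd.DataFrame(5.0, index=["a", "b", "c", "d"], columns=["x", "y"]),
            n_sig=pd.DataFrame(1, index=["a", "b", "c", "d"], columns=["x", "y"]),
            n_subtypes=2,
        ).with_cutoff(score_significance_cutoff([5.0] * 25, 0.05))
        assert not m.significant.any().any()

    def test_half_tail_is_median(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 40, 501)
        assert score_significance_cutoff(scores, 0.5) == pytest.approx(
            np.median(scores)
        )

    def test_few_scores_warn(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="pgxscreen.scoring"):
            score_significance_cutoff([1.0, 2.0, 3.0], 0.05)
        assert "unstable" in caplog.text


class TestSubtypeContribution:
    def test_enumerated_percentage(self):
        # 16 category drugs tested in subtype S0, 10 significant -> 62.5%
        rows = []
        for d in range(16):
            z = -2.0 if d < 10 else 0.0
            rows.append(("G1", f"D{d:02d}", "C", "S0", np.tanh(z), z))
        table = make_table(rows, {"C": 16}, n_subtypes=1)
        contrib = subtype_contribution(table, "G1", "C", "sensitivity")
        assert contrib.loc[0, "n_drugs_tested"] == 16
        assert contrib.loc[0, "n_sig_subtype"] == 10
        assert contrib.loc[0, "percent"] == pytest.approx(62.5)

    def test_no_significant_drugs_is_zero(self):
        rows = [("G1", "D1", "C", "S0", 0.1, 0.2), ("G1", "D2", "C", "S0", 0.0, 0.0)]
        table = make_table(rows, {"C": 2}, n_subtypes=1)
        contrib = subtype_contribution(table, "G1", "C", "resistance")
        assert contrib["percent"].tolist() == [0.0]

    def test_untested_drugs_excluded_from_denominator(self):
        rows = [
            ("G1", "D1", "C", "S0", -0.8, -3.0),
            ("G1", "D2", "C", "S0", np.nan, np.nan),  # constant vector: not tested
        ]
        table = make_table(rows, {"C": 2}, n_subtypes=1)
        contrib = subtype_contribution(table, "G1", "C", "sensitivity")
        assert contrib.loc[0, "n_drugs_tested"] == 1
        assert contrib.loc[0, "percent"] == pytest.approx(100.0)

    @pytest.mark.parametrize("direction", ["sensitivity", "resistance"])
    def test_conservation_against_global_score(self, tiny_table, direction):
        """Sum of per-subtype numerators equals the global numerator."""
        for gene in tiny_table.genes:
            for category in tiny_table.categories:
                gs = global_score(tiny_table, gene, category, direction)
                contrib = subtype_contribution(tiny_table, gene, category, direction)
                assert contrib["n_sig_subtype"].sum() == gs.n_sig


def test_contribution_table_shape(tiny_table):
    df = contribution_table(tiny_table, genes=["G0001"])
    # 2 categories x 2 directions x 2 subtypes
    assert len(df) == 8
    assert set(df["direction"]) == {"sensitivity", "resistance"}
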