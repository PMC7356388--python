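"""Ordinal/length profiles and cross-component difference correlations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import _analyze
from methcomp.profiles import (
    difference_correlation,
    length_profile,
    levels_frame,
    ordinal_profile,
)
from methcomp.region_stats import RegionTestResult
from methcomp.synthetic import SyntheticConfig

NO_ISLANDS = {k: 0.0 for k in ("promoter", "exon_first", "exon_later",
                               "intron_first", "intron_later")}


def _levels_row(kind, ordinal, level, gene="g1", island=False, length=100, group="low"):
    return {
        "gene_id": gene, "chrom": "chr1", "component_kind": kind,
        "ordinal": ordinal, "cpg_island": island, "length": length,
        "group": group, "level": level,
    }


class TestOrdinalProfile:
    def test_small_genes_leave_high_ordinals_empty(self):
        rows = [
            _levels_row("exon", o, 0.2, gene=f"g{i}")
            for i in range(4)
            for o in (1, 2, 3)
        ]
        prof = ordinal_profile(pd.DataFrame(rows), cap=20)
        labels = set(prof.table["ordinal_label"])
        assert labels == {"1", "2", "3"}
        assert "overflow" not in labels

    def test_overflow_pooled_and_captured_fraction(self):
        rows = [_levels_row("exon", o, 0.5, gene=f"g{o}") for o in range(1, 26)]
        prof = ordinal_profile(pd.DataFrame(rows), cap=20)
        overflow = prof.table[prof.table["ordinal_label"] == "overflow"]
        assert int(overflow["n"].iloc[0]) == 5
        assert prof.captured_fraction[("exon", False)] == pytest.approx(20 / 25)

    def test_region_counts_sum_to_regions_per_kind(self, recovery_analysis):
        levels = levels_frame(recovery_analysis.results)
        prof = ordinal_profile(levels, cap=20)
        for kind in ("promoter", "exon", "intron"):
            expected = len(
                {
                    (r.gene_id, r.ordinal, r.cpg_island)
                    for r in recovery_analysis.results
                    if r.component_kind == kind
                }
            ) * 3  # three groups have coverage everywhere in this dataset
            got = prof.table[prof.table["component_kind"] == kind]["n"].sum()
            assert got == expected

    def test_recovers_generator_component_ordering(self, recovery_analysis):
        """Promoters were generated least methylated, first exons/introns
        below later ordinals, island regions lower still; the profile must
        recover that ordering in every group."""
        levels = levels_frame(recovery_analysis.results)
        prof = ordinal_profile(levels, cap=20)
        t = prof.table[~prof.table["cpg_island"]]
        for group in ("low", "medium", "high"):
            g = t[t["group"] == group].set_index(["component_kind", "ordinal_label"])
            prom = g.loc[("promoter", "0"), "level"]
            assert prom < g.loc[("exon", "1"), "level"] < g.loc[("exon", "2"), "level"]
            assert g.loc[("intron", "1"), "level"] < g.loc[("intron", "2"), "level"]
        ti = prof.table[prof.table["cpg_island"]].set_index(
            ["group", "component_kind", "ordinal_label"]
        )
        t_all = t.set_index(["group", "component_kind", "ordinal_label"])
        assert (
            ti.loc[("low", "promoter", "0"), "level"]
            < t_all.loc[("low", "promoter", "0"), "level"]
        )


class TestLengthProfile:
    def test_uniform_length_collapses_to_single_bin(self):
        rows = [_levels_row("exon", 1, 0.2, gene=f"g{i}", length=150) for i in range(20)]
        prof = length_profile(pd.DataFrame(rows))
        sub = prof.table[prof.table["ordinal_class"] == "first"]
        assert len(sub) == 1 and int(sub["n"].iloc[0]) == 20

    def test_empty_strata_absent_not_fabricated(self):
        rows = [_levels_row("exon", 1, 0.3, gene=f"g{i}", length=100 + i) for i in range(5)]
        prof = length_profile(pd.DataFrame(rows), n_bins=10)
        assert (prof.table["n"] > 0).all()

    def test_recovers_planted_length_trend(self):
        """With generator methylation increasing in exon length, the binned
        first-exon profile shows a positive Spearman trend."""
        config = SyntheticConfig(
            seed=11,
            n_genes=40,
            island_prob=dict(NO_ISLANDS),
            n_planted_per_effect=0,
            length_methylation_slope=0.10,
        )
        analyzed = _analyze(config)
        levels = levels_frame(analyzed.results)
        prof = length_profile(levels, n_bins=8)
        assert prof.trend[("exon", "first", False)] > 0.5


def _diff_result(gene, kind, ordinal, diff):
    return RegionTestResult(
        gene_id=gene, chrom="chr1", component_kind=kind, ordinal=ordinal,
        cpg_island=False, start=0, end=10, length=10, n_cytosines=1,
        meth_low=0.5, meth_medium=0.5, meth_high=0.5 - diff, meth_diff=diff,
        beta=0.0, intercept=0.0, p_value=0.5, q_value=0.5, direction="ns",
    )


class TestDifferenceCorrelation:
    def _results(self, prom_diffs, exon_diffs):
        out = []
        for i, (dp, de) in enumerate(zip(prom_diffs, exon_diffs)):
            out.append(_diff_result(f"g{i}", "promoter", 0, dp))
            out.append(_diff_result(f"g{i}", "exon", 1, de))
        return out

    def test_identical_vectors_give_unit_pcc(self):
        diffs = [0.1, -0.2, 0.05, 0.3, -0.1]
        table = difference_correlation(self._results(diffs, diffs))
        row = table[(table["component_a"] == "promoter") & (table["component_b"] == "exon1")]
        assert row["pcc"].iloc[0] == pytest.approx(1.0)
        assert int(row["n"].iloc[0]) == 5

    def test_negated_vector_gives_minus_one(self):
        diffs = [0.1, -0.2, 0.05, 0.3, -0.1]
        table = difference_correlation(self._results(diffs, [-d for d in diffs]))
        row = table[(table["component_a"] == "promoter") & (table["component_b"] == "exon1")]
        assert row["pcc"].iloc[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_random_vectors(self):
        rng = np.random.default_rng(42)
        a, b = rng.normal(size=200), rng.normal(size=200)
        table = difference_correlation(self._results(a, b))
        pcc = table[
            (table["component_a"] == "promoter") & (table["component_b"] == "exon1")
        ]["pcc"].iloc[0]
        # direct sum-formula oracle
        ac, bc = a - a.mean(), b - b.mean()
        expected = float(np.sum(ac * bc) / np.sqrt(np.sum(ac**2) * np.sum(bc**2)))
        assert abs(pcc - expected) < 1e-12
        assert abs(pcc) < 0.2

    def test_too_few_shared_genes_flagged_undefined(self):
        table = difference_correlation(self._results([0.1, 0.2], [0.1, 0.2]))
        row = table[(table["component_a"] == "promoter") & (table["component_b"] == "exon1")]
        assert np.isnan(row["pcc"].iloc[0]) and int(row["n"].iloc[0]) == 2
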