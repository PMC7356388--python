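"""Component derivation, ordinal numbering, island intersection, assignment."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methcomp.annotation import (
    ComponentRegion,
    assign_cytosines,
    derive_components,
    intersect_with_islands,
    select_transcripts,
)
from methcomp.io_formats import CytosineRecord, GeneModel


def by_key(regions):
    return {(r.component_kind, r.ordinal): r for r in regions}


class TestDeriveComponents:
    def test_plus_strand_layout(self, plus_gene):
        got = by_key(derive_components(plus_gene, 50, 0))
        assert got[("promoter", 0)].intervals == ((50, 100),)
        assert got[("exon", 1)].intervals == ((100, 200),)
        assert got[("exon", 2)].intervals == ((300, 400),)
        assert got[("intron", 1)].intervals == ((200, 300),)
        assert len(got) == 4

    def test_minus_strand_mirrors_ordinals(self, minus_gene):
        got = by_key(derive_components(minus_gene, 50, 0))
        assert got[("promoter", 0)].intervals == ((400, 450),)
        assert got[("exon", 1)].intervals == ((300, 400),)
        assert got[("exon", 2)].intervals == ((100, 200),)
        assert got[("intron", 1)].intervals == ((200, 300),)

    def test_single_exon_gene_has_no_introns(self):
        g = GeneModel("g", "chr1", "+", 1000, 1400, (1000,), (1400,))
        regions = derive_components(g, 100, 0)
        kinds = sorted(r.component_kind for r in regions)
        assert kinds == ["exon", "promoter"]

    def test_promoter_clipped_at_contig_start(self):
        g = GeneModel("g", "chr1", "+", 30, 200, (30,), (200,))
        got = by_key(derive_components(g, 100, 0))
        assert got[("promoter", 0)].intervals == ((0, 30),)

    def test_promoter_downstream_window(self, plus_gene):
        got = by_key(derive_components(plus_gene, 200, 50))
        assert got[("promoter", 0)].intervals == ((0, 150),)

    def test_zero_length_intron_gap_skipped(self):
        g = GeneModel("g", "chr1", "+", 0, 300, (0, 150), (150, 300))
        regions = derive_components(g, 10, 0)
        assert not [r for r in regions if r.component_kind == "intron"]


class TestSelectTranscripts:
    def make(self, gene_id, start, end):
        return GeneModel(gene_id, "chr1", "+", start, end, (start,), (end,))

    def test_longest_span_kept(self):
        kept = select_transcripts([self.make("g", 0, 800), self.make("g", 0, 1000)])
        assert [g.span for g in kept] == [1000]

    def test_unique_gene_passes_through(self):
        g = self.make("solo", 10, 20)
        assert select_transcripts([g]) == [g]

    def test_tie_broken_by_smaller_start(self):
        kept = select_transcripts([self.make("g", 500, 600), self.make("g", 100, 200)])
        assert kept[0].tx_start == 100

    def test_first_policy(self):
        kept = select_transcripts(
            [self.make("g", 0, 10), self.make("g", 0, 100)], policy="first"
        )
        assert kept[0].span == 10


class TestIslandIntersection:
    def prom(self):
        return ComponentRegion("g", "promoter", 0, False, "chr1", ((50, 100),))

    def test_simple_overlap(self):
        out = intersect_with_islands([self.prom()], [("chr1", 80, 120)])
        island = [r for r in out if r.cpg_island]
        assert len(island) == 1 and island[0].intervals == ((80, 100),)
        assert self.prom() in out  # original retained

    def test_two_fragments_one_region(self):
        exon = ComponentRegion("g", "exon", 1, False, "chr1", ((100, 200),))
        out = intersect_with_islands(
            [exon], [("chr1", 110, 130), ("chr1", 150, 160)]
        )
        (island,) = [r for r in out if r.cpg_island]
        assert island.intervals == ((110, 130), (150, 160))
        assert island.key == ("g", "exon", 1, True)

    def test_no_overlap_emits_nothing(self):
        out = intersect_with_islands([self.prom()], [("chr1", 200, 300)])
        assert not [r for r in out if r.cpg_island]

    def test_idempotent_and_fragments_subset_of_parent(self):
        exon = ComponentRegion("g", "exon", 2, False, "chr2", ((0, 1000),))
        islands = [("chr2", 100, 200), ("chr2", 500, 2000)]
        once = intersect_with_islands([exon], islands)
        twice = intersect_with_islands(once, islands)
        assert sorted(r.key for r in twice) == sorted(r.key for r in once)
        (island,) = [r for r in once if r.cpg_island]
        for s, e in island.intervals:
            assert any(ps <= s and e <= pe for ps, pe in exon.intervals)


@st.composite
def gene_models(draw):
    k = draw(st.integers(1, 8))
    # keep coordinates >= 100 so a 100-bp promoter window never clips at 0
    bounds = draw(
        st.lists(st.integers(100, 100_000), min_size=2 * k, max_size=2 * k, unique=True)
    )
    bounds = sorted(bounds)
    starts = tuple(bounds[0::2])
    ends = tuple(bounds[1::2])
    strand = draw(st.sampled_from("+-"))
    return GeneModel("g", "chr1", strand, bounds[0], bounds[-1], starts, ends)


class TestStructuralInvariants:
    @settings(derandomize=True, max_examples=200)
    @given(gene_models())
    def test_exon_intron_tiling_and_ordinals(self, gene):
        regions = derive_components(gene, 100, 0)
        exons = [r for r in regions if r.component_kind == "exon"]
        introns = [r for r in regions if r.component_kind == "intron"]
        assert len(introns) == len(exons) - 1
        assert sorted(r.ordinal for r in exons) == list(range(1, len(exons) + 1))
        assert sorted(r.ordinal for r in introns) == list(range(1, len(introns) + 1))
        # exons and introns tile [tx_start, tx_end) with no gaps or overlaps
        spans = sorted(
            iv for r in exons + introns for iv in r.intervals
        )
        assert spans[0][0] == gene.tx_start and spans[-1][1] == gene.tx_end
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            assert s2 == e1

    @settings(derandomize=True, max_examples=100)
    @given(gene_models())
    def test_ordinals_invariant_under_mirror_and_strand_flip(self, gene):
        m = 200_000
        flipped = GeneModel(
            gene.gene_id,
            gene.chrom,
            "-" if gene.strand == "+" else "+",
            m - gene.tx_end,
            m - gene.tx_start,
            tuple(m - e for e in reversed(gene.exon_ends)),
            tuple(m - s for s in reversed(gene.exon_starts)),
        )
        orig = by_key(derive_components(gene, 100, 0))
        mirr = by_key(derive_components(flipped, 100, 0))
        assert set(orig) == set(mirr)
        for key, region in orig.items():
            expected = tuple(
                sorted((m - e, m - s) for s, e in region.intervals)
            )
            assert mirr[key].intervals == expected


def _rec(sample, pos, chrom="chr1"):
    return CytosineRecord(sample, chrom, pos, 1, 4)


class TestAssignCytosines:
    def regions(self):
        return [
            ComponentRegion("g", "exon", 2, False, "chr1", ((99, 100),)),
            ComponentRegion("g", "exon", 3, False, "chr1", ((100, 200),)),
            ComponentRegion("g", "exon", 3, True, "chr1", ((150, 160),)),
        ]

    def test_boundary_membership(self):
        a = assign_cytosines({"s": [_rec("s", 100)]}, self.regions())
        assert ("g", "exon", 2, False) in a.by_region  # pos-1 = 99 in [99,100)
        assert ("g", "exon", 3, False) not in a.by_region

    def test_dual_membership_island_and_parent(self):
        a = assign_cytosines({"s": [_rec("s", 155)]}, self.regions())
        assert ("g", "exon", 3, False) in a.by_region
        assert ("g", "exon", 3, True) in a.by_region

    def test_unknown_chromosome_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            a = assign_cytosines({"s": [_rec("s", 155, chrom="chrX")]}, self.regions())
        assert not a.by_region and "chrX" in caplog.text

    def test_duplicate_sample_position_counted_once(self):
        a = assign_cytosines({"s": [_rec("s", 155), _rec("s", 155)]}, self.regions())
        assert len(a.by_region[("g", "exon", 3, False)]) == 1

    def test_summary_counts_non_empty_components(self):
        recs = {"s": [_rec("s", 100), _rec("s", 155)]}
        a = assign_cytosines(recs, self.regions())
        assert a.summary() == {"genes": 1, "promoters": 0, "exons": 2, "introns": 0}
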