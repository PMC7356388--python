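"""Gene-component annotation: promoters, ordinal exons/introns, CpG-island
intersections, and cytosine-to-region assignment.

Components are numbered in transcription order: on the minus strand the
genomic-rightmost exon is exon 1, and intron *i* always lies between
transcription-order exons *i* and *i+1*.  The promoter is a strand-aware
window around the TSS (default 2000 bp upstream / 0 bp downstream — this is
a convention, not something derivable from the data, and results depend on
it, so it is an explicit parameter everywhere).

A component that overlaps a CpG island additionally yields an
"island-intersection" region with the same identity but ``cpg_island=True``
and intervals restricted to the geometric intersection; the full component
is retained alongside, so plain and island variants of the same component
deliberately share cytosines.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .io_formats import CytosineRecord, GeneModel, position_in_interval

log = logging.getLogger(__name__)

PROMOTER = "promoter"
EXON = "exon"
INTRON = "intron"

#: (component_kind, cpg_island) -> conventional family label
FAMILY_LABELS = {
    (PROMOTER, False): "DMP",
    (EXON, False): "DME",
    (INTRON, False): "DMI",
    (PROMOTER, True): "DMP-CpGi",
    (EXON, True): "DME-CpGi",
    (INTRON, True): "DMI-CpGi",
}

#: identity of a region: (gene_id, component_kind, ordinal, cpg_island)
RegionKey = tuple[str, str, int, bool]


@dataclass(frozen=True)
class ComponentRegion:
    """A promoter, ordinal exon, ordinal intron, or its CpG-island intersection.

    ``intervals`` are disjoint, sorted, 0-based half-open spans; island
    intersections may fragment a component into several spans.  The promoter
    carries ordinal 0, exons/introns ordinals >= 1 in transcription order.
    """

    gene_id: str
    component_kind: str
    ordinal: int
    cpg_island: bool
    chrom: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.component_kind not in (PROMOTER, EXON, INTRON):
            raise ValueError(f"unknown component kind {self.component_kind!r}")
        if (self.ordinal == 0) != (self.component_kind == PROMOTER):
            raise ValueError("ordinal 0 iff promoter")
        if not self.intervals:
            raise ValueError("region must have at least one interval")
        prev_end = None
        for s, e in self.intervals:
            if e <= s:
                raise ValueError(f"empty interval [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("intervals must be disjoint and sorted")
            prev_end = e

    @property
    def key(self) -> RegionKey:
        return (self.gene_id, self.component_kind, self.ordinal, self.cpg_island)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, pos: int) -> bool:
        """Membership of a 1-based cytosine position."""
        return any(position_in_interval(pos, s, e) for s, e in self.intervals)


def select_transcripts(
    genes: Sequence[GeneModel], policy: str = "longest"
) -> list[GeneModel]:
    """Collapse multiple transcript rows per gene id to one gene model.

    ``longest`` keeps the transcript with the widest genomic span, ties broken
    by smaller tx_start; ``first`` keeps the first row encountered.
    """
    if policy not in ("longest", "first"):
        raise ValueError(f"unknown transcript policy {policy!r}")
    chosen: dict[str, GeneModel] = {}
    for g in genes:
        cur = chosen.get(g.gene_id)
        if cur is None:
            chosen[g.gene_id] = g
        elif policy == "longest" and (-g.span, g.tx_start) < (-cur.span, cur.tx_start):
            chosen[g.gene_id] = g
    return list(chosen.values())


def derive_components(
    gene: GeneModel,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 0,
) -> list[ComponentRegion]:
    """Derive the promoter and strand-aware ordinal exons/introns of one gene.

    The promoter window is ``[TSS - upstream, TSS + downstream)`` on the plus
    strand and its mirror image on the minus strand, clipped (never extended)
    at position 0.  Single-exon genes yield no introns; zero-length intron
    gaps between abutting exons are skipped.
    """
    if promoter_upstream < 0 or promoter_downstream < 0:
        raise ValueError("promoter window parameters must be >= 0")
    if promoter_upstream == 0 and promoter_downstream == 0:
        raise ValueError("promoter window cannot be empty on both sides")
    regions: list[ComponentRegion] = []
    k = gene.n_exons
    if gene.strand == "+":
        tss = gene.tx_start
        prom = (max(0, tss - promoter_upstream), tss + promoter_downstream)
    else:
        tss = gene.tx_end
        prom = (max(0, tss - promoter_downstream), tss + promoter_upstream)
    if prom[1] > prom[0]:
        regions.append(
            ComponentRegion(gene.gene_id, PROMOTER, 0, False, gene.chrom, (prom,))
        )
    else:
        log.info("gene %s: promoter window empty after clipping, skipped", gene.gene_id)

    for g_idx, (s, e) in enumerate(zip(gene.exon_starts, gene.exon_ends)):
        ordinal = g_idx + 1 if gene.strand == "+" else k - g_idx
        regions.append(
            ComponentRegion(gene.gene_id, EXON, ordinal, False, gene.chrom, ((s, e),))
        )
    for g_idx in range(k - 1):
        s, e = gene.exon_ends[g_idx], gene.exon_starts[g_idx + 1]
        if e <= s:
            log.info("gene %s: zero-length intron gap skipped", gene.gene_id)
            continue
        ordinal = g_idx + 1 if gene.strand == "+" else k - g_idx - 1
        regions.append(
            ComponentRegion(gene.gene_id, INTRON, ordinal, False, gene.chrom, ((s, e),))
        )
    return regions


def _island_index(
    islands: Iterable[tuple[str, int, int]],
) -> dict[str, tuple[list[int], list[int]]]:
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, start, end in islands:
        starts, ends = by_chrom.setdefault(chrom, ([], []))
        starts.append(start)
        ends.append(end)
    return by_chrom


def intersect_with_islands(
    components: Sequence[ComponentRegion],
    islands: Sequence[tuple[str, int, int]],
) -> list[ComponentRegion]:
    """Add CpG-island-intersection variants to a component list.

    ``islands`` must be merged and sorted (as produced by
    ``read_bed_intervals``).  Returns the original components followed by one
    island region per component with non-empty overlap, holding the geometric
    intersection (possibly several fragments) and ``cpg_island=True``.
    """
    index = _island_index(islands)
    out = list(components)
    existing = {c.key for c in components if c.cpg_island}
    for comp in components:
        if comp.cpg_island or (comp.gene_id, comp.component_kind, comp.ordinal, True) in existing:
            continue
        chrom_idx = index.get(comp.chrom)
        if chrom_idx is None:
            continue
        starts, ends = chrom_idx
        fragments: list[tuple[int, int]] = []
        for s, e in comp.intervals:
            # islands whose end > s and start < e can overlap [s, e)
            i = bisect_right(ends, s)
            while i < len(starts) and starts[i] < e:
                fragments.append((max(s, starts[i]), min(e, ends[i])))
                i += 1
        if fragments:
            out.append(
                ComponentRegion(
                    comp.gene_id,
                    comp.component_kind,
                    comp.ordinal,
                    True,
                    comp.chrom,
                    tuple(fragments),
                )
            )
    return out


@dataclass
class RegionAssignment:
    """Cytosine records grouped by the region they fall in.

    ``by_region`` maps each non-empty region key to its (sample_id, record)
    pairs; a cytosine legitimately appears under several regions (e.g. under
    both an exon and that exon's island fragment), but a (sample, position)
    pair appears at most once within one region.
    """

    regions: list[ComponentRegion]
    by_region: dict[RegionKey, list[tuple[str, CytosineRecord]]] = field(
        default_factory=dict
    )

    @property
    def region_map(self) -> dict[RegionKey, ComponentRegion]:
        return {r.key: r for r in self.regions}

    def non_empty_regions(self) -> list[ComponentRegion]:
        keys = set(self.by_region)
        return [r for r in self.regions if r.key in keys]

    def summary(self) -> dict[str, int]:
        """Counts of genes and components with at least one assigned cytosine."""
        genes: set[str] = set()
        per_kind: dict[str, set] = {PROMOTER: set(), EXON: set(), INTRON: set()}
        for gene_id, kind, ordinal, island in self.by_region:
            if not island:
                genes.add(gene_id)
                per_kind[kind].add((gene_id, ordinal))
        return {
            "genes": len(genes),
            "promoters": len(per_kind[PROMOTER]),
            "exons": len(per_kind[EXON]),
            "introns": len(per_kind[INTRON]),
        }


def assign_cytosines(
    records_by_sample: Mapping[str, Sequence[CytosineRecord]],
    regions: Sequence[ComponentRegion],
) -> RegionAssignment:
    """Assign (already coverage-filtered) cytosines to component regions.

    Membership uses the 1-based-point-in-half-open-interval predicate; regions
    with zero assigned cytosines across all samples are simply absent from
    ``by_region`` and thereby excluded from testing.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, region in enumerate(regions):
        for s, e in region.intervals:
            trees[region.chrom].addi(s, e, idx)

    assignment = RegionAssignment(regions=list(regions))
    by_region = assignment.by_region
    lookup_cache: dict[tuple[str, int], tuple[int, ...]] = {}
    missing_chroms: set[str] = set()
    seen: set[tuple[RegionKey, str, int]] = set()

    for sample_id in records_by_sample:
        for rec in records_by_sample[sample_id]:
            cache_key = (rec.chrom, rec.pos)
            hit = lookup_cache.get(cache_key)
            if hit is None:
                tree = trees.get(rec.chrom)
                if tree is None:
                    if rec.chrom not in missing_chroms:
                        missing_chroms.add(rec.chrom)
                        log.warning(
                            "chromosome %s present in records but absent from "
                            "annotation; records skipped",
                            rec.chrom,
                        )
                    hit = ()
                else:
                    hit = tuple(iv.data for iv in tree.at(rec.pos - 1))
                lookup_cache[cache_key] = hit
            for idx in hit:
                key = regions[idx].key
                dedupe = (key, sample_id, rec.pos)
                if dedupe in seen:
                    continue
                seen.add(dedupe)
                by_region.setdefault(key, []).append((sample_id, rec))

    log.info("cytosine assignment summary: %s", assignment.summary())
    return assignment
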