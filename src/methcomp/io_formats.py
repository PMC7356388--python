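"""Readers and writers for the external file formats the pipeline touches.

Coordinate conventions
----------------------
Cytosine positions are 1-based (bismark ``.cov`` dialect, where start == end
for a single cytosine).  All interval types (gene models, BED islands,
derived component regions) are 0-based half-open.  A 1-based cytosine at
``pos`` lies inside a half-open interval ``[start, end)`` iff
``start < pos <= end``, i.e. ``(pos - 1) in [start, end)`` — that predicate
lives in :func:`position_in_interval` and is the single place where the two
conventions meet.

Cytosine strand is not modelled: the coverage files are assumed to be
CpG-destranded upstream (plus/minus counts already merged per CpG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError, ParseError

log = logging.getLogger(__name__)

#: The three phenotype group labels used throughout the analysis.
GROUPS = ("low", "medium", "high")

RESULT_COLUMNS = [
    "gene_id",
    "chrom",
    "component_kind",
    "ordinal",
    "cpg_island",
    "start",
    "end",
    "n_cytosines",
    "meth_low",
    "meth_high",
    "meth_diff",
    "p_value",
    "q_value",
    "direction",
]


def position_in_interval(pos: int, start: int, end: int) -> bool:
    """True iff 1-based ``pos`` falls inside 0-based half-open ``[start, end)``."""
    return start < pos <= end


@dataclass(frozen=True, slots=True)
class CytosineRecord:
    """One cytosine's methylated / total read counts in one sample.

    ``pos`` is the 1-based genomic position of the cytosine.
    """

    sample_id: str
    chrom: str
    pos: int
    meth_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads < 1:
            raise ValueError(
                f"total_reads must be >= 1, got {self.total_reads} at "
                f"{self.chrom}:{self.pos}"
            )
        if not 0 <= self.meth_reads <= self.total_reads:
            raise ValueError(
                f"meth_reads must lie in [0, total_reads], got "
                f"{self.meth_reads}/{self.total_reads} at {self.chrom}:{self.pos}"
            )

    @property
    def fraction(self) -> float:
        return self.meth_reads / self.total_reads


@dataclass(frozen=True)
class GeneModel:
    """One gene's transcript structure in 0-based half-open coordinates.

    Exon coordinate lists are stored in ascending *genomic* order regardless
    of strand; strand-aware ordinal numbering happens in the annotation
    module.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ValueError(f"{self.gene_id}: exon lists empty or unequal length")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(
                    f"{self.gene_id}: exon [{s},{e}) outside transcript span "
                    f"[{self.tx_start},{self.tx_end}) or empty"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_start


@dataclass(frozen=True)
class SampleSheet:
    """Mapping from sample id to its phenotype group (low / medium / high)."""

    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.groups.values() if g not in GROUPS}
        if bad:
            raise DataError(
                f"sample sheet contains unknown group labels {sorted(bad)}; "
                f"allowed: {GROUPS}"
            )

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a two-column TSV (sample_id, group); '#' comment lines skipped."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        sample, group = fields
        if sample in mapping:
            raise ParseError(f"{path}:{lineno}: duplicate sample id {sample!r}")
        mapping[sample] = group
    return SampleSheet(mapping)


def read_coverage_file(
    path: str | Path, sample_id: str, *, strip_chr_prefix: bool = False
) -> list[CytosineRecord]:
    """Read a bismark-style coverage file into cytosine records.

    Expected columns (tab-separated): chrom, start, end, percent methylation,
    count methylated, count unmethylated.  Start is 1-based and equals end for
    single cytosines; the percent column is ignored and recomputed downstream
    from the counts.
    """
    records: list[CytosineRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 6:
            raise ParseError(
                f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}"
            )
        chrom, start_s, _end_s, _pct, meth_s, unmeth_s = fields
        try:
            pos = int(start_s)
            meth = int(meth_s)
            unmeth = int(unmeth_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from exc
        if meth < 0 or unmeth < 0:
            raise ParseError(f"{path}:{lineno}: negative read count")
        if meth + unmeth == 0:
            raise ParseError(f"{path}:{lineno}: zero total reads")
        if strip_chr_prefix and chrom.startswith("chr"):
            chrom = chrom[3:]
        records.append(
            CytosineRecord(
                sample_id=sample_id,
                chrom=chrom,
                pos=pos,
                meth_reads=meth,
                total_reads=meth + unmeth,
            )
        )
    if not records:
        log.warning("coverage file %s is empty (sample %s)", path, sample_id)
    return records


def _parse_comma_list(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in text.strip().rstrip(",").split(",") if x != "")


def read_refgene_table(
    path: str | Path, *, strip_chr_prefix: bool = False
) -> list[GeneModel]:
    """Read a UCSC refGene/genePred flat table into gene models.

    Accepts the 10+ column genePred dialect (name, chrom, strand, txStart,
    txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds), with or
    without the leading ``bin`` column; exon lists are comma-separated with a
    tolerated trailing comma.  Duplicate gene ids are passed through — the
    annotation module owns transcript deduplication.
    """
    genes: list[GeneModel] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        # a leading integer "bin" column shifts everything right by one
        offset = 0
        if len(fields) >= 11 and fields[2] not in ("+", "-") and fields[3] in ("+", "-"):
            offset = 1
        if len(fields) < 10 + offset:
            raise ParseError(f"{path}:{lineno}: expected >=10 genePred fields")
        f = fields[offset:]
        name, chrom, strand = f[0], f[1], f[2]
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
        try:
            tx_start, tx_end = int(f[3]), int(f[4])
            exon_count = int(f[7])
            exon_starts = _parse_comma_list(f[8])
            exon_ends = _parse_comma_list(f[9])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed field ({exc})") from exc
        if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
            raise ParseError(
                f"{path}:{lineno}: exonCount={exon_count} inconsistent with "
                f"exon list lengths {len(exon_starts)}/{len(exon_ends)}"
            )
        if strip_chr_prefix and chrom.startswith("chr"):
            chrom = chrom[3:]
        try:
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exon_starts=exon_starts,
                    exon_ends=exon_ends,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Sort intervals by (chrom, start) and merge overlapping/adjacent-overlap ones.

    Touching intervals ([0,10) and [10,20)) are kept separate; only genuine
    overlaps merge.
    """
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def read_bed_intervals(
    path: str | Path, *, strip_chr_prefix: bool = False
) -> list[tuple[str, int, int]]:
    """Read BED3+ intervals (0-based half-open), returning them merged and sorted."""
    raw: list[tuple[str, int, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 BED fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if end <= start:
            raise ParseError(f"{path}:{lineno}: end {end} <= start {start}")
        if strip_chr_prefix and chrom.startswith("chr"):
            chrom = chrom[3:]
        raw.append((chrom, start, end))
    merged = merge_intervals(raw)
    n_merged = len(raw) - len(merged)
    if n_merged:
        log.info("merged %d overlapping intervals in %s", n_merged, path)
    return merged


def _result_sort_key(r) -> tuple:
    return (r.chrom, r.start, r.component_kind, r.ordinal, r.cpg_island)


def write_results_table(results: Sequence, path: str | Path) -> None:
    """Write region test results as a TSV (header always present).

    Methylation levels and differences are written in percent at 4 decimals;
    p/Q-values at 6 significant digits.  Rows are ordered by
    (chrom, start, component kind, ordinal) so output is deterministic.
    """
    lines = ["\t".join(RESULT_COLUMNS)]
    for r in sorted(results, key=_result_sort_key):
        lines.append(
            "\t".join(
                [
                    r.gene_id,
                    r.chrom,
                    r.component_kind,
                    str(r.ordinal),
                    str(bool(r.cpg_island)),
                    str(r.start),
                    str(r.end),
                    str(r.n_cytosines),
                    f"{100.0 * r.meth_low:.4f}",
                    f"{100.0 * r.meth_high:.4f}",
                    f"{100.0 * r.meth_diff:.4f}",
                    f"{r.p_value:.6g}",
                    f"{r.q_value:.6g}",
                    r.direction,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame (levels in percent, as written)."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
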