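"""Synthetic RRBS dataset generator with a known ground truth.

Emulates the structure of a small bisulfite study: three phenotype groups
(low / medium / high) with three replicates each, gene models laid out on a
few synthetic chromosomes, CpG islands overlapping a configurable fraction
of promoters / first exons / first introns, CpG sites denser inside islands,
negative-binomially overdispersed coverage, and component-dependent baseline
methylation (promoters lowest, first exon/intron lower than later ordinals,
island regions lower still via a multiplicative factor).

Group differences are *planted*: a configurable number of regions per effect
size receives a low-vs-high difference, applied symmetrically (+e/2 to the
low group, -e/2 to the high group, with a random sign per region) so the
medium group sits between the two.  The truth table records the signed
planted effect of every generated base region (0 for nulls), which is what
recovery tests measure against.

Identical config + seed produce byte-identical output files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import annotation
from .annotation import EXON, INTRON, PROMOTER, ComponentRegion, derive_components
from .errors import ConfigError
from .io_formats import CytosineRecord, GeneModel, SampleSheet, merge_intervals

log = logging.getLogger(__name__)

#: baseline-methylation classes used by the generator
CLASSES = ("promoter", "exon_first", "exon_later", "intron_first", "intron_later")


def _component_class(kind: str, ordinal: int) -> str:
    if kind == PROMOTER:
        return "promoter"
    first = ordinal == 1
    if kind == EXON:
        return "exon_first" if first else "exon_later"
    return "intron_first" if first else "intron_later"


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults emulate a small RRBS study.

    Baselines are proportions; the island multiplier (< 1) scales the
    baseline of sites falling inside CpG islands.  Coverage is negative
    binomial with the given mean and dispersion (``size``) parameter, so
    variance = mean + mean^2 / dispersion.  ``bb_rho`` > 0 switches
    methylated-read draws from binomial to beta-binomial with intra-site
    correlation rho (off by default, so the differential test is run under
    its own assumed model).
    """

    seed: int = 0
    n_genes: int = 100
    n_chromosomes: int = 3
    chromosome_length: int | None = None  # None = auto-sized
    exon_count_range: tuple[int, int] = (1, 20)
    exon_length_log_mean: float = math.log(250.0)
    exon_length_log_sd: float = 0.6
    intron_length_log_mean: float = math.log(1200.0)
    intron_length_log_sd: float = 0.7
    min_feature_length: int = 40
    intergenic_gap: int = 3000
    promoter_upstream: int = 2000
    promoter_downstream: int = 0
    island_prob: dict = field(
        default_factory=lambda: {
            "promoter": 0.7,
            "exon_first": 0.5,
            "intron_first": 0.4,
            "exon_later": 0.15,
            "intron_later": 0.15,
        }
    )
    island_cover_range: tuple[float, float] = (0.4, 0.9)
    replicates: int = 3
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    baseline: dict = field(
        default_factory=lambda: {
            "promoter": 0.10,
            "exon_first": 0.22,
            "exon_later": 0.45,
            "intron_first": 0.31,
            "intron_later": 0.45,
        }
    )
    island_multiplier: float = 0.5
    cpg_density: float = 0.02
    island_cpg_density: float = 0.08
    length_methylation_slope: float = 0.0  # added to exon baselines per log-bp
    effect_sizes: tuple[float, ...] = (0.05, 0.10, 0.20)
    n_planted_per_effect: int = 50
    bb_rho: float = 0.0

    def validate(self) -> None:
        if self.n_genes < 1 or self.replicates < 1 or self.n_chromosomes < 1:
            raise ConfigError("n_genes, replicates and n_chromosomes must be >= 1")
        lo, hi = self.exon_count_range
        if not 1 <= lo <= hi:
            raise ConfigError("exon_count_range must satisfy 1 <= lo <= hi")
        for name, p in {
            **{f"island_prob[{k}]": v for k, v in self.island_prob.items()},
            **{f"baseline[{k}]": v for k, v in self.baseline.items()},
            "island_multiplier": self.island_multiplier,
            "bb_rho": self.bb_rho,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        missing = set(CLASSES) - set(self.baseline)
        if missing:
            raise ConfigError(f"baseline missing classes {sorted(missing)}")
        if not 0 < self.cpg_density <= 1 or not 0 < self.island_cpg_density <= 1:
            raise ConfigError("CpG densities must lie in (0, 1]")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ConfigError("coverage mean and dispersion must be positive")
        # every requested effect size must be applicable to at least one
        # baseline class without pushing a proportion outside [0, 1]
        levels = [b * m for b in self.baseline.values() for m in (1.0, self.island_multiplier)]
        for e in self.effect_sizes:
            if not 0 < e <= 1:
                raise ConfigError(f"effect size {e} must lie in (0, 1]")
            if self.n_planted_per_effect > 0 and not any(
                e / 2 <= p <= 1 - e / 2 for p in levels
            ):
                raise ConfigError(
                    f"effect size {e} pushes every baseline class outside [0, 1]"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exon_count_range"] = list(self.exon_count_range)
        d["island_cover_range"] = list(self.island_cover_range)
        d["effect_sizes"] = list(self.effect_sizes)
        return d


#: SyntheticTruth: (gene_id, component_kind, ordinal) -> signed planted effect
TruthTable = dict[tuple[str, str, int], float]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes: list[GeneModel]
    islands: list[tuple[str, int, int]]
    sample_sheet: SampleSheet
    samples: dict[str, list[CytosineRecord]]
    truth: TruthTable


def _feature_length(rng: np.random.Generator, log_mean: float, log_sd: float, floor: int) -> int:
    return max(floor, int(round(rng.lognormal(log_mean, log_sd))))


def generate_annotation(
    config: SyntheticConfig,
) -> tuple[list[GeneModel], list[tuple[str, int, int]]]:
    """Generate non-overlapping gene models and CpG islands.

    Genes are packed left-to-right across the configured chromosomes with an
    intergenic gap wide enough for the promoter window; a fixed
    ``chromosome_length`` that cannot hold its share of genes raises
    :class:`ConfigError`.  Islands are placed per component class with the
    configured probabilities, each covering a random sub-span of its
    component, then merged.
    """
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), 11])
    cursors = {f"chr{i + 1}": 0 for i in range(config.n_chromosomes)}
    chrom_names = list(cursors)
    genes: list[GeneModel] = []
    islands: list[tuple[str, int, int]] = []
    lo, hi = config.exon_count_range
    for g_idx in range(config.n_genes):
        chrom = chrom_names[g_idx % len(chrom_names)]
        k = int(rng.integers(lo, hi + 1))
        exon_lens = [
            _feature_length(
                rng, config.exon_length_log_mean, config.exon_length_log_sd,
                config.min_feature_length,
            )
            for _ in range(k)
        ]
        intron_lens = [
            _feature_length(
                rng, config.intron_length_log_mean, config.intron_length_log_sd,
                config.min_feature_length,
            )
            for _ in range(k - 1)
        ]
        tx_start = cursors[chrom] + config.promoter_upstream + config.intergenic_gap
        starts, ends = [], []
        pos = tx_start
        for i, el in enumerate(exon_lens):
            starts.append(pos)
            ends.append(pos + el)
            pos += el
            if i < k - 1:
                pos += intron_lens[i]
        tx_end = pos
        cursors[chrom] = tx_end + config.promoter_upstream
        if config.chromosome_length is not None and cursors[chrom] > config.chromosome_length:
            raise ConfigError(
                f"infeasible packing: {config.n_genes} genes do not fit in "
                f"{config.n_chromosomes} chromosomes of length {config.chromosome_length}"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel(
            gene_id=f"G{g_idx + 1:04d}",
            chrom=chrom,
            strand=strand,
            tx_start=tx_start,
            tx_end=tx_end,
            exon_starts=tuple(starts),
            exon_ends=tuple(ends),
        )
        genes.append(gene)
        for comp in derive_components(
            gene, config.promoter_upstream, config.promoter_downstream
        ):
            cls = _component_class(comp.component_kind, comp.ordinal)
            if rng.random() >= config.island_prob.get(cls, 0.0):
                continue
            s, e = comp.intervals[0]
            frac = rng.uniform(*config.island_cover_range)
            width = max(10, int(frac * (e - s)))
            if width >= e - s:
                islands.append((comp.chrom, s, e))
            else:
                off = int(rng.integers(0, e - s - width))
                islands.append((comp.chrom, s + off, s + off + width))
    return genes, merge_intervals(islands)


def _site_positions(
    rng: np.random.Generator,
    span: tuple[int, int],
    islands_idx: dict[str, tuple[list[int], list[int]]],
    chrom: str,
    config: SyntheticConfig,
) -> tuple[list[int], list[bool]]:
    """1-based CpG site positions in [start, end), flagged by island membership."""
    from bisect import bisect_right

    start, end = span
    pieces: list[tuple[int, int, bool]] = []
    starts, ends = islands_idx.get(chrom, ([], []))
    cur = start
    i = bisect_right(ends, start)
    while cur < end and i < len(starts) and starts[i] < end:
        if starts[i] > cur:
            pieces.append((cur, min(starts[i], end), False))
        seg_end = min(ends[i], end)
        if seg_end > max(cur, starts[i]):
            pieces.append((max(cur, starts[i]), seg_end, True))
        cur = seg_end
        i += 1
    if cur < end:
        pieces.append((cur, end, False))
    positions: list[int] = []
    in_island: list[bool] = []
    for s, e, isl in pieces:
        density = config.island_cpg_density if isl else config.cpg_density
        n = int(rng.binomial(e - s, density))
        if n == 0:
            continue
        offs = np.sort(rng.choice(e - s, size=n, replace=False))
        for off in offs:
            positions.append(s + int(off) + 1)  # 1-based
            in_island.append(isl)
    return positions, in_island


def generate_counts(
    config: SyntheticConfig,
    genes: Sequence[GeneModel],
    islands: Sequence[tuple[str, int, int]],
) -> tuple[dict[str, list[CytosineRecord]], TruthTable]:
    """Generate per-sample cytosine counts and the planted-effect truth table."""
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), 23])
    islands_idx = annotation._island_index(list(islands))

    # lay out sites per base region and their baseline proportions
    site_chrom: list[str] = []
    site_pos: list[int] = []
    site_p0: list[float] = []
    site_region: list[int] = []  # index into region_keys
    region_keys: list[tuple[str, str, int]] = []
    region_site_p: list[list[float]] = []
    for gene in genes:
        for comp in derive_components(
            gene, config.promoter_upstream, config.promoter_downstream
        ):
            cls = _component_class(comp.component_kind, comp.ordinal)
            base = config.baseline[cls]
            if comp.component_kind == EXON and config.length_methylation_slope != 0.0:
                base = base + config.length_methylation_slope * (
                    math.log(comp.length) - config.exon_length_log_mean
                )
                base = min(0.999, max(0.001, base))
            positions, island_flags = _site_positions(
                rng, comp.intervals[0], islands_idx, comp.chrom, config
            )
            ridx = len(region_keys)
            region_keys.append((comp.gene_id, comp.component_kind, comp.ordinal))
            region_site_p.append([])
            for pos, isl in zip(positions, island_flags):
                p0 = base * (config.island_multiplier if isl else 1.0)
                site_chrom.append(comp.chrom)
                site_pos.append(pos)
                site_p0.append(p0)
                site_region.append(ridx)
                region_site_p[ridx].append(p0)

    # plant effects on eligible regions (at most one effect per region)
    truth: TruthTable = {key: 0.0 for key in region_keys}
    if config.n_planted_per_effect > 0:
        available = set(range(len(region_keys)))
        for e in sorted(config.effect_sizes):
            eligible = [
                ridx
                for ridx in sorted(available)
                if region_site_p[ridx]
                and all(e / 2 <= p <= 1 - e / 2 for p in region_site_p[ridx])
            ]
            if len(eligible) < config.n_planted_per_effect:
                raise ConfigError(
                    f"only {len(eligible)} regions eligible for effect size {e}; "
                    f"{config.n_planted_per_effect} requested"
                )
            chosen = rng.choice(eligible, size=config.n_planted_per_effect, replace=False)
            signs = rng.choice([-1.0, 1.0], size=config.n_planted_per_effect)
            for ridx, sign in zip(chosen, signs):
                truth[region_keys[int(ridx)]] = float(sign) * e
                available.discard(int(ridx))

    p0 = np.array(site_p0)
    delta = np.array([truth[region_keys[r]] for r in site_region])
    n_sites = len(p0)
    group_shift = {"low": 0.5, "medium": 0.0, "high": -0.5}
    disp = config.coverage_dispersion
    nb_p = disp / (disp + config.coverage_mean)

    samples: dict[str, list[CytosineRecord]] = {}
    for group in ("low", "medium", "high"):
        p_group = np.clip(p0 + group_shift[group] * delta, 0.0, 1.0)
        for rep in range(1, config.replicates + 1):
            sample_id = f"{group}_{rep}"
            coverage = rng.negative_binomial(disp, nb_p, size=n_sites)
            if config.bb_rho > 0:
                s = (1.0 - config.bb_rho) / config.bb_rho
                p_draw = np.where(
                    (p_group <= 0) | (p_group >= 1),
                    p_group,
                    rng.beta(
                        np.maximum(p_group * s, 1e-9),
                        np.maximum((1.0 - p_group) * s, 1e-9),
                    ),
                )
            else:
                p_draw = p_group
            meth = rng.binomial(coverage, p_draw)
            recs = [
                CytosineRecord(
                    sample_id=sample_id,
                    chrom=site_chrom[i],
                    pos=site_pos[i],
                    meth_reads=int(meth[i]),
                    total_reads=int(coverage[i]),
                )
                for i in range(n_sites)
                if coverage[i] > 0
            ]
            samples[sample_id] = recs
    return samples, truth


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run both generator stages and bundle the in-memory result."""
    genes, islands = generate_annotation(config)
    samples, truth = generate_counts(config, genes, islands)
    sheet = SampleSheet({s: s.rsplit("_", 1)[0] for s in samples})
    return SyntheticDataset(
        config=config,
        genes=genes,
        islands=islands,
        sample_sheet=sheet,
        samples=samples,
        truth=truth,
    )


def write_refgene(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = []
    for g in genes:
        lines.append(
            "\t".join(
                [
                    g.gene_id,
                    g.chrom,
                    g.strand,
                    str(g.tx_start),
                    str(g.tx_end),
                    str(g.tx_start),
                    str(g.tx_end),
                    str(g.n_exons),
                    ",".join(str(s) for s in g.exon_starts) + ",",
                    ",".join(str(e) for e in g.exon_ends) + ",",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_bed(intervals: Sequence[tuple[str, int, int]], path: str | Path) -> None:
    lines = [f"{c}\t{s}\t{e}" for c, s, e in intervals]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_coverage(records: Sequence[CytosineRecord], path: str | Path) -> None:
    lines = []
    for r in records:
        pct = 100.0 * r.meth_reads / r.total_reads
        lines.append(
            f"{r.chrom}\t{r.pos}\t{r.pos}\t{pct:.6g}\t{r.meth_reads}"
            f"\t{r.total_reads - r.meth_reads}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_truth(truth: TruthTable, path: str | Path) -> None:
    lines = ["gene_id\tcomponent_kind\tordinal\teffect\tdirection"]
    for (gene_id, kind, ordinal), effect in sorted(truth.items()):
        direction = "hyper" if effect > 0 else ("hypo" if effect < 0 else "none")
        lines.append(f"{gene_id}\t{kind}\t{ordinal}\t{effect:.6g}\t{direction}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> TruthTable:
    truth: TruthTable = {}
    for line in Path(path).read_text().splitlines()[1:]:
        gene_id, kind, ordinal, effect, _direction = line.split("\t")
        truth[(gene_id, kind, int(ordinal))] = float(effect)
    return truth


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the pipeline's input formats; returns file paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {
        "refgene": out / "refgene.tsv",
        "islands": out / "islands.bed",
        "samples": out / "samples.tsv",
        "truth": out / "truth.tsv",
        "config": out / "config.yaml",
    }
    write_refgene(dataset.genes, paths["refgene"])
    write_bed(dataset.islands, paths["islands"])
    sheet_lines = [f"{s}\t{g}" for s, g in sorted(dataset.sample_sheet.groups.items())]
    paths["samples"].write_text("\n".join(sheet_lines) + "\n")
    write_truth(dataset.truth, paths["truth"])
    paths["config"].write_text(yaml.safe_dump(dataset.config.to_dict(), sort_keys=True))
    for sample_id in sorted(dataset.samples):
        p = out / f"{sample_id}.cov"
        write_coverage(dataset.samples[sample_id], p)
        paths[f"coverage:{sample_id}"] = p
    return paths
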