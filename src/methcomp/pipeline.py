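"""End-to-end pipeline: read inputs, filter, annotate, test, classify, profile.

One :func:`run_pipeline` call executes the whole analysis reproducibly and
writes a results bundle:

* ``results.tsv`` — every tested region with levels, difference, p, Q and
  direction;
* ``levels.tsv`` — tidy per-region x per-group weighted levels (input for
  re-profiling);
* six DMR tables (``dmp.tsv`` ... ``dmi_cpgi.tsv``) holding only the
  significant regions of each family;
* ``profile_ordinal.tsv`` / ``profile_length.tsv`` / ``difference_correlation.tsv``;
* ``overlap_summary.json`` — per-gene DMP/DME/DMI overlap counts and
  first-vs-other ordinal proportions among significant regions;
* ``filter_report.json`` and ``manifest.json`` (config snapshot, content
  hashes of the inputs, per-stage row counts).

Identical config + inputs give a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .annotation import (
    FAMILY_LABELS,
    assign_cytosines,
    derive_components,
    intersect_with_islands,
    select_transcripts,
)
from .errors import ConfigError
from .filtering import filter_coverage
from .io_formats import (
    read_bed_intervals,
    read_coverage_file,
    read_refgene_table,
    read_sample_sheet,
    write_results_table,
)
from .profiles import (
    difference_correlation,
    length_profile,
    levels_frame,
    ordinal_profile,
)
from .region_stats import (
    DMRClassification,
    HYPER,
    HYPO,
    RegionTestResult,
    analyze_regions,
    classify_regions,
)

log = logging.getLogger(__name__)

FAMILY_FILES = {
    "DMP": "dmp.tsv",
    "DME": "dme.tsv",
    "DMI": "dmi.tsv",
    "DMP-CpGi": "dmp_cpgi.tsv",
    "DME-CpGi": "dme_cpgi.tsv",
    "DMI-CpGi": "dmi_cpgi.tsv",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (typically loaded from YAML)."""

    refgene: str
    islands: str
    sample_sheet: str
    outdir: str
    coverage_dir: str | None = None
    coverage_files: dict[str, str] | None = None  # sample_id -> path
    promoter_upstream: int = 2000
    promoter_downstream: int = 0
    transcript_policy: str = "longest"
    chr_prefix_strip: bool = False
    min_coverage_exclusive: int = 10
    max_coverage_percentile: float = 99.9
    alpha: float = 0.05
    fdr_family: str = "per_family"
    test: str = "wald"
    groups_tested: tuple[str, str] = ("low", "high")
    ordinal_cap: int = 20
    length_bins: int = 10
    seed: int = 0
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.groups_tested = tuple(cfg.groups_tested)  # yaml gives a list
        return cfg

    def resolve_coverage(self) -> dict[str, Path]:
        sheet = read_sample_sheet(self.sample_sheet)
        if self.coverage_files:
            files = {s: Path(p) for s, p in self.coverage_files.items()}
        elif self.coverage_dir:
            files = {s: Path(self.coverage_dir) / f"{s}.cov" for s in sheet}
        else:
            raise ConfigError("either coverage_files or coverage_dir is required")
        missing = [str(p) for p in files.values() if not p.exists()]
        if missing:
            raise ConfigError(f"coverage files not found: {missing}")
        return files

    def validate(self) -> None:
        for name in ("refgene", "islands", "sample_sheet"):
            if not Path(getattr(self, name)).exists():
                raise ConfigError(f"{name} file not found: {getattr(self, name)}")
        if len(self.groups_tested) != 2:
            raise ConfigError("groups_tested must list exactly two groups")
        self.resolve_coverage()


@dataclass
class RunResult:
    config: RunConfig
    results: list[RegionTestResult]
    classification: DMRClassification
    manifest: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def summarize_overlaps(results: list[RegionTestResult]) -> dict:
    """Per-gene overlap of DMP/DME/DMI calls and first-vs-other proportions.

    Returns intersection cell counts of the three plain families and of the
    three island families (genes carrying at least one significant region of
    each family in the cell), plus the percentage of significant exons and
    introns sitting at ordinal position 1.
    """
    sig = [r for r in results if r.direction in (HYPER, HYPO)]
    gene_sets: dict[str, set[str]] = {fam: set() for fam in FAMILY_LABELS.values()}
    for r in sig:
        gene_sets[r.family].add(r.gene_id)

    def cells(fams: tuple[str, str, str]) -> dict[str, int]:
        a, b, c = (gene_sets[f] for f in fams)
        return {
            "only_" + fams[0]: len(a - b - c),
            "only_" + fams[1]: len(b - a - c),
            "only_" + fams[2]: len(c - a - b),
            fams[0] + "&" + fams[1]: len((a & b) - c),
            fams[0] + "&" + fams[2]: len((a & c) - b),
            fams[1] + "&" + fams[2]: len((b & c) - a),
            "all_three": len(a & b & c),
        }

    first_vs_other: dict[str, dict] = {}
    for fam in ("DME", "DMI", "DME-CpGi", "DMI-CpGi"):
        regions = [r for r in sig if r.family == fam]
        n = len(regions)
        n_first = sum(1 for r in regions if r.ordinal == 1)
        first_vs_other[fam] = {
            "n": n,
            "n_first": n_first,
            "pct_first": (100.0 * n_first / n) if n else 0.0,
        }
    return {
        "venn": cells(("DMP", "DME", "DMI")),
        "venn_cpgi": cells(("DMP-CpGi", "DME-CpGi", "DMI-CpGi")),
        "first_vs_other": first_vs_other,
        "genes_per_family": {f: len(s) for f, s in gene_sets.items()},
    }


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute filter -> annotate -> test -> classify -> profile and write outputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
    }
    manifest["config"]["groups_tested"] = list(config.groups_tested)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()

    # --- read + filter coverage ------------------------------------------
    log.info("stage: coverage input + filtering")
    coverage_paths = config.resolve_coverage()
    sheet = read_sample_sheet(config.sample_sheet)
    filtered: dict[str, list] = {}
    filter_reports = []
    for sample_id in sorted(coverage_paths):
        path = coverage_paths[sample_id]
        manifest["inputs"][f"coverage:{sample_id}"] = _sha256(path)
        records = read_coverage_file(
            path, sample_id, strip_chr_prefix=config.chr_prefix_strip
        )
        kept, report = filter_coverage(
            records,
            min_exclusive=config.min_coverage_exclusive,
            upper_percentile=config.max_coverage_percentile,
        )
        assert report.removed_low + report.removed_high + report.retained == report.n_input
        filtered[sample_id] = kept
        filter_reports.append(report.to_dict())
    manifest["stages"]["filtered_records"] = {
        s: len(v) for s, v in sorted(filtered.items())
    }

    # --- annotation ------------------------------------------------------
    log.info("stage: annotation")
    for name in ("refgene", "islands", "sample_sheet"):
        manifest["inputs"][name] = _sha256(Path(getattr(config, name)))
    genes = read_refgene_table(config.refgene, strip_chr_prefix=config.chr_prefix_strip)
    genes = select_transcripts(genes, policy=config.transcript_policy)
    islands = read_bed_intervals(
        config.islands, strip_chr_prefix=config.chr_prefix_strip
    )
    components = []
    for gene in genes:
        components.extend(
            derive_components(
                gene, config.promoter_upstream, config.promoter_downstream
            )
        )
    regions = intersect_with_islands(components, islands)
    manifest["stages"]["genes"] = len(genes)
    manifest["stages"]["regions_total"] = len(regions)

    assignment = assign_cytosines(filtered, regions)
    manifest["stages"]["regions_with_data"] = len(assignment.by_region)
    manifest["stages"]["coverage_summary"] = assignment.summary()

    # --- testing + classification ---------------------------------------
    log.info("stage: differential testing")
    results = analyze_regions(
        assignment,
        sheet,
        alpha=config.alpha,
        fdr_family=config.fdr_family,
        groups_tested=config.groups_tested,
        test=config.test,
    )
    classification = classify_regions(results, alpha=config.alpha)
    manifest["stages"]["regions_tested"] = len(results)
    manifest["stages"]["significant"] = {
        fam: len(classification.significant(fam)) for fam in FAMILY_FILES
    }

    # --- outputs ---------------------------------------------------------
    log.info("stage: writing results bundle")
    paths: dict[str, Path] = {}
    paths["results"] = outdir / "results.tsv"
    write_results_table(results, paths["results"])
    for fam, fname in FAMILY_FILES.items():
        paths[fam] = outdir / fname
        write_results_table(classification.significant(fam), paths[fam])

    levels = levels_frame(results)
    paths["levels"] = outdir / "levels.tsv"
    levels.to_csv(paths["levels"], sep="\t", index=False, float_format="%.6g")

    oprof = ordinal_profile(levels, cap=config.ordinal_cap)
    paths["profile_ordinal"] = outdir / "profile_ordinal.tsv"
    oprof.table.to_csv(
        paths["profile_ordinal"], sep="\t", index=False, float_format="%.6g"
    )
    lprof = length_profile(levels, n_bins=config.length_bins)
    paths["profile_length"] = outdir / "profile_length.tsv"
    lprof.table.to_csv(
        paths["profile_length"], sep="\t", index=False, float_format="%.6g"
    )
    corr = difference_correlation(results)
    paths["difference_correlation"] = outdir / "difference_correlation.tsv"
    corr.to_csv(
        paths["difference_correlation"], sep="\t", index=False, float_format="%.6g"
    )

    overlaps = summarize_overlaps(results)
    paths["overlap_summary"] = outdir / "overlap_summary.json"
    paths["overlap_summary"].write_text(json.dumps(overlaps, indent=2, sort_keys=True))
    paths["filter_report"] = outdir / "filter_report.json"
    paths["filter_report"].write_text(
        json.dumps(filter_reports, indent=2, sort_keys=True)
    )
    manifest["captured_fraction"] = {
        f"{kind}:{'cpgi' if island else 'all'}": frac
        for (kind, island), frac in sorted(oprof.captured_fraction.items())
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if config.plots:
        from .profiles import plot_ordinal_profile

        paths["plot_ordinal"] = outdir / "profile_ordinal.png"
        plot_ordinal_profile(oprof, paths["plot_ordinal"])

    return RunResult(
        config=config,
        results=results,
        classification=classification,
        manifest=manifest,
        paths=paths,
    )
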