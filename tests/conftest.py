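"""Shared fixtures: toy gene models and seeded synthetic analyses.

The two expensive session fixtures (`null_analysis`, `recovery_analysis`)
run the full filter -> annotate -> test chain once on generator output and
are shared between the calibration, power and profile tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from methcomp.annotation import (
    assign_cytosines,
    derive_components,
    intersect_with_islands,
)
from methcomp.filtering import filter_coverage
from methcomp.io_formats import GeneModel
from methcomp.region_stats import analyze_regions
from methcomp.synthetic import SyntheticConfig, SyntheticDataset, generate_dataset


@pytest.fixture
def plus_gene() -> GeneModel:
    """Two-exon plus-strand gene: exons [100,200) and [300,400)."""
    return GeneModel(
        gene_id="plus",
        chrom="chr1",
        strand="+",
        tx_start=100,
        tx_end=400,
        exon_starts=(100, 300),
        exon_ends=(200, 400),
    )


@pytest.fixture
def minus_gene() -> GeneModel:
    """Same exon layout on the minus strand."""
    return GeneModel(
        gene_id="minus",
        chrom="chr1",
        strand="-",
        tx_start=100,
        tx_end=400,
        exon_starts=(100, 300),
        exon_ends=(200, 400),
    )


@dataclass
class AnalyzedDataset:
    dataset: SyntheticDataset
    results: list
    by_base_key: dict


def _analyze(config: SyntheticConfig) -> AnalyzedDataset:
    dataset = generate_dataset(config)
    filtered = {s: filter_coverage(r)[0] for s, r in dataset.samples.items()}
    components = []
    for gene in dataset.genes:
        components.extend(
            derive_components(
                gene, config.promoter_upstream, config.promoter_downstream
            )
        )
    regions = intersect_with_islands(components, dataset.islands)
    assignment = assign_cytosines(filtered, regions)
    results = analyze_regions(assignment, dataset.sample_sheet)
    by_base_key = {
        (r.gene_id, r.component_kind, r.ordinal): r
        for r in results
        if not r.cpg_island
    }
    return AnalyzedDataset(dataset=dataset, results=results, by_base_key=by_base_key)


@pytest.fixture(scope="session")
def null_analysis() -> AnalyzedDataset:
    """No planted effects, no islands: ~2000 independent null regions, 3v3,
    negative-binomial coverage with mean 30."""
    config = SyntheticConfig(
        seed=20260924,
        n_genes=100,
        island_prob={k: 0.0 for k in ("promoter", "exon_first", "exon_later",
                                      "intron_first", "intron_later")},
        n_planted_per_effect=0,
    )
    return _analyze(config)


@pytest.fixture(scope="session")
def recovery_analysis() -> AnalyzedDataset:
    """Default study conditions with 50 planted regions per effect size."""
    config = SyntheticConfig(seed=20260924, n_genes=100)
    return _analyze(config)
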