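# Methods

This note documents the statistical model, the conventions and defaults, the
synthetic-data generator, and the numerical choices behind `methcomp`, in
enough detail to audit or re-implement any stage.

## Region model

A gene contributes one promoter, its exons, and its introns, each treated as
a single testable entity.

* **Coordinates.** Gene models and all derived regions are 0-based
  half-open; cytosine positions are 1-based (bismark `.cov` dialect). The
  only place the two meet is the membership predicate
  `start < pos ≤ end`, equivalent to `(pos − 1) ∈ [start, end)`.
* **Promoter.** `[TSS − upstream, TSS + downstream)`, strand-aware,
  clipped (never extended) at position 0. Default 2000 bp upstream, 0 bp
  downstream. There is no data-driven promoter definition; this is a
  convention and therefore an explicit configuration knob — DMP results
  depend on it.
* **Ordinals.** Exons are numbered 1..k in transcription order (on the
  minus strand the genomic-rightmost exon is exon 1); intron *i* lies
  between transcription-order exons *i* and *i+1*. Single-exon genes have
  no introns; zero-length gaps between abutting exons are skipped with a
  log entry. For every gene, exons and introns exactly tile
  `[tx_start, tx_end)`; this invariant is property-tested.
* **Transcript deduplication.** Gene tables often carry several transcripts
  per gene id; one is selected before annotation — default the longest
  span, ties to the smaller start. The policy is configurable (`longest` |
  `first`) because no principled choice exists without expression data.
* **CpG-island intersections.** A component overlapping an island yields an
  additional region with the same identity, `cpg_island=true`, and
  intervals equal to the geometric intersection (possibly fragmented). The
  parent region is retained, so plain and island variants intentionally
  share cytosines; they are tested in separate FDR families.
* **Cytosine strand** is not modelled: coverage files are assumed
  CpG-destranded upstream (plus/minus counts merged per CpG).

## Coverage filter

Per sample, independently: cytosines with total reads ≤ 10 are removed;
then the 99.9th percentile of the remaining coverage distribution is
computed and cytosines at or above it are removed (PCR duplicates and
repetitive regions). The percentile is **nearest-rank** — the
`ceil(q/100·n)`-th order statistic, with the rank computed in exact integer
arithmetic after resolving `q` to three decimals, so boundary cases (the
99.9th percentile of exactly 1000 values) do not drift on binary rounding.
Whether the upper cut should be per sample or pooled across samples is a
judgment call; per sample is used, and the per-sample thresholds are
recorded in the filter report so the choice is auditable.

## Weighted methylation level

For one region and one group, individual *i*'s per-region counts are
`M_i = Σ_j MR_ij`, `T_i = Σ_j TR_ij`. The level is the weighted form
`Σ_i (M_i/T_i)·W_i` with `W_i = T_i/Σ_i T_i`, which is algebraically the
pooled ratio `Σ_i M_i / Σ_i T_i`. The implementation evaluates the weighted
form; the pooled ratio serves as the independent oracle in tests (identity
asserted to 1e-12 over randomized configurations). Individuals with zero
coverage in the region are excluded from the weights; a region with no
reads in a tested group is excluded from testing and counted in the log.

## Differential test

Per region, a binomial GLM with logit link is fitted on the
individual-level aggregated successes/failures `(M_i, T_i − M_i)` with an
intercept and a two-level group indicator (low = 0, high = 1), using
statsmodels IRLS. The reported p-value is the two-sided Wald test for the
group coefficient (an LRT is available behind the `test` option). Fitting
on individual-level rows rather than pooled group totals keeps the model
honest about its unit of replication, although the two-group fit is
saturated at the group level, so the ML coefficient equals
`logit(π_high) − logit(π_low)` on pooled ratios — that closed form is the
cross-check oracle (agreement to 1e-6 asserted on random instances).

**Separation.** If a group is entirely methylated or unmethylated, the MLE
diverges. The fit then falls back to the closed form on continuity-adjusted
pooled cells (0.5 added to each of the four cells, the Haldane–Anscombe
correction), with the standard log-odds-ratio Wald error
`sqrt(Σ 1/cell)`. The region is flagged `separation=true`, never silently.

**Only low vs high** enter the model; the medium group's level is reported
descriptively. The methylation difference is `π_low − π_high` (positive =
hyper), matching the low-before-high phrasing used for the group design;
swapping the tested group order flips the sign and leaves p-values
unchanged (tested).

**FDR.** Benjamini–Hochberg step-up (`q_(k) = min_{j≥k} p_(j)·m/j`, capped
at 1), implemented directly and tested for exact equality against an
independent O(n²) brute force and against `statsmodels.multipletests`.
Whether one family or six is the right multiplicity unit is genuinely open;
the default adjusts **within each of the six families** (DMP, DME, DMI and
island variants), since the six lists are reported separately, and a
`global` option exists. NaN p-values propagate and are excluded from m.
Significance is strict `q < 0.05`.

## Profiles

Each region contributes its level once (region-equal weighting, matching
how regions appear as observations in boxplot-style summaries), not
weighted by reads. Ordinal profiles aggregate up to a cap of 20 ordinal
positions — beyond it, positions are sparsely populated — with an overflow
pool and the captured fraction reported. Length profiles use decile bins of
the observed length distribution per (kind, first/other, island) stratum
(merged with a warning when lengths are too few) and report a Spearman
trend of bin midpoint versus bin mean. Difference correlations are Pearson
correlations of per-gene methylation differences across promoter / first
exon / first intron, pairwise-complete, undefined (and flagged) below 3
shared genes.

## Synthetic data generator

What it emulates, with defaults:

| aspect | default | rationale |
|---|---|---|
| design | 3 groups × 3 replicates | the small-cohort design the method targets |
| genes | 100, 1–20 exons (uniform), exon/intron lengths lognormal (median ≈ 250 / 1200 bp) | compact but ordinal-rich gene structures |
| CpG density | 1/50 bp outside islands, 1/12.5 bp inside | RRBS enriches CpG-dense fractions; islands are denser |
| island placement | promoter 0.7, first exon 0.5, first intron 0.4, later 0.15, covering 40–90% of the component | islands concentrate at gene starts |
| coverage | negative binomial, mean 30, dispersion 5 | overdispersed counts typical of RRBS after deduplication |
| baselines | promoter 0.10, first exon 0.22, first intron 0.31, later exons/introns 0.45; island sites × 0.5 | the canonical ordering: promoters lowest, first ordinals below later ones, island sites lower still |
| planted effects | 50 regions each at ±5, ±10, ±20 percentage points, random sign, applied ±e/2 to low/high so the medium group sits between | known truth for power and direction checks |
| methylated reads | binomial given coverage (beta-binomial behind `bb_rho`) | the test's assumed model; the knob demonstrates miscalibration under overdispersion |

Planting is eligibility-aware: a region can receive effect *e* only if
every site proportion stays within [0, 1] after ±e/2 — so a 20-point effect
never lands on a 5%-methylated island promoter; infeasible configurations
are rejected at validation. The truth table covers every base region
exactly once (0 for nulls); island variants inherit their parent's effect
because they share its cytosines.

What it does **not** emulate: read-level artifacts (bisulfite conversion
error, mapping bias, strand asymmetries), correlated methylation along the
genome, sample-level covariates, and biological between-replicate variance
beyond the coverage model (unless `bb_rho` is set). Passing calibration
tests therefore shows the inference is correct *under its own model*; on
real RRBS with biological replicate variance the binomial GLM is expected
to be anticonservative, which is exactly what the `bb_rho` knob exposes.

## Problem sizes and numerical choices

* Calibration and power checks run at 100 genes (≈ 2000–2500 testable
  regions), chosen so Monte-Carlo intervals are tight while a full run
  stays in tens of seconds; the null simulation disables islands so the
  ~2000 p-values come from disjoint cytosine sets and are independent.
* The null type-I error at p < 0.05 is required to sit inside the 99%
  binomial interval around 0.05; detection of 20-point effects is required
  at ≥ 90% with per-family BH, with monotone power in effect size and
  correct hyper/hypo direction for every detected planted region.
* Seeds: every stochastic component takes a single integer seed;
  annotation and counts use distinct child streams
  (`default_rng([seed, k])`) so the two generator stages are independently
  reproducible. Identical config + seed give byte-identical files; output
  tables are written with fixed formats (levels at 4 decimals in percent,
  p/Q at 6 significant digits) and deterministic row order
  (chrom, start, kind, ordinal).
* Degenerate inputs: empty coverage files warn and return empty; regions
  with no covered cytosines are excluded and counted; a filter that removes
  everything raises instead of returning an empty study; unknown
  chromosomes in coverage data are logged once and skipped.

## Known limitations

* The Wald test on 3-vs-3 aggregated counts leans on large pooled read
  counts, not on the number of animals; with few sites and low coverage
  p-values are slightly anticonservative (visible as a null rejection rate
  a few per mil above 0.05).
* Components of different genes may overlap (promoters over neighbouring
  first exons); regions are tested as-is, without de-overlapping, and
  island variants are correlated with their parents by construction —
  per-family FDR does not correct across families.
* No smoothing or dispersion shrinkage (methylKit/DSS-style); the plain
  logistic model is the method under study, deliberately.
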