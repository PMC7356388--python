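"""Region-level methylation statistics and differential testing.

The per-region, per-group summary is the *weighted methylation level*

    pi = sum_i sum_j MR_ij / sum_i sum_j TR_ij

where ``MR_ij`` / ``TR_ij`` are the methylated / total read counts of
cytosine *j* in individual *i*: each individual's methylation ratio is
weighted by its share of the group's reads, which is algebraically the
pooled ratio of methylated to total reads.  The implementation evaluates the
explicit weighted form; the pooled-ratio identity is asserted in the test
suite.

Differential testing between the low and high groups fits, per region, a
binomial GLM with logit link on the individual-level aggregated counts
``(M_i, T_i - M_i)`` with a two-level group indicator:

    ln(pi_i / (1 - pi_i)) = u + beta * group_i

and reports the two-sided Wald p-value for ``beta = 0`` (likelihood-ratio
test available as an option).  Because the two-group model is saturated at
the group level, the maximum-likelihood ``beta`` equals
``logit(pi_high) - logit(pi_low)`` on the pooled group ratios — the closed
form used both as an independent oracle and as the continuity-adjusted
fallback when a group is completely (un)methylated.

Q-values are Benjamini–Hochberg step-up adjusted p-values, applied by
default separately within each of the six region families (promoter, exon,
intron, and their CpG-island variants).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import chi2, norm

from .annotation import FAMILY_LABELS, RegionAssignment, RegionKey
from .errors import ConfigError, DataError
from .io_formats import GROUPS, SampleSheet

log = logging.getLogger(__name__)

HYPER = "hyper"
HYPO = "hypo"
NS = "ns"


@dataclass(frozen=True)
class GroupRegionCounts:
    """Read counts of one region aggregated per individual, for one group.

    ``meth[i]`` / ``total[i]`` are the sums of methylated / total reads over
    the region's cytosines for individual *i*; ``n_sites`` is the number of
    distinct cytosine positions contributing in this group.
    """

    key: RegionKey
    group: str
    meth: tuple[int, ...]
    total: tuple[int, ...]
    n_sites: int

    def __post_init__(self) -> None:
        if len(self.meth) != len(self.total) or not self.meth:
            raise ValueError("per-individual count vectors empty or unequal")
        for m, t in zip(self.meth, self.total):
            if not 0 <= m <= t:
                raise ValueError(f"invalid counts m={m}, t={t}")

    @property
    def n(self) -> int:
        return len(self.total)

    @property
    def pooled(self) -> tuple[int, int]:
        return (sum(self.meth), sum(self.total))


def weighted_methylation(counts: GroupRegionCounts) -> float:
    """Weighted methylation level of one region in one group (a fraction)."""
    meth = np.asarray(counts.meth, dtype=float)
    total = np.asarray(counts.total, dtype=float)
    covered = total > 0
    if not covered.any():
        raise DataError(f"region {counts.key}: no reads in group {counts.group}")
    weights = total[covered] / total[covered].sum()
    return float(np.sum(meth[covered] / total[covered] * weights))


def methylation_difference(level_low: float, level_high: float) -> float:
    """Signed methylation difference, low-group minus high-group.

    Positive differences are hyper-methylation, negative hypo-methylation.
    """
    return level_low - level_high


@dataclass(frozen=True)
class LogisticFit:
    beta: float
    intercept: float
    p_value: float
    separation: bool = False


def _adjusted_closed_form(ml: int, tl: int, mh: int, th: int) -> LogisticFit:
    """Closed-form fit with a 0.5 continuity adjustment on the pooled cells."""
    a, b = ml + 0.5, (tl - ml) + 0.5
    c, d = mh + 0.5, (th - mh) + 0.5
    beta = float(np.log(c / d) - np.log(a / b))
    intercept = float(np.log(a / b))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    p = float(2.0 * norm.sf(abs(beta) / se))
    return LogisticFit(beta=beta, intercept=intercept, p_value=p, separation=True)


def logistic_test(
    counts_low: GroupRegionCounts,
    counts_high: GroupRegionCounts,
    test: str = "wald",
) -> LogisticFit:
    """Binomial-logistic two-group differential test for one region.

    The group indicator is 0 for the first (reference) argument and 1 for the
    second, so ``beta`` is the log-odds of the second group relative to the
    first.  Complete separation (a group entirely methylated or entirely
    unmethylated) falls back to the continuity-adjusted closed form and is
    flagged, never silent.
    """
    if test not in ("wald", "lrt"):
        raise ConfigError(f"unknown test {test!r}")
    ml, tl = counts_low.pooled
    mh, th = counts_high.pooled
    if tl == 0 or th == 0:
        raise DataError("both groups need at least one read")
    if ml in (0, tl) or mh in (0, th):
        return _adjusted_closed_form(ml, tl, mh, th)

    meth = np.array(counts_low.meth + counts_high.meth, dtype=float)
    total = np.array(counts_low.total + counts_high.total, dtype=float)
    indicator = np.concatenate(
        [np.zeros(counts_low.n), np.ones(counts_high.n)]
    )
    covered = total > 0
    endog = np.column_stack([meth[covered], (total - meth)[covered]])
    exog = sm.add_constant(indicator[covered])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(endog, exog, family=sm.families.Binomial())
            res = model.fit()
        if not np.all(np.isfinite(res.params)) or not np.isfinite(res.bse[1]):
            raise ValueError("non-finite GLM estimates")
    except Exception:  # noqa: BLE001 - any fit failure routes to the fallback
        log.warning("region %s: GLM failed, using adjusted closed form", counts_low.key)
        return _adjusted_closed_form(ml, tl, mh, th)
    beta = float(res.params[1])
    intercept = float(res.params[0])
    if test == "wald":
        z = beta / float(res.bse[1])
        p = float(2.0 * norm.sf(abs(z)))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_res = sm.GLM(
                endog, exog[:, :1], family=sm.families.Binomial()
            ).fit()
        stat = 2.0 * (res.llf - null_res.llf)
        p = float(chi2.sf(max(stat, 0.0), df=1))
    return LogisticFit(beta=beta, intercept=intercept, p_value=p)


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (Q-values).

    NaN entries propagate as NaN and are excluded from the testing count m.
    The adjustment preserves p-value order and is capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    m = int(mask.sum())
    if m == 0:
        return q
    pv = p[mask]
    if pv.min() < 0 or pv.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order]
    raw = ranked * m / np.arange(1, m + 1)
    stepped = np.minimum.accumulate(raw[::-1])[::-1]
    stepped = np.minimum(stepped, 1.0)
    q_masked = np.empty(m)
    q_masked[order] = stepped
    q[mask] = q_masked
    return q


@dataclass
class RegionTestResult:
    """Full per-region test outcome, including descriptive medium-group level."""

    gene_id: str
    chrom: str
    component_kind: str
    ordinal: int
    cpg_island: bool
    start: int
    end: int
    length: int
    n_cytosines: int
    meth_low: float
    meth_medium: float
    meth_high: float
    meth_diff: float
    beta: float
    intercept: float
    p_value: float
    q_value: float = float("nan")
    direction: str = NS
    separation: bool = False

    @property
    def key(self) -> RegionKey:
        return (self.gene_id, self.component_kind, self.ordinal, self.cpg_island)

    @property
    def family(self) -> str:
        return FAMILY_LABELS[(self.component_kind, self.cpg_island)]


def _group_counts(
    pairs: Sequence[tuple[str, object]],
    sheet: SampleSheet,
    group: str,
    key: RegionKey,
) -> GroupRegionCounts | None:
    samples = sheet.samples_in(group)
    if not samples:
        return None
    per_sample: dict[str, list] = {s: [] for s in samples}
    positions: set[int] = set()
    for sample_id, rec in pairs:
        if sample_id in per_sample:
            per_sample[sample_id].append(rec)
            positions.add(rec.pos)
    meth = tuple(sum(r.meth_reads for r in recs) for recs in per_sample.values())
    total = tuple(sum(r.total_reads for r in recs) for recs in per_sample.values())
    if sum(total) == 0:
        return None
    return GroupRegionCounts(
        key=key, group=group, meth=meth, total=total, n_sites=len(positions)
    )


def analyze_regions(
    assignment: RegionAssignment,
    sample_sheet: SampleSheet,
    *,
    alpha: float = 0.05,
    fdr_family: str = "per_family",
    groups_tested: tuple[str, str] = ("low", "high"),
    test: str = "wald",
) -> list[RegionTestResult]:
    """Test every non-empty region and attach BH Q-values and directions.

    Only the two ``groups_tested`` enter the logistic model (the medium
    group's level is reported descriptively); ``meth_diff`` is the level of
    the first listed group minus the second.  ``fdr_family`` selects whether
    BH runs separately within each of the six region families (default) or
    once globally.  Direction requires strict ``q < alpha``.
    """
    if fdr_family not in ("per_family", "global"):
        raise ConfigError(f"unknown fdr_family {fdr_family!r}")
    for g in groups_tested:
        if g not in GROUPS:
            raise ConfigError(f"unknown group {g!r} in groups_tested")

    region_map = assignment.region_map
    results: list[RegionTestResult] = []
    n_skipped = 0
    ordered_keys = sorted(
        assignment.by_region,
        key=lambda k: (
            region_map[k].chrom,
            region_map[k].start,
            k[1],
            k[2],
            k[3],
        ),
    )
    ref_group, alt_group = groups_tested
    for key in ordered_keys:
        region = region_map[key]
        pairs = assignment.by_region[key]
        counts = {
            g: _group_counts(pairs, sample_sheet, g, key) for g in GROUPS
        }
        ref, alt = counts[ref_group], counts[alt_group]
        if ref is None or alt is None:
            n_skipped += 1
            continue
        levels = {
            g: (weighted_methylation(c) if c is not None else float("nan"))
            for g, c in counts.items()
        }
        fit = logistic_test(ref, alt, test=test)
        n_sites = len({rec.pos for _, rec in pairs})
        results.append(
            RegionTestResult(
                gene_id=region.gene_id,
                chrom=region.chrom,
                component_kind=region.component_kind,
                ordinal=region.ordinal,
                cpg_island=region.cpg_island,
                start=region.start,
                end=region.end,
                length=region.length,
                n_cytosines=n_sites,
                meth_low=levels["low"],
                meth_medium=levels["medium"],
                meth_high=levels["high"],
                meth_diff=methylation_difference(levels[ref_group], levels[alt_group]),
                beta=fit.beta,
                intercept=fit.intercept,
                p_value=fit.p_value,
                separation=fit.separation,
            )
        )
    if n_skipped:
        log.info("%d regions skipped (no reads in a tested group)", n_skipped)

    if fdr_family == "global":
        families: dict[str, list[int]] = {"all": list(range(len(results)))}
    else:
        families = {}
        for i, r in enumerate(results):
            families.setdefault(r.family, []).append(i)
    for indices in families.values():
        q = adjust_fdr([results[i].p_value for i in indices])
        for i, qi in zip(indices, q):
            results[i].q_value = float(qi)
    for r in results:
        if not np.isnan(r.q_value) and r.q_value < alpha:
            if r.meth_diff > 0:
                r.direction = HYPER
            elif r.meth_diff < 0:
                r.direction = HYPO
            else:
                r.direction = "ns-direction"
                log.info("region %s significant with zero difference", r.key)
        else:
            r.direction = NS
    return results


@dataclass
class DMRClassification:
    """Significant regions partitioned by family and direction."""

    alpha: float
    sets: dict[str, dict[str, list[RegionTestResult]]]
    n_tested: dict[str, int]

    def counts(self) -> dict[str, dict[str, int]]:
        return {
            fam: {direction: len(items) for direction, items in dirs.items()}
            for fam, dirs in self.sets.items()
        }

    def significant(self, family: str) -> list[RegionTestResult]:
        dirs = self.sets.get(family, {})
        return dirs.get(HYPER, []) + dirs.get(HYPO, [])


def classify_regions(
    results: Sequence[RegionTestResult], alpha: float = 0.05
) -> DMRClassification:
    """Partition tested regions into hyper/hypo DMR sets per family.

    Families are DMP/DME/DMI and their -CpGi variants; significance is strict
    ``q < alpha``; direction is the sign of the methylation difference.
    Every tested region lands in exactly one of hyper / hypo /
    not-significant within its family.
    """
    sets: dict[str, dict[str, list[RegionTestResult]]] = {
        fam: {HYPER: [], HYPO: [], NS: []} for fam in FAMILY_LABELS.values()
    }
    n_tested: dict[str, int] = {fam: 0 for fam in FAMILY_LABELS.values()}
    for r in results:
        n_tested[r.family] += 1
        direction = r.direction if r.direction in (HYPER, HYPO) else NS
        if r.direction == "ns-direction":
            log.info("region %s: significant but zero difference", r.key)
        sets[r.family][direction].append(r)
    return DMRClassification(alpha=alpha, sets=sets, n_tested=n_tested)
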