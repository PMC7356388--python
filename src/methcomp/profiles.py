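"""Descriptive component-level methylation summaries.

Three views of the per-region weighted levels:

* ordinal profiles — mean level per group for the promoter (ordinal 0) and
  the first ``cap`` ordinal exon/intron positions, island and non-island
  regions separately, with regions beyond the cap pooled into an overflow
  class and the captured fraction reported;
* length profiles — mean level by length bin (deciles of the observed
  length distribution by default), split into first vs later ordinals, with
  a Spearman trend statistic of bin midpoint against mean level;
* difference correlations — Pearson correlation of per-gene methylation
  differences between component kinds (promoter vs first exon vs first
  intron), the classic check of whether promoters and first exons move
  together.

Each region contributes its level once (region-equal weighting), not
weighted by read counts, so heavily covered regions do not dominate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .annotation import EXON, INTRON, PROMOTER
from .region_stats import RegionTestResult

log = logging.getLogger(__name__)

OVERFLOW = "overflow"


def levels_frame(results: Sequence[RegionTestResult]) -> pd.DataFrame:
    """Tidy per-region x per-group weighted levels (fractions).

    Columns: gene_id, chrom, component_kind, ordinal, cpg_island, length,
    group, level.  Groups without coverage in a region appear as NaN and are
    dropped.
    """
    rows = []
    for r in results:
        for group, level in (
            ("low", r.meth_low),
            ("medium", r.meth_medium),
            ("high", r.meth_high),
        ):
            if np.isnan(level):
                continue
            rows.append(
                {
                    "gene_id": r.gene_id,
                    "chrom": r.chrom,
                    "component_kind": r.component_kind,
                    "ordinal": r.ordinal,
                    "cpg_island": r.cpg_island,
                    "length": r.length,
                    "group": group,
                    "level": level,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "chrom",
            "component_kind",
            "ordinal",
            "cpg_island",
            "length",
            "group",
            "level",
        ],
    )


@dataclass
class OrdinalProfile:
    """Aggregated levels per group x kind x ordinal x island flag."""

    cap: int
    table: pd.DataFrame  # group, component_kind, ordinal_label, cpg_island, level, n
    captured_fraction: dict[tuple[str, bool], float]


def ordinal_profile(levels: pd.DataFrame, cap: int = 20) -> OrdinalProfile:
    """Aggregate region levels by ordinal position up to ``cap``.

    The promoter is summarized as ordinal 0; exons/introns beyond the cap are
    pooled into an ``overflow`` class.  ``captured_fraction`` reports, per
    (kind, island flag), the fraction of distinct regions with ordinal <= cap.
    """
    df = levels.copy()
    df["ordinal_label"] = np.where(
        (df["component_kind"] != PROMOTER) & (df["ordinal"] > cap),
        OVERFLOW,
        df["ordinal"].astype(str),
    )
    grouped = (
        df.groupby(
            ["group", "component_kind", "ordinal_label", "cpg_island"],
            as_index=False,
        )
        .agg(level=("level", "mean"), n=("level", "size"))
        .sort_values(["group", "component_kind", "cpg_island", "ordinal_label"])
        .reset_index(drop=True)
    )
    captured: dict[tuple[str, bool], float] = {}
    regions = df.drop_duplicates(["gene_id", "component_kind", "ordinal", "cpg_island"])
    for (kind, island), sub in regions.groupby(["component_kind", "cpg_island"]):
        if kind == PROMOTER:
            continue
        captured[(kind, bool(island))] = float((sub["ordinal"] <= cap).mean())
    return OrdinalProfile(cap=cap, table=grouped, captured_fraction=captured)


@dataclass
class LengthProfile:
    table: pd.DataFrame  # component_kind, ordinal_class, cpg_island, bin, midpoint, level, n
    trend: dict[tuple[str, str, bool], float]  # Spearman rho of midpoint vs mean level


def length_profile(
    levels: pd.DataFrame, n_bins: int = 10, kinds: Sequence[str] = (EXON, INTRON)
) -> LengthProfile:
    """Mean level per length bin, split into first vs later ordinals.

    Bins are quantiles (deciles by default) of the observed lengths within
    each (kind, ordinal class, island) stratum; if there are fewer distinct
    lengths than bins, bins are merged with a warning.  The trend statistic
    is the Spearman correlation of bin midpoints with bin mean levels.
    """
    df = levels[levels["component_kind"].isin(kinds)].copy()
    # one observation per region: average the group levels
    df = (
        df.groupby(
            ["gene_id", "component_kind", "ordinal", "cpg_island", "length"],
            as_index=False,
        )["level"]
        .mean()
    )
    df["ordinal_class"] = np.where(df["ordinal"] == 1, "first", "other")
    rows = []
    trend: dict[tuple[str, str, bool], float] = {}
    for (kind, oclass, island), sub in df.groupby(
        ["component_kind", "ordinal_class", "cpg_island"]
    ):
        n_eff = min(n_bins, sub["length"].nunique())
        if n_eff < n_bins:
            log.warning(
                "%s/%s island=%s: only %d distinct lengths, merging bins",
                kind,
                oclass,
                island,
                n_eff,
            )
        if n_eff <= 1:
            bins = pd.Series(["all"] * len(sub), index=sub.index)
            mids = {"all": float(sub["length"].mean())}
        else:
            cat = pd.qcut(sub["length"], q=n_eff, duplicates="drop")
            bins = cat.astype(str)
            mids = {str(iv): float(iv.mid) for iv in cat.cat.categories}
        sub = sub.assign(bin=bins)
        agg = sub.groupby("bin", as_index=False, observed=True).agg(
            level=("level", "mean"), n=("level", "size")
        )
        agg["midpoint"] = agg["bin"].map(mids)
        agg = agg.sort_values("midpoint").reset_index(drop=True)
        for _, row in agg.iterrows():
            rows.append(
                {
                    "component_kind": kind,
                    "ordinal_class": oclass,
                    "cpg_island": bool(island),
                    "bin": row["bin"],
                    "midpoint": row["midpoint"],
                    "level": row["level"],
                    "n": int(row["n"]),
                }
            )
        if len(agg) >= 3 and agg["level"].nunique() > 1:
            rho = spearmanr(agg["midpoint"], agg["level"]).statistic
        else:
            rho = float("nan")
        trend[(kind, oclass, bool(island))] = float(rho)
    table = pd.DataFrame(
        rows,
        columns=[
            "component_kind",
            "ordinal_class",
            "cpg_island",
            "bin",
            "midpoint",
            "level",
            "n",
        ],
    )
    return LengthProfile(table=table, trend=trend)


#: default components compared in difference_correlation: (kind, ordinal)
DEFAULT_COMPONENTS = (
    (PROMOTER, 0),
    (EXON, 1),
    (INTRON, 1),
)


def difference_correlation(
    results: Sequence[RegionTestResult],
    components: Sequence[tuple[str, int]] = DEFAULT_COMPONENTS,
    *,
    cpg_island: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of per-gene methylation differences across components.

    For each pair of components (default: promoter, first exon, first
    intron), genes carrying both are joined and the PCC of their methylation
    differences is computed; pairs with fewer than 3 shared genes are flagged
    as undefined (NaN).  The returned table is symmetric in the pair order.
    """
    diffs: dict[tuple[str, int], dict[str, float]] = {c: {} for c in components}
    for r in results:
        c = (r.component_kind, r.ordinal)
        if c in diffs and r.cpg_island == cpg_island:
            diffs[c][r.gene_id] = r.meth_diff
    rows = []
    for (ca, cb) in itertools.combinations(components, 2):
        shared = sorted(set(diffs[ca]) & set(diffs[cb]))
        n = len(shared)
        if n < 3:
            pcc = float("nan")
            log.warning("pair %s vs %s: only %d shared genes, PCC undefined", ca, cb, n)
        else:
            a = np.array([diffs[ca][g] for g in shared])
            b = np.array([diffs[cb][g] for g in shared])
            if np.std(a) == 0 or np.std(b) == 0:
                pcc = float("nan")
            else:
                pcc = float(pearsonr(a, b).statistic)
        rows.append(
            {
                "component_a": f"{ca[0]}{ca[1] or ''}",
                "component_b": f"{cb[0]}{cb[1] or ''}",
                "pcc": pcc,
                "n": n,
            }
        )
    return pd.DataFrame(rows, columns=["component_a", "component_b", "pcc", "n"])


def plot_ordinal_profile(profile: OrdinalProfile, path) -> None:
    """Line plot of mean methylation level by ordinal position, per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, island in zip(axes, (False, True)):
        sub = profile.table[
            (~profile.table["ordinal_label"].eq(OVERFLOW))
            & (profile.table["cpg_island"] == island)
            & (profile.table["component_kind"] != PROMOTER)
        ]
        for (group, kind), s in sub.groupby(["group", "component_kind"]):
            s = s.assign(o=s["ordinal_label"].astype(int)).sort_values("o")
            ax.plot(s["o"], 100 * s["level"], marker="o", ms=3, label=f"{group} {kind}")
        ax.set_title("CpG-island regions" if island else "all regions")
        ax.set_xlabel("ordinal position")
    axes[0].set_ylabel("methylation level (%)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
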