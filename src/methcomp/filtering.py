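"""Cytosine-level coverage quality filters.

Two rules, applied per sample independently:

1. drop cytosines with total read count <= ``min_exclusive`` (default 10);
2. recompute the upper ``upper_percentile``-th percentile (default 99.9) of
   the remaining coverage distribution and drop cytosines at or above it —
   these are almost always PCR duplicates or repeats.

The percentile is the nearest-rank order statistic (the ``ceil(q/100 * n)``-th
smallest value), which is reproducible across platforms and is recorded in
the filter report so either threshold can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import DataError
from .io_formats import CytosineRecord


@dataclass(frozen=True)
class FilterReport:
    """Per-sample accounting of the coverage filter.

    Invariant: ``removed_low + removed_high + retained == n_input``.
    """

    sample_id: str
    n_input: int
    removed_low: int
    removed_high: int
    retained: int
    low_threshold: int
    high_threshold: float

    def __post_init__(self) -> None:
        assert self.removed_low + self.removed_high + self.retained == self.n_input

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def nearest_rank_percentile(values: Sequence[float], q: float) -> float:
    """The q-th percentile as the ceil(q/100 * n)-th order statistic.

    The rank is computed in exact integer arithmetic with ``q`` resolved to
    three decimal places, so boundary cases like the 99.9th percentile of
    1000 values give the mathematically exact rank instead of drifting on
    binary rounding of ``q/100``.
    """
    if not 0 < q < 100:
        raise ValueError(f"percentile must be in (0, 100), got {q}")
    ordered = sorted(values)
    q_milli = round(q * 1000)  # q with 3-decimal resolution, as an integer
    rank = -(-q_milli * len(ordered) // 100_000)  # ceil division
    return ordered[max(rank, 1) - 1]


def filter_coverage(
    records: Sequence[CytosineRecord],
    min_exclusive: int = 10,
    upper_percentile: float = 99.9,
) -> tuple[list[CytosineRecord], FilterReport]:
    """Apply both coverage filters to one sample's records.

    Returns the retained records and a :class:`FilterReport`.  Raises
    :class:`DataError` if nothing survives, since that indicates thresholds
    unsuited to the data.
    """
    if not records:
        raise DataError("filter_coverage requires a non-empty record list")
    sample_id = records[0].sample_id
    above_low = [r for r in records if r.total_reads > min_exclusive]
    removed_low = len(records) - len(above_low)
    if not above_low:
        raise DataError(
            f"sample {sample_id}: all {len(records)} cytosines removed by the "
            f"<= {min_exclusive} coverage rule; review the thresholds"
        )
    threshold = nearest_rank_percentile(
        [r.total_reads for r in above_low], upper_percentile
    )
    retained = [r for r in above_low if r.total_reads < threshold]
    if not retained:
        raise DataError(
            f"sample {sample_id}: no cytosines survive the {upper_percentile}th "
            f"percentile cut (threshold {threshold}); review the thresholds"
        )
    report = FilterReport(
        sample_id=sample_id,
        n_input=len(records),
        removed_low=removed_low,
        removed_high=len(above_low) - len(retained),
        retained=len(retained),
        low_threshold=min_exclusive,
        high_threshold=float(threshold),
    )
    return retained, report
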