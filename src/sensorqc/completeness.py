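"""Completeness metrics: IRLR, SCR and MDR.

* IRLR — interpretable record length ratio: fraction of a participant's
  records with at least two data points.
* SCR — sensor channel ratio: channels present in a record relative to the
  cohort-modal (expected) channel count ESCC.
* MDR — missing data ratio: inferred missing points over the total (observed
  plus missing) point count, with gaps judged against the record's modal
  sampling interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensor_records import (
    RecordSet,
    SensorRecord,
    UndefinedMetricError,
    infer_sampling_interval,
)

__all__ = ["CompletenessResult", "irlr", "escc", "scr", "mdr", "GAP_TOLERANCE"]

# A consecutive gap must exceed (1 + GAP_TOLERANCE) x the modal interval to
# register missing points, so ordinary clock jitter alone is not missingness.
GAP_TOLERANCE = 0.10


@dataclass
class CompletenessResult:
    irlr: float
    scr: float
    mdr: float
    mpc: int
    tpc: int
    escc: int


def irlr(records: RecordSet) -> float:
    """Fraction of records with two or more points (order-invariant)."""
    n = len(records)
    if n == 0:
        raise UndefinedMetricError("IRLR undefined for an empty RecordSet")
    return sum(1 for r in records if r.length > 1) / n


def escc(records: RecordSet) -> int:
    """Expected sensor channel count: the modal channel count across records.

    Ties break to the larger count — the conservative choice, flagging
    dropout in the smaller-channel records rather than excusing it.
    """
    counts = [r.n_channels for r in records if r.n_channels >= 1]
    if not counts:
        raise UndefinedMetricError("no record reports any channel")
    vals, freq = np.unique(counts, return_counts=True)
    return int(vals[freq == freq.max()].max())


def scr(record: SensorRecord, expected_channels: int) -> float:
    """Sensor channel ratio SCC/ESCC, capped at 1."""
    if expected_channels < 1:
        raise ValueError("expected channel count must be >= 1")
    return min(record.n_channels / expected_channels, 1.0)


def mdr(
    record: SensorRecord,
    *,
    sampling_interval: float | None = None,
    gap_tolerance: float = GAP_TOLERANCE,
) -> tuple[float, int, int]:
    """Missing data ratio of a record: (MDR, MPC, TPC).

    For each consecutive gap larger than the (tolerated) modal interval
    ``ts``, the missing point count MPC grows by ``ceil(gap/ts - 1)``; the
    total point count TPC is observed points plus MPC, so MDR lies in [0, 1).
    """
    if record.length < 2:
        raise UndefinedMetricError("MDR undefined for RL < 2")
    ts = sampling_interval if sampling_interval is not None else infer_sampling_interval(record)
    if ts <= 0:
        raise ValueError("sampling interval must be positive")
    gaps = np.diff(record.timestamps)
    big = gaps > (1.0 + gap_tolerance) * ts
    mpc = int(np.sum(np.ceil(gaps[big] / ts - 1.0))) if big.any() else 0
    tpc = record.length + mpc
    return mpc / tpc, mpc, tpc
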