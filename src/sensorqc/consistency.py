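"""Consistency metrics: RLC, SRC and VRC.

Each score maps a coefficient of variation (cv) through the sigmoid-based
"normalized reciprocal" ``2 * (1 - logistic(cv))``: 1 at cv = 0 (perfect
uniformity), monotonically falling towards 0 as dispersion grows.

* RLC — record length consistency: cv of record lengths across a RecordSet.
* SRC — sampling rate consistency: cv of a single record's consecutive
  sampling intervals (intra-record); aggregated to participant level by the
  median over records.
* VRC — value range consistency: cv of per-record value ranges across a
  RecordSet.

Population (not sample) standard deviation is used throughout: with as few
as two records the sample estimator inflates the cv.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .sensor_records import RecordSet, SensorRecord, UndefinedMetricError, value_range

__all__ = ["normalized_reciprocal", "rlc", "src", "vrc"]


def normalized_reciprocal(cv: float) -> float:
    """``2 * (1 - logistic(cv))``; strictly decreasing, 1 at cv=0, -> 0.

    Evaluated as ``2 * logistic(-cv)``, which stays positive up to the
    double-precision underflow limit (cv ~ 745) instead of cancelling to
    zero near cv ~ 37.
    """
    if not np.isfinite(cv) or cv < 0:
        raise ValueError(f"coefficient of variation must be finite and >= 0, got {cv}")
    return float(2.0 * expit(-cv))


def _cv(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        raise ZeroDivisionError("cv undefined for zero mean")
    return float(values.std() / mean)  # population sigma


def rlc(records: RecordSet) -> float:
    """Record length consistency across a RecordSet; 1 for a single record."""
    if len(records) == 0:
        raise UndefinedMetricError("RLC undefined for an empty RecordSet")
    if len(records) == 1:
        return 1.0
    lengths = np.array([r.length for r in records], dtype=float)
    if lengths.mean() == 0:
        raise UndefinedMetricError("RLC undefined when all records are empty")
    return normalized_reciprocal(_cv(lengths))


def src(record: SensorRecord) -> float:
    """Sampling rate consistency of one record's consecutive intervals."""
    if record.length < 3:
        raise UndefinedMetricError("SRC undefined for RL < 3")
    intervals = np.diff(record.timestamps)
    if intervals.mean() == 0:
        raise UndefinedMetricError("SRC undefined for all-duplicate timestamps")
    return normalized_reciprocal(_cv(intervals))


def vrc(records: RecordSet) -> float:
    """Value range consistency across a RecordSet; 1 for a single record.

    All-zero ranges mean perfectly stable output, hence a score of 1.
    """
    usable = [r for r in records if r.length >= 1 and r.n_channels >= 1]
    if not usable:
        raise UndefinedMetricError("VRC undefined without an interpretable record")
    if len(usable) == 1:
        return 1.0
    ranges = np.array([value_range(r)[0] for r in usable], dtype=float)
    if ranges.mean() == 0:
        return 1.0
    return normalized_reciprocal(_cv(ranges))
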