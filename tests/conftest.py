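"""Shared fixtures and builders for the sensorqc test suite."""

from __future__ import annotations

import numpy as np
import pytest

from sensorqc.sensor_records import RecordSet, SensorRecord


def make_record(
    timestamps,
    channels=None,
    *,
    record_id="r",
    participant_id="p",
    device_type="android",
    sensor_type="accelerometer",
    channel_names=(),
):
    ts = np.asarray(timestamps, dtype=float)
    if channels is None:
        channels = np.ones((ts.size, 1))
    return SensorRecord(
        record_id=record_id,
        participant_id=participant_id,
        device_type=device_type,
        sensor_type=sensor_type,
        timestamps=ts,
        channels=np.asarray(channels, dtype=float),
        channel_names=tuple(channel_names),
    )


def grid_record(n, interval=10.0, **kw):
    return make_record(np.arange(n) * interval, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def perfect_recordset():
    """Five identical, perfectly sampled 3-channel records."""
    recs = []
    for i in range(5):
        ts = np.arange(50) * 10.0
        x = np.column_stack([np.sin(ts / 40.0), np.cos(ts / 40.0), ts / 500.0])
        recs.append(
            make_record(ts, x, record_id=f"r{i}", sensor_type="accelerometer")
        )
    return RecordSet(recs)
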