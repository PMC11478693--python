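"""Data model and I/O for per-record multichannel sensor time series.

A *record* is one short duration of continuously sampled passive sensor data:
a vector of millisecond timestamps plus one value channel per sensor axis
(e.g. x/y/z acceleration, or lat/lon/alt for GPS).  Records are grouped per
(participant, sensor) into :class:`RecordSet`, the unit over which
participant-level quality metrics are aggregated.

On-disk format: one CSV per record with header ``t,<ch1>,...`` and a
JSON-lines cohort manifest mapping record files to participant, device type
and sensor type.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "DEVICE_TYPES",
    "SENSOR_TYPES",
    "SensorRecord",
    "RecordSet",
    "ManifestEntry",
    "read_record",
    "write_record",
    "read_manifest",
    "write_manifest",
    "load_cohort",
    "infer_sampling_interval",
    "value_range",
]

logger = logging.getLogger(__name__)

DEVICE_TYPES = ("android", "ios")
SENSOR_TYPES = ("accelerometer", "gyroscope", "gps")


class RecordParseError(ValueError):
    """Raised when a record file contains a malformed cell."""


class UndefinedMetricError(ValueError):
    """Raised when a metric's precondition is not met (e.g. too few points)."""


@dataclass
class SensorRecord:
    """One continuously sampled observation from a single sensor.

    ``timestamps`` are milliseconds (float, ascending after construction);
    ``channels`` has one row per timestamp and one column per channel.
    """

    record_id: str
    participant_id: str
    device_type: str
    sensor_type: str
    timestamps: np.ndarray
    channels: np.ndarray
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float).ravel()
        n = self.timestamps.shape[0]
        ch = np.asarray(self.channels, dtype=float)
        if ch.ndim == 1:
            ch = (
                ch.reshape(-1, 1)
                if ch.size
                else ch.reshape(n, 0) if n else ch.reshape(0, len(self.channel_names))
            )
        if ch.ndim != 2:
            raise ValueError("channels must be a 2-D matrix")
        if ch.shape[0] != n:
            if ch.size == 0:
                ch = ch.reshape(n, 0)
            elif ch.shape[1] == n:
                ch = ch.T
            else:
                raise ValueError(
                    f"channel rows ({ch.shape[0]}) != timestamps ({n})"
                )
        self.channels = ch
        order = np.argsort(self.timestamps, kind="stable")
        if not np.all(order == np.arange(order.size)):
            self.timestamps = self.timestamps[order]
            self.channels = self.channels[order]
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.channels.shape[1]))

    @property
    def length(self) -> int:
        """Record length RL: number of data points."""
        return int(self.timestamps.shape[0])

    @property
    def n_channels(self) -> int:
        """Sensor channel count SCC."""
        return int(self.channels.shape[1])

    def copy(self, **overrides) -> "SensorRecord":
        kw = dict(
            record_id=self.record_id,
            participant_id=self.participant_id,
            device_type=self.device_type,
            sensor_type=self.sensor_type,
            timestamps=self.timestamps.copy(),
            channels=self.channels.copy(),
            channel_names=self.channel_names,
        )
        kw.update(overrides)
        return SensorRecord(**kw)


@dataclass
class RecordSet:
    """Ordered collection of records sharing participant, device and sensor."""

    records: list[SensorRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {(r.participant_id, r.device_type, r.sensor_type) for r in self.records}
        if len(ids) > 1:
            raise ValueError(f"records mix identities: {sorted(ids)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SensorRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def participant_id(self) -> str:
        return self.records[0].participant_id

    @property
    def device_type(self) -> str:
        return self.records[0].device_type

    @property
    def sensor_type(self) -> str:
        return self.records[0].sensor_type


@dataclass
class ManifestEntry:
    participant_id: str
    device_type: str
    sensor_type: str
    path: str
    record_id: str = ""


def read_record(
    path: str | Path,
    *,
    record_id: str = "",
    participant_id: str = "",
    device_type: str = "",
    sensor_type: str = "",
) -> SensorRecord:
    """Read a record CSV (header ``t,<ch1>,...``) into a :class:`SensorRecord`.

    Rows are sorted by timestamp on load.  Zero-row and one-row files load
    successfully (degenerate records feed the interpretable-record-length
    ratio).  Duplicate timestamps are retained with a log message.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        names = header.split(",")[1:] if header else []
        ts: list[float] = []
        vals: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            try:
                row = [float(c) for c in cells]
            except ValueError as exc:
                raise RecordParseError(
                    f"{path}: malformed numeric cell at row {lineno}: {line!r}"
                ) from exc
            ts.append(row[0])
            vals.append(row[1:])
    t = np.asarray(ts, dtype=float)
    x = (
        np.asarray(vals, dtype=float)
        if vals
        else np.empty((0, len(names)), dtype=float)
    )
    if t.size > 1 and np.unique(t).size < t.size:
        logger.info("%s: duplicate timestamps retained", path)
    return SensorRecord(
        record_id=record_id or path.stem,
        participant_id=participant_id,
        device_type=device_type,
        sensor_type=sensor_type,
        timestamps=t,
        channels=x,
        channel_names=tuple(names),
    )


def write_record(record: SensorRecord, path: str | Path, *, fmt: str = "%.6g") -> None:
    """Write a record as CSV; round-trips timestamps/values at ``fmt`` precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("t," + ",".join(record.channel_names) + "\n")
        for t, row in zip(record.timestamps, record.channels):
            fh.write((fmt % t) + "," + ",".join(fmt % v for v in row) + "\n")


def write_manifest(entries: Iterable[ManifestEntry], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for e in entries:
            fh.write(
                json.dumps(
                    {
                        "participant_id": e.participant_id,
                        "device_type": e.device_type,
                        "sensor_type": e.sensor_type,
                        "path": e.path,
                        "record_id": e.record_id,
                    }
                )
                + "\n"
            )


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    path = Path(path)
    out = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            out.append(
                ManifestEntry(
                    participant_id=str(d["participant_id"]),
                    device_type=str(d["device_type"]),
                    sensor_type=str(d["sensor_type"]),
                    path=str(d["path"]),
                    record_id=str(d.get("record_id", "")),
                )
            )
    return out


def load_cohort(manifest_path: str | Path) -> dict[tuple[str, str], RecordSet]:
    """Load all records listed in a manifest, grouped per (participant, sensor).

    Record paths are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    groups: dict[tuple[str, str], list[SensorRecord]] = {}
    for e in read_manifest(manifest_path):
        rec = read_record(
            root / e.path,
            record_id=e.record_id,
            participant_id=e.participant_id,
            device_type=e.device_type,
            sensor_type=e.sensor_type,
        )
        groups.setdefault((e.participant_id, e.sensor_type), []).append(rec)
    return {k: RecordSet(v) for k, v in sorted(groups.items())}


def infer_sampling_interval(
    record: SensorRecord, *, quantum_ms: float = 1.0
) -> float:
    """Data-driven sampling interval: the modal consecutive timestamp difference.

    Real clocks jitter, so differences are quantized (default 1 ms) before the
    mode is taken.  Zero intervals (duplicate timestamps) are excluded; ties
    between modal intervals break to the smallest, which maximizes detected
    missingness.
    """
    if record.length < 2:
        raise UndefinedMetricError("sampling interval undefined for RL < 2")
    diffs = np.diff(record.timestamps)
    q = np.rint(diffs / quantum_ms) * quantum_ms
    q = q[q > 0]
    if q.size == 0:
        raise UndefinedMetricError("all intervals zero (duplicate timestamps only)")
    vals, counts = np.unique(q, return_counts=True)
    modal = vals[counts == counts.max()]
    return float(modal.min())


def value_range(record: SensorRecord) -> tuple[float, np.ndarray]:
    """Per-channel max − min; the scalar record range is the maximum over channels."""
    if record.length < 1:
        raise UndefinedMetricError("value range undefined for empty record")
    per_channel = record.channels.max(axis=0) - record.channels.min(axis=0)
    scalar = float(per_channel.max()) if per_channel.size else 0.0
    return scalar, per_channel
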