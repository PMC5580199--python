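"""Time-stamped multi-sensor records and stream file I/O.

A sensor stream is an ordered sequence of :class:`SensorRecord`, one record
per measurement from a named channel (dust-sensor raw voltage, PM2.5,
temperature, humidity, spirometry, tri-axial acceleration, heart rate, GPS
location).  Streams are stored as CSV or JSON-lines; both formats round-trip
exactly.  "Online source" features (ozone, AQI, traffic, weather) are replayed
from a fixture table keyed by timestamp instead of live API calls, and joined
to analysis windows by last observation carried forward (LOCF).

Timestamps are UTC epoch seconds (float); windows downstream use half-open
intervals ``[start, end)``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "CHANNELS",
    "VECTOR_CHANNELS",
    "SensorRecord",
    "SubjectProfile",
    "OnlineFeatureRow",
    "ParseReport",
    "StreamParseError",
    "MissingOnlineDataError",
    "read_stream",
    "write_stream",
    "read_online_table",
    "write_online_table",
    "join_online_features",
]

#: Channel name -> number of value components (1 = scalar).
#: ``gyro`` is accepted on ingest for completeness but ignored by the
#: feature pipeline, which uses only the channels below it.
CHANNELS: dict[str, int] = {
    "dust_raw": 1,
    "pm25": 1,
    "temperature": 1,
    "humidity": 1,
    "pef": 1,
    "fev1": 1,
    "accel": 3,
    "gyro": 3,
    "heart_rate": 1,
    "location": 2,
}

VECTOR_CHANNELS = frozenset(c for c, n in CHANNELS.items() if n > 1)

Value = Union[float, tuple[float, ...]]


class StreamParseError(ValueError):
    """A stream file contained lines that could not be parsed."""

    def __init__(self, message: str, bad_lines: list[tuple[int, str]]):
        super().__init__(message)
        self.bad_lines = bad_lines


class MissingOnlineDataError(KeyError):
    """A window predates every row of the online-feature fixture table."""


@dataclass(frozen=True)
class SensorRecord:
    """One time-stamped measurement from a named channel.

    Parameters
    ----------
    subject_id:
        Opaque subject identifier.
    channel:
        One of :data:`CHANNELS`.
    t:
        UTC epoch seconds (finite, non-negative).
    value:
        Scalar in channel units, or a 3-tuple (m/s^2) for ``accel``/``gyro``,
        or a (lat, lon) degree pair for ``location``.
    """

    subject_id: str
    channel: str
    t: float
    value: Value

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if not math.isfinite(self.t) or self.t < 0:
            raise ValueError(f"timestamp must be finite and >= 0, got {self.t!r}")
        ncomp = CHANNELS[self.channel]
        if ncomp == 1:
            if isinstance(self.value, (tuple, list)):
                raise ValueError(f"channel {self.channel!r} takes a scalar value")
            v = float(self.value)
            if not math.isfinite(v):
                raise ValueError(f"non-finite value {self.value!r}")
            object.__setattr__(self, "value", v)
        else:
            if not isinstance(self.value, (tuple, list)) or len(self.value) != ncomp:
                raise ValueError(
                    f"channel {self.channel!r} takes exactly {ncomp} components"
                )
            comps = tuple(float(v) for v in self.value)
            if not all(math.isfinite(v) for v in comps):
                raise ValueError(f"non-finite component in {self.value!r}")
            object.__setattr__(self, "value", comps)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject baseline data used by the feature pipeline.

    ``baseline_pef`` (L/min) and ``baseline_fev1`` (L) are the three resting
    spirometry measurements taken while symptom-free; percent-of-personal-best
    features are computed against their means.  ``hr_rest`` feeds the heart
    rate reserve HRR = HRmax - HRrest with HRmax = 208 - 0.7 * age.
    ``channel_ranges`` maps each channel to its closed valid physical range;
    samples outside it (sensor sentinels included) are discarded during
    cleaning.
    """

    subject_id: str
    age: float
    hr_rest: float
    baseline_pef: tuple[float, float, float]
    baseline_fev1: tuple[float, float, float]
    channel_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be positive")
        if not self.hr_rest > 0:
            raise ValueError("resting heart rate must be positive")
        for name, triplet in (("pef", self.baseline_pef), ("fev1", self.baseline_fev1)):
            if len(triplet) != 3 or not all(v > 0 for v in triplet):
                raise ValueError(
                    f"baseline_{name} must be three strictly positive values"
                )
            object.__setattr__(self, f"baseline_{name}", tuple(float(v) for v in triplet))
        for ch, (lo, hi) in self.channel_ranges.items():
            if not lo < hi:
                raise ValueError(f"channel range for {ch!r} must have min < max")


ONLINE_FEATURES = (
    "ozone",
    "pressure",
    "cloud_cover",
    "wind_speed",
    "precip_probability",
    "precip_intensity",
    "traffic_density",
    "aqi",
)


@dataclass(frozen=True)
class OnlineFeatureRow:
    """One timestamped row of replayed online-source features."""

    t: float
    ozone: float
    pressure: float
    cloud_cover: float
    wind_speed: float
    precip_probability: float
    precip_intensity: float
    traffic_density: float
    aqi: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ONLINE_FEATURES}


@dataclass
class ParseReport:
    """Accounting of a lenient parse: every input line is either parsed or
    reported, never silently dropped."""

    n_lines: int = 0
    n_parsed: int = 0
    bad_lines: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_bad(self) -> int:
        return len(self.bad_lines)


def _record_from_parts(subject: str, channel: str, t: str, values: Sequence) -> SensorRecord:
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    ncomp = CHANNELS[channel]
    if ncomp == 1:
        value: Value = float(values[0])
    else:
        value = tuple(float(v) for v in values[:ncomp])
    return SensorRecord(subject_id=subject, channel=channel, t=float(t), value=value)


def _parse_jsonl_line(line: str) -> SensorRecord:
    obj = json.loads(line)
    value = obj["value"]
    values = value if isinstance(value, list) else [value]
    return _record_from_parts(obj["subject"], obj["channel"], obj["t"], values)


def _parse_csv_row(row: Sequence[str]) -> SensorRecord:
    if len(row) < 4:
        raise ValueError(f"expected >= 4 columns, got {len(row)}")
    subject, channel, t = row[0], row[1], row[2]
    values = [v for v in row[3:6] if v != ""]
    if not values:
        raise ValueError("no value columns")
    return _record_from_parts(subject, channel, t, values)


CSV_HEADER = ["subject", "channel", "t", "v1", "v2", "v3"]


def read_stream(
    path: str | Path,
    format: str = "jsonl",
    on_error: str = "raise",
) -> list[SensorRecord] | tuple[list[SensorRecord], ParseReport]:
    """Read a sensor-record stream file, returned sorted by timestamp.

    The sort is stable, so records sharing a timestamp keep file order.

    Parameters
    ----------
    format:
        ``"jsonl"`` (one JSON object per line) or ``"csv"``
        (``subject,channel,t,v1,v2,v3`` with a header row).
    on_error:
        ``"raise"``: any malformed line aborts with
        :class:`StreamParseError` naming line numbers and offending tokens.
        ``"collect"``: return ``(records, ParseReport)`` instead, with every
        bad line accounted for in the report.
    """
    if format not in ("csv", "jsonl"):
        raise ValueError(f"unknown format {format!r}")
    if on_error not in ("raise", "collect"):
        raise ValueError(f"on_error must be 'raise' or 'collect', got {on_error!r}")
    path = Path(path)
    report = ParseReport()
    records: list[SensorRecord] = []

    with path.open(newline="") as fh:
        if format == "csv":
            reader = csv.reader(fh)
            lines: Iterable[tuple[int, object]] = enumerate(reader, start=1)
        else:
            lines = enumerate(fh, start=1)
        for lineno, raw in lines:
            if format == "csv":
                row = raw  # type: ignore[assignment]
                if not row or (lineno == 1 and row[0] == "subject"):
                    continue
                report.n_lines += 1
                try:
                    records.append(_parse_csv_row(row))
                    report.n_parsed += 1
                except (ValueError, KeyError) as exc:
                    report.bad_lines.append((lineno, str(exc)))
            else:
                text = str(raw).strip()
                if not text:
                    continue
                report.n_lines += 1
                try:
                    records.append(_parse_jsonl_line(text))
                    report.n_parsed += 1
                except (ValueError, KeyError, TypeError) as exc:
                    report.bad_lines.append((lineno, str(exc)))

    records.sort(key=lambda r: r.t)
    if report.bad_lines and on_error == "raise":
        first = report.bad_lines[0]
        raise StreamParseError(
            f"{len(report.bad_lines)} malformed line(s) in {path}; "
            f"first at line {first[0]}: {first[1]}",
            report.bad_lines,
        )
    if on_error == "collect":
        return records, report
    return records


def write_stream(records: Sequence[SensorRecord], path: str | Path, format: str = "jsonl") -> None:
    """Write records to ``path`` in time order (stable for ties).

    The output is re-readable by :func:`read_stream` with round-trip identity.
    """
    if format not in ("csv", "jsonl"):
        raise ValueError(f"unknown format {format!r}")
    ordered = sorted(records, key=lambda r: r.t)
    path = Path(path)
    with path.open("w", newline="") as fh:
        if format == "csv":
            writer = csv.writer(fh)
            writer.writerow(CSV_HEADER)
            for rec in ordered:
                vals = rec.value if isinstance(rec.value, tuple) else (rec.value,)
                row = [rec.subject_id, rec.channel, repr(rec.t)]
                row += [repr(v) for v in vals]
                row += [""] * (3 - len(vals))
                writer.writerow(row)
        else:
            for rec in ordered:
                value = list(rec.value) if isinstance(rec.value, tuple) else rec.value
                fh.write(
                    json.dumps(
                        {
                            "subject": rec.subject_id,
                            "channel": rec.channel,
                            "t": rec.t,
                            "value": value,
                        }
                    )
                    + "\n"
                )


ONLINE_CSV_HEADER = ["t", *ONLINE_FEATURES]


def read_online_table(path: str | Path) -> list[OnlineFeatureRow]:
    """Read an online-feature fixture table (CSV, strictly increasing t)."""
    rows: list[OnlineFeatureRow] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        for raw in reader:
            rows.append(
                OnlineFeatureRow(
                    t=float(raw["t"]),
                    **{name: float(raw[name]) for name in ONLINE_FEATURES},
                )
            )
    for a, b in zip(rows, rows[1:]):
        if not a.t < b.t:
            raise ValueError("online table timestamps must be strictly increasing")
    return rows


def write_online_table(rows: Sequence[OnlineFeatureRow], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ONLINE_CSV_HEADER)
        for row in rows:
            writer.writerow([repr(row.t)] + [repr(getattr(row, n)) for n in ONLINE_FEATURES])


def load_profile(path: str | Path) -> SubjectProfile:
    """Load a subject profile from TOML.

    Expected layout::

        [profile]
        subject_id = "adult-01"
        age = 29.0
        hr_rest = 60.0
        baseline_pef = [310.0, 320.0, 330.0]
        baseline_fev1 = [2.9, 3.0, 3.1]

        [profile.ranges]
        heart_rate = [30.0, 220.0]
        # ... one entry per channel present in the stream
    """
    import tomllib

    with Path(path).open("rb") as fh:
        config = tomllib.load(fh)
    section = config.get("profile", config)
    ranges = {
        ch: (float(lo), float(hi)) for ch, (lo, hi) in section.get("ranges", {}).items()
    }
    return SubjectProfile(
        subject_id=str(section["subject_id"]),
        age=float(section["age"]),
        hr_rest=float(section["hr_rest"]),
        baseline_pef=tuple(section["baseline_pef"]),
        baseline_fev1=tuple(section["baseline_fev1"]),
        channel_ranges=ranges,
    )


def join_online_features(
    times: Sequence[float], table: Sequence[OnlineFeatureRow]
) -> list[OnlineFeatureRow]:
    """Align online-feature rows to window end-times by LOCF.

    Each time is matched to the most recent table row at-or-before it.  A time
    earlier than the first row has no defensible carry-forward value and
    raises :class:`MissingOnlineDataError`.
    """
    if not table:
        raise ValueError("online feature table is empty")
    ts = [row.t for row in table]
    if any(a >= b for a, b in zip(ts, ts[1:])):
        raise ValueError("online table must be sorted with strictly increasing t")
    out: list[OnlineFeatureRow] = []
    import bisect

    for t in times:
        idx = bisect.bisect_right(ts, t) - 1
        if idx < 0:
            raise MissingOnlineDataError(
                f"window time {t} precedes first online row at {ts[0]}"
            )
        out.append(table[idx])
    return out
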