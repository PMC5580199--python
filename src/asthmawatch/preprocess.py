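"""Stream cleaning and smoothing.

Raw wearable streams carry two kinds of junk: genuinely missing values and
out-of-bound sentinels (sensors that report a value far outside their
physical range to mean "no data").  Cleaning removes both against per-channel
closed valid ranges and returns an exact accounting.  Environmental channels
are then smoothed with a trailing (causal) 6-second moving mean, matching
real-time operation where future samples are unavailable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import CHANNELS, SensorRecord

__all__ = ["CleanReport", "remove_invalid", "smooth", "smooth_records", "baseline_scale"]


@dataclass
class CleanReport:
    """Per-channel accounting for :func:`remove_invalid`.

    Invariant: ``n_input == n_kept + n_removed_out_of_bound + n_removed_missing``.
    """

    channel: str
    n_input: int = 0
    n_kept: int = 0
    n_removed_out_of_bound: int = 0
    n_removed_missing: int = 0
    removed_timestamps: list[float] = field(default_factory=list)


def _is_missing(value) -> bool:
    if isinstance(value, tuple):
        return any(v is None or not math.isfinite(v) for v in value)
    return value is None or not math.isfinite(value)


def _out_of_bound(value, lo: float, hi: float) -> bool:
    comps = value if isinstance(value, tuple) else (value,)
    return any(not (lo <= v <= hi) for v in comps)


def remove_invalid(
    records: Sequence[SensorRecord],
    ranges: dict[str, tuple[float, float]],
) -> tuple[list[SensorRecord], dict[str, CleanReport]]:
    """Drop missing and out-of-bound samples; keep order; account exactly.

    Ranges are closed intervals — a value exactly at a range limit is a
    legitimate saturated reading and is kept.  Every channel present in the
    stream must have a declared range (vector channels are checked
    per-component).  Returns the surviving records, in the original order,
    plus one :class:`CleanReport` per channel seen.
    """
    present = {r.channel for r in records}
    undeclared = present - set(ranges)
    if undeclared:
        raise KeyError(f"no valid range declared for channel(s): {sorted(undeclared)}")

    reports = {ch: CleanReport(channel=ch) for ch in sorted(present)}
    kept: list[SensorRecord] = []
    for rec in records:
        rep = reports[rec.channel]
        rep.n_input += 1
        lo, hi = ranges[rec.channel]
        if _is_missing(rec.value):
            rep.n_removed_missing += 1
            rep.removed_timestamps.append(rec.t)
        elif _out_of_bound(rec.value, lo, hi):
            rep.n_removed_out_of_bound += 1
            rep.removed_timestamps.append(rec.t)
        else:
            rep.n_kept += 1
            kept.append(rec)
    return kept, reports


def smooth(
    t: np.ndarray, values: np.ndarray, window_s: float = 6.0
) -> np.ndarray:
    """Trailing moving-window mean over an irregularly sampled series.

    Each output value is the arithmetic mean of all input samples whose
    timestamps fall in the half-open trailing window ``(t_i - window_s, t_i]``
    — at minimum the sample itself.  The operation is causal: when several
    samples share a timestamp, sample i averages only those up to and
    including position i.  Timestamps are unchanged.  ``t`` must be sorted
    ascending.
    """
    if window_s <= 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape[0] != values.shape[0]:
        raise ValueError("t and values must be 1-D and the same length")
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be sorted ascending")
    if t.size == 0:
        return values.copy()
    # cumulative-sum trick: window (t_i - w, t_i] spans indices [left_i, i]
    left = np.searchsorted(t, t - window_s, side="right")
    idx = np.arange(t.size)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    counts = idx - left + 1
    return (csum[idx + 1] - csum[left]) / counts


def smooth_records(
    records: Sequence[SensorRecord], window_s: float = 6.0
) -> list[SensorRecord]:
    """Apply :func:`smooth` to a time-sorted scalar-channel record stream."""
    if any(r.channel in CHANNELS and isinstance(r.value, tuple) for r in records):
        raise ValueError("smooth_records handles scalar channels only")
    t = np.array([r.t for r in records])
    v = np.array([r.value for r in records])
    sm = smooth(t, v, window_s)
    return [
        SensorRecord(r.subject_id, r.channel, r.t, float(s))
        for r, s in zip(records, sm)
    ]


def baseline_scale(values: np.ndarray, baseline: float, gain: float = 1.0) -> np.ndarray:
    """Amplify deviations from a baseline: ``v -> baseline + gain*(v - baseline)``.

    ``gain=1`` is the identity (the default: sensitivity scaling off);
    the baseline itself is a fixed point for any gain.
    """
    if not math.isfinite(baseline):
        raise ValueError("baseline must be finite")
    if gain < 0:
        raise ValueError(f"gain must be >= 0, got {gain}")
    values = np.asarray(values, dtype=float)
    return baseline + gain * (values - baseline)
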