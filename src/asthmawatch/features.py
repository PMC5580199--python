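"""Per-window feature engineering for risk classification.

Each classification window (60 s trailing by default) is summarized by 16
features:

* ``percent_fev1``, ``percent_pef`` — spirometry as percent of the subject's
  personal best, i.e. 100 * current / mean(three resting baseline
  measurements); spirometry is episodic, so the most recent measurement is
  carried forward up to a staleness horizon.
* ``dust_density``, ``particulate_matter``, ``temperature``, ``humidity`` —
  trailing-window means of the (calibrated, smoothed) environmental channels.
* ``heart_rate_reserve`` — the fraction of the subject's heart rate reserve
  in use: (HR_mean - HRrest) / HRR with HRR = HRmax - HRrest and
  HRmax = 208 - 0.7 * age (an age-predicted maximum that holds down to
  childhood).  The per-subject HRR constant itself is exposed separately.
* ``total_energy_expenditure`` — mean composite-acceleration statistic Km
  over the window's complete 5-s accelerometer sub-windows.  Km is the
  summed per-axis sample variance
  ``Km = (1/(n-1)) * (Q - P/n)``, ``Q = sum(x^2)+sum(y^2)+sum(z^2)``,
  ``P = (sum x)^2 + (sum y)^2 + (sum z)^2``,
  a cheap accelerometer proxy for energy expenditure.
* eight "online source" features (ozone ... AQI) copied from the replayed
  fixture row joined to the window end.

Missing features are carried as NaN and flagged, never zero-filled; the
model imputes them from training-set medians at prediction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import ONLINE_FEATURES, OnlineFeatureRow, SubjectProfile

__all__ = [
    "FEATURE_ORDER",
    "AccelWindow",
    "FeatureVector",
    "composite_accel_km",
    "energy_expenditure",
    "hr_max",
    "hr_reserve",
    "heart_rate_reserve_fraction",
    "percent_of_baseline",
    "build_feature_vector",
]

#: The 16 model features, in the fixed order used for model I/O.
FEATURE_ORDER: tuple[str, ...] = (
    "percent_fev1",
    "percent_pef",
    "dust_density",
    "particulate_matter",
    "temperature",
    "humidity",
    "heart_rate_reserve",
    "total_energy_expenditure",
    "ozone",
    "pressure",
    "cloud_cover",
    "wind_speed",
    "precip_probability",
    "precip_intensity",
    "traffic_density",
    "aqi",
)

#: Accelerometer sub-window length for Km, seconds.
ACCEL_SUBWINDOW_S = 5.0

#: Fraction-of-HRR clip range; transient optical-HR overshoots above HRmax
#: are capped rather than discarded.
HRR_FRACTION_CLIP = (0.0, 1.5)


@dataclass(frozen=True)
class AccelWindow:
    """Tri-axial accelerometer samples over one short (<= 5 s) sub-window."""

    samples: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if arr.shape[0] < 2:
            raise ValueError("Km needs at least two samples (divides by n-1)")
        object.__setattr__(self, "samples", arr)

    @property
    def n(self) -> int:
        return self.samples.shape[0]


def composite_accel_km(window: AccelWindow | np.ndarray, as_printed: bool = False) -> float:
    """Composite acceleration statistic Km for one accelerometer sub-window.

    ``Km = (Q - P/n) / (n - 1)`` with Q the total sum of squares and P the
    sum of squared per-axis sums — algebraically the sum over axes of the
    sample variance (ddof=1).  Km is therefore non-negative, invariant to
    constant offsets per axis (gravity drops out), and scales as k^2 when
    deviations are scaled by k.

    ``as_printed=True`` keeps an audit variant in which P duplicates Q
    (a typographic artifact), degenerating to Q/n.
    """
    if not isinstance(window, AccelWindow):
        window = AccelWindow(np.asarray(window))
    a = window.samples
    n = window.n
    q = float(np.sum(a * a))
    if as_printed:
        p = q
    else:
        sums = a.sum(axis=0)
        p = float(np.sum(sums * sums))
    return (q - p / n) / (n - 1)


def energy_expenditure(
    t: np.ndarray,
    accel: np.ndarray,
    window: tuple[float, float],
    subwindow_s: float = ACCEL_SUBWINDOW_S,
    aggregate: str = "mean",
) -> float:
    """Window-level energy-expenditure proxy from an accelerometer stream.

    The classification window ``[start, end)`` is tiled with consecutive
    ``subwindow_s`` sub-windows from its start; Km is computed for every
    complete sub-window holding >= 2 samples and aggregated (mean by
    default, ``aggregate="sum"`` available).  Returns NaN when no sub-window
    qualifies (missing-feature flag, not an error).
    """
    if aggregate not in ("mean", "sum"):
        raise ValueError(f"aggregate must be 'mean' or 'sum', got {aggregate!r}")
    start, end = window
    if not end > start:
        raise ValueError("window end must exceed start")
    t = np.asarray(t, dtype=float)
    accel = np.asarray(accel, dtype=float)
    kms: list[float] = []
    n_sub = int(math.floor((end - start) / subwindow_s))
    for i in range(n_sub):
        lo = start + i * subwindow_s
        hi = lo + subwindow_s
        mask = (t >= lo) & (t < hi)
        if int(mask.sum()) >= 2:
            kms.append(composite_accel_km(accel[mask]))
    if not kms:
        return float("nan")
    return float(np.sum(kms)) if aggregate == "sum" else float(np.mean(kms))


def hr_max(age: float) -> float:
    """Age-predicted maximum heart rate, bpm: ``208 - 0.7 * age``."""
    return 208.0 - 0.7 * age


def hr_reserve(profile: SubjectProfile) -> float:
    """Heart rate reserve HRR = HRmax - HRrest (bpm), a per-subject constant."""
    hrr = hr_max(profile.age) - profile.hr_rest
    if hrr <= 0:
        raise ValueError(
            f"non-positive heart rate reserve ({hrr:.1f} bpm): "
            "resting HR exceeds age-predicted maximum"
        )
    return hrr


def heart_rate_reserve_fraction(profile: SubjectProfile, hr_window_mean: float) -> float:
    """Fraction of HRR in use for a window: (HR - HRrest) / HRR, clipped.

    The raw HRR is constant per subject and carries no within-subject signal;
    the fraction of it in use is the discriminative per-window feature.
    """
    hrr = hr_reserve(profile)
    frac = (hr_window_mean - profile.hr_rest) / hrr
    lo, hi = HRR_FRACTION_CLIP
    return float(min(max(frac, lo), hi))


def percent_of_baseline(current: float, baseline_triplet: Sequence[float]) -> float:
    """Spirometry value as percent of the mean of three baseline measurements."""
    if len(baseline_triplet) != 3:
        raise ValueError("baseline triplet must have exactly three values")
    mean = float(np.mean(baseline_triplet))
    if mean <= 0:
        raise ValueError(f"baseline mean must be positive, got {mean}")
    return 100.0 * current / mean


@dataclass(frozen=True)
class FeatureVector:
    """The 16 features for one classification window.

    ``features`` maps every name in :data:`FEATURE_ORDER` to a float (NaN
    when missing); ``missing`` lists the names flagged missing.
    """

    window_start: float
    window_end: float
    features: dict[str, float]
    missing: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if set(self.features) != set(FEATURE_ORDER):
            extra = set(self.features) - set(FEATURE_ORDER)
            lacking = set(FEATURE_ORDER) - set(self.features)
            raise ValueError(
                f"feature names mismatch (extra={sorted(extra)}, missing={sorted(lacking)})"
            )
        ordered = {name: float(self.features[name]) for name in FEATURE_ORDER}
        miss = frozenset(
            name for name in FEATURE_ORDER
            if name in self.missing or math.isnan(ordered[name])
        )
        for name, v in ordered.items():
            if not math.isfinite(v) and not math.isnan(v):
                raise ValueError(f"feature {name} must be finite or NaN, got {v}")
        object.__setattr__(self, "features", ordered)
        object.__setattr__(self, "missing", miss)

    def as_array(self) -> np.ndarray:
        """Values in :data:`FEATURE_ORDER` order (NaN for missing)."""
        return np.array([self.features[name] for name in FEATURE_ORDER])

    def as_row(self) -> dict[str, float]:
        row = {"window_start": self.window_start, "window_end": self.window_end}
        row.update(self.features)
        return row


def _window_mean(series, start: float, end: float) -> float:
    """Mean of a (t, value) series over [start, end); NaN when empty."""
    if series is None:
        return float("nan")
    t, v = series
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    mask = (t >= start) & (t < end)
    if not mask.any():
        return float("nan")
    return float(np.mean(v[mask]))


def _locf(series, at: float, horizon_s: float) -> float:
    """Most recent value at-or-before ``at`` within ``horizon_s``; else NaN."""
    if series is None:
        return float("nan")
    t, v = series
    t = np.asarray(t, dtype=float)
    idx = int(np.searchsorted(t, at, side="right")) - 1
    if idx < 0 or at - t[idx] > horizon_s:
        return float("nan")
    return float(np.asarray(v, dtype=float)[idx])


def build_feature_vector(
    streams: Mapping[str, tuple[np.ndarray, np.ndarray]],
    profile: SubjectProfile,
    online_row: OnlineFeatureRow | None,
    window: tuple[float, float],
    spiro_staleness_s: float = 24 * 3600.0,
    ee_aggregate: str = "mean",
) -> FeatureVector:
    """Assemble one window's :class:`FeatureVector` from prepared streams.

    ``streams`` maps channel names to ``(t, values)`` arrays; expected keys
    are ``dust_density``, ``pm25``, ``temperature``, ``humidity``,
    ``heart_rate``, ``pef``, ``fev1`` (all scalar series, already cleaned,
    calibrated and smoothed) and ``accel`` as ``(t, (n,3) array)``.  Absent
    keys yield missing (NaN) features.  Environmental channels and heart
    rate are summarized by the window mean; spirometry by LOCF at the window
    end within the staleness horizon; online features are copied from the
    joined fixture row.
    """
    start, end = window
    if not end > start:
        raise ValueError("window end must exceed start")
    if not streams:
        raise ValueError("no sensor streams supplied for the window")

    feats: dict[str, float] = {}
    feats["dust_density"] = _window_mean(streams.get("dust_density"), start, end)
    feats["particulate_matter"] = _window_mean(streams.get("pm25"), start, end)
    feats["temperature"] = _window_mean(streams.get("temperature"), start, end)
    feats["humidity"] = _window_mean(streams.get("humidity"), start, end)

    hr_mean = _window_mean(streams.get("heart_rate"), start, end)
    feats["heart_rate_reserve"] = (
        heart_rate_reserve_fraction(profile, hr_mean)
        if not math.isnan(hr_mean)
        else float("nan")
    )

    accel = streams.get("accel")
    if accel is not None:
        feats["total_energy_expenditure"] = energy_expenditure(
            accel[0], accel[1], window, aggregate=ee_aggregate
        )
    else:
        feats["total_energy_expenditure"] = float("nan")

    pef = _locf(streams.get("pef"), end, spiro_staleness_s)
    fev1 = _locf(streams.get("fev1"), end, spiro_staleness_s)
    feats["percent_pef"] = (
        percent_of_baseline(pef, profile.baseline_pef) if not math.isnan(pef) else float("nan")
    )
    feats["percent_fev1"] = (
        percent_of_baseline(fev1, profile.baseline_fev1)
        if not math.isnan(fev1)
        else float("nan")
    )

    for name in ONLINE_FEATURES:
        feats[name] = getattr(online_row, name) if online_row is not None else float("nan")

    return FeatureVector(window_start=start, window_end=end, features=feats)


FEATURE_CSV_HEADER = ("window_start", "window_end", *FEATURE_ORDER)


def write_feature_table(vectors: Sequence[FeatureVector], path) -> None:
    """Serialize feature vectors as CSV with the fixed 18-column header."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FEATURE_CSV_HEADER)
        for fv in vectors:
            row = fv.as_row()
            writer.writerow([repr(row[name]) for name in FEATURE_CSV_HEADER])


def read_feature_table(path) -> list[FeatureVector]:
    import csv
    from pathlib import Path

    out: list[FeatureVector] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != FEATURE_CSV_HEADER:
            raise ValueError("feature CSV header does not match the declared order")
        for row in reader:
            out.append(
                FeatureVector(
                    window_start=float(row["window_start"]),
                    window_end=float(row["window_end"]),
                    features={name: float(row[name]) for name in FEATURE_ORDER},
                )
            )
    return out
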