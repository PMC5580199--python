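"""End-to-end wiring: raw record streams -> cleaned/calibrated series ->
windowed feature vectors -> labeled training table or windowed predictions.

Stages, in order:

1. range/sentinel cleaning against the subject profile's per-channel valid
   ranges (exact removal accounting);
2. dust calibration: each raw-voltage sample is paired with the most recent
   temperature and humidity readings (falling back to the calibration
   reference conditions when none precede it) and mapped through the
   piecewise calibration, then clamped to non-negative density;
3. 6-s trailing-mean smoothing of the environmental channels (dust density,
   PM2.5, temperature, humidity);
4. 60-s trailing classification windows (hop 60 s), each summarized into the
   16-feature vector, with online-source rows joined by LOCF at window ends;
5. optional label alignment from hourly ACT observations (windows without a
   nearby observation are dropped from training, never from prediction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCoefficients, DEFAULT_COEFFICIENTS, clamp_nonnegative, dust_density
from .features import FEATURE_ORDER, FeatureVector, build_feature_vector
from .labels import ACTObservation, RiskLevel, align_labels
from .model import ModelBundle, predict
from .preprocess import CleanReport, remove_invalid, smooth
from .records import (
    MissingOnlineDataError,
    OnlineFeatureRow,
    SensorRecord,
    SubjectProfile,
    join_online_features,
)

__all__ = ["PipelineConfig", "WindowedDataset", "prepare_streams", "make_windows",
           "build_dataset", "predict_stream"]

#: Environmental channels smoothed before windowing.
SMOOTHED_CHANNELS = ("dust_density", "pm25", "temperature", "humidity")


@dataclass(frozen=True)
class PipelineConfig:
    """Window geometry and preprocessing knobs."""

    window_s: float = 60.0
    hop_s: float = 60.0
    smoothing_window_s: float = 6.0
    spiro_staleness_s: float = 24 * 3600.0
    coeffs: CalibrationCoefficients = DEFAULT_COEFFICIENTS

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.hop_s <= 0:
            raise ValueError("window_s and hop_s must be positive")


@dataclass
class WindowedDataset:
    """Windowed feature table, optionally labeled."""

    vectors: list[FeatureVector]
    windows: list[tuple[float, float]]
    labels: list[Optional[RiskLevel]]
    clean_reports: dict[str, CleanReport] = field(default_factory=dict)
    n_clamped_dust: int = 0

    @property
    def frame(self) -> pd.DataFrame:
        """18-column table: window bounds plus the 16 features."""
        return pd.DataFrame([fv.as_row() for fv in self.vectors])

    def labeled(self) -> tuple[pd.DataFrame, list[RiskLevel]]:
        """Feature matrix and labels restricted to labeled windows."""
        keep = [i for i, lbl in enumerate(self.labels) if lbl is not None]
        X = self.frame.iloc[keep][list(FEATURE_ORDER)].reset_index(drop=True)
        y = [self.labels[i] for i in keep]
        return X, y


def _series(records: Sequence[SensorRecord], channel: str):
    recs = [r for r in records if r.channel == channel]
    if not recs:
        return None
    t = np.array([r.t for r in recs])
    v = np.array([r.value for r in recs])
    return t, v


def _locf_lookup(t_query: np.ndarray, series, fallback: float) -> np.ndarray:
    if series is None:
        return np.full(t_query.shape, fallback)
    t, v = series
    idx = np.searchsorted(t, t_query, side="right") - 1
    out = np.where(idx >= 0, v[np.maximum(idx, 0)], fallback)
    return out


def prepare_streams(
    records: Sequence[SensorRecord],
    profile: SubjectProfile,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[dict, dict[str, CleanReport], int]:
    """Clean, calibrate and smooth raw records into per-channel series.

    Returns ``(streams, clean_reports, n_clamped_dust)`` where ``streams``
    maps channel names (including the derived ``dust_density``) to
    ``(t, values)`` arrays ready for :func:`~asthmawatch.features.build_feature_vector`.
    """
    kept, reports = remove_invalid(records, profile.channel_ranges)

    streams: dict = {}
    for ch in ("pm25", "temperature", "humidity", "heart_rate", "pef", "fev1"):
        s = _series(kept, ch)
        if s is not None:
            streams[ch] = s

    accel = [r for r in kept if r.channel == "accel"]
    if accel:
        streams["accel"] = (
            np.array([r.t for r in accel]),
            np.array([r.value for r in accel]),
        )

    n_clamped = 0
    dust = _series(kept, "dust_raw")
    if dust is not None:
        t_dust, x = dust
        temp = _locf_lookup(t_dust, streams.get("temperature"), config.coeffs.ref_temperature)
        hum = _locf_lookup(t_dust, streams.get("humidity"), config.coeffs.ref_humidity)
        rho = np.empty_like(x)
        for i in range(x.size):
            r, clamped = clamp_nonnegative(
                dust_density(float(x[i]), float(temp[i]), float(hum[i]), config.coeffs)
            )
            rho[i] = r
            n_clamped += clamped
        streams["dust_density"] = (t_dust, rho)

    for ch in SMOOTHED_CHANNELS:
        if ch in streams:
            t, v = streams[ch]
            streams[ch] = (t, smooth(t, v, config.smoothing_window_s))

    return streams, reports, n_clamped


def make_windows(t_start: float, t_end: float, config: PipelineConfig) -> list[tuple[float, float]]:
    """Consecutive half-open windows covering [t_start, t_end]."""
    windows = []
    s = t_start
    while s + config.window_s <= t_end + 1e-9:
        windows.append((s, s + config.window_s))
        s += config.hop_s
    return windows


def build_dataset(
    records: Sequence[SensorRecord],
    profile: SubjectProfile,
    online_table: Sequence[OnlineFeatureRow],
    acts: Sequence[ACTObservation] | None = None,
    config: PipelineConfig = PipelineConfig(),
    windows: Sequence[tuple[float, float]] | None = None,
) -> WindowedDataset:
    """Run the full preprocessing + feature pipeline over a record stream.

    ``windows`` defaults to consecutive ``window_s`` windows spanning the
    stream.  When ``acts`` is given, windows are labeled by nearest-ACT
    alignment (None where no observation lies within the horizon).
    """
    if not records:
        raise ValueError("empty record stream")
    streams, reports, n_clamped = prepare_streams(records, profile, config)
    if not streams:
        raise ValueError("no usable channels after cleaning")
    if windows is None:
        t_min = min(r.t for r in records)
        t_max = max(r.t for r in records)
        windows = make_windows(t_min, t_max, config)
    windows = list(windows)
    if not windows:
        raise ValueError("stream shorter than one classification window")

    online_rows = join_online_features([w[1] for w in windows], online_table)
    vectors = [
        build_feature_vector(
            streams,
            profile,
            row,
            win,
            spiro_staleness_s=config.spiro_staleness_s,
        )
        for win, row in zip(windows, online_rows)
    ]
    labels: list[Optional[RiskLevel]]
    if acts is not None:
        labels = align_labels(windows, acts)
    else:
        labels = [None] * len(windows)
    return WindowedDataset(
        vectors=vectors,
        windows=windows,
        labels=labels,
        clean_reports=reports,
        n_clamped_dust=n_clamped,
    )


def predict_stream(
    bundle: ModelBundle,
    records: Sequence[SensorRecord],
    profile: SubjectProfile,
    online_table: Sequence[OnlineFeatureRow],
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Windowed real-time-style prediction over a recorded stream.

    Returns a DataFrame with columns ``t_start, t_end, label, p_low, p_medium,
    p_high``.
    """
    ds = build_dataset(records, profile, online_table, acts=None, config=config)
    rows = []
    for fv in ds.vectors:
        label, probs = predict(bundle, fv)
        rows.append(
            {
                "t_start": fv.window_start,
                "t_end": fv.window_end,
                "label": label.value,
                "p_low": probs["low"],
                "p_medium": probs["medium"],
                "p_high": probs["high"],
            }
        )
    return pd.DataFrame(rows)
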