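"""Synthetic multi-sensor streams with scripted exacerbation episodes.

The generator emits everything the pipeline consumes — sensor records,
an online-feature fixture table, hourly ACT observations, and per-window
ground-truth risk — with the statistical structure the classifier assumes:

* **quiet** periods: every channel at its baseline plus Gaussian noise;
* **smoke** episodes: dust voltage and PM2.5 scaled up by a multiplier and
  spirometry (PEF, FEV1) depressed by a percent drop, with a modest heart
  rate rise — the smoky-kitchen exacerbation;
* **exercise** episodes: accelerometer variance scaled up and heart rate
  driven toward rest + intensity * HRR — the running exacerbation;
* sensor **dropout**: samples replaced by an out-of-range sentinel value, to
  exercise range-based cleaning.

Episode severity maps to ground truth through the same bins the ACT labels
use: quiet hours draw ACT scores 20-25 (low risk), mild episodes
(intensity < 1) draw 15-19 (medium), severe episodes (intensity >= 1) draw
5-14 (high).  ACT is administered at each mid-hour so hourly labels align
cleanly with the +/-30 min label horizon.

Everything is driven by one integer seed; identical seeds give identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .features import hr_reserve
from .labels import ACTObservation, RiskLevel, write_act_table
from .records import (
    OnlineFeatureRow,
    SensorRecord,
    SubjectProfile,
    write_online_table,
    write_stream,
)

__all__ = [
    "EpisodeScript",
    "GeneratorConfig",
    "SyntheticDataset",
    "default_profile",
    "default_mixed_script",
    "generate",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class EpisodeScript:
    """One scripted episode: ``kind`` in {smoke, exercise, quiet}, half-open
    time span, and a non-negative intensity (1.0 = the configured full
    effect; >= 1 counts as severe)."""

    kind: str
    start: float
    end: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("smoke", "exercise", "quiet"):
            raise ValueError(f"unknown episode kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError("episode start must precede end")
        if self.intensity < 0:
            raise ValueError("episode intensity must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling rates, baselines, noise levels and episode effect sizes.

    Defaults are the package's canonical study conditions: a wearable-like
    rate mix (accelerometer 20 Hz, heart rate 1 Hz, dust/PM 0.2 Hz,
    temperature/humidity 0.1 Hz, spirometry every minute as in the
    validation protocol, online rows every 15 min, ACT hourly), noise
    levels giving clearly non-trivial but learnable class overlap, a 5x
    particulate elevation and 30 % spirometry depression under
    full-intensity smoke, and a 10x accelerometer-variance rise under
    full-intensity exercise.  Per-sample noise is independent across
    classification windows so that zeroing the effect sizes leaves no
    feature-label association.
    """

    duration_s: float = 3600.0
    t0: float = 0.0
    seed: int = 0

    # sample rates (Hz) and cadences (s)
    accel_hz: float = 20.0
    hr_hz: float = 1.0
    dust_hz: float = 0.2
    pm_hz: float = 0.2
    env_hz: float = 0.1
    spiro_period_s: float = 60.0
    online_period_s: float = 900.0
    act_period_s: float = 3600.0

    # quiet baselines (channel units)
    dust_raw_baseline: float = 300.0
    pm25_baseline: float = 10.0
    temperature_baseline: float = 25.0
    humidity_baseline: float = 40.0

    # per-channel Gaussian noise SDs
    dust_raw_sd: float = 15.0
    pm25_sd: float = 2.0
    temperature_sd: float = 0.3
    humidity_sd: float = 1.0
    heart_rate_sd: float = 2.0
    accel_sd: float = 0.05
    spiro_frac_sd: float = 0.03

    # episode effect sizes (full intensity = 1.0)
    smoke_dust_multiplier: float = 5.0
    smoke_pm_multiplier: float = 5.0
    smoke_spiro_drop_frac: float = 0.30
    smoke_hr_rise_bpm: float = 10.0
    exercise_spiro_drop_frac: float = 0.10
    exercise_hr_fraction: float = 1.0
    accel_variance_multiplier: float = 10.0

    # dropout
    dropout_probability: float = 0.01
    sentinel: float = 65535.0

    severe_intensity_threshold: float = 1.0

    def __post_init__(self) -> None:
        for name in ("accel_hz", "hr_hz", "dust_hz", "pm_hz", "env_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.dropout_probability <= 1:
            raise ValueError("dropout_probability must be in [0, 1]")
        for name in (
            "smoke_dust_multiplier",
            "smoke_pm_multiplier",
            "smoke_spiro_drop_frac",
            "smoke_hr_rise_bpm",
            "exercise_spiro_drop_frac",
            "exercise_hr_fraction",
            "accel_variance_multiplier",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def zeroed_effects(self) -> "GeneratorConfig":
        """Copy with every episode effect nulled (multipliers 1, shifts 0):
        features become statistically independent of the scripted labels."""
        return replace(
            self,
            smoke_dust_multiplier=1.0,
            smoke_pm_multiplier=1.0,
            smoke_spiro_drop_frac=0.0,
            smoke_hr_rise_bpm=0.0,
            exercise_spiro_drop_frac=0.0,
            exercise_hr_fraction=0.0,
            accel_variance_multiplier=1.0,
        )


DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "dust_raw": (0.0, 4000.0),
    "pm25": (0.0, 500.0),
    "temperature": (-20.0, 60.0),
    "humidity": (0.0, 100.0),
    "pef": (60.0, 800.0),
    "fev1": (0.5, 8.0),
    "heart_rate": (30.0, 220.0),
    "accel": (-50.0, 50.0),
    "gyro": (-50.0, 50.0),
    "location": (-180.0, 180.0),
}


def default_profile(subject_id: str = "synthetic-adult") -> SubjectProfile:
    """Synthetic adult profile mirroring the feasibility-study subject:
    age 29, resting HR 60 bpm, resting PEF around 320 L/min."""
    return SubjectProfile(
        subject_id=subject_id,
        age=29.0,
        hr_rest=60.0,
        baseline_pef=(310.0, 320.0, 330.0),
        baseline_fev1=(2.9, 3.0, 3.1),
        channel_ranges=dict(DEFAULT_RANGES),
    )


def default_mixed_script(t0: float = 0.0) -> tuple[GeneratorConfig, list[EpisodeScript]]:
    """The canonical 6-hour mixed scenario: hour-long quiet, mild exercise
    and severe smoke episodes, twice each, so all three risk levels appear
    in balanced proportion."""
    config = GeneratorConfig(duration_s=6 * 3600.0, t0=t0)
    h = 3600.0
    script = [
        EpisodeScript("exercise", t0 + 1 * h, t0 + 2 * h, intensity=0.6),
        EpisodeScript("smoke", t0 + 2 * h, t0 + 3 * h, intensity=1.0),
        EpisodeScript("exercise", t0 + 4 * h, t0 + 5 * h, intensity=0.6),
        EpisodeScript("smoke", t0 + 5 * h, t0 + 6 * h, intensity=1.0),
    ]
    return config, script


@dataclass
class SyntheticDataset:
    """Everything one generator run produces."""

    records: list[SensorRecord]
    online: list[OnlineFeatureRow]
    acts: list[ACTObservation]
    windows: list[tuple[float, float]]
    window_truth: list[RiskLevel]
    profile: SubjectProfile
    config: GeneratorConfig
    script: list[EpisodeScript]


def _validate_script(config: GeneratorConfig, script: Sequence[EpisodeScript]) -> None:
    t_end = config.t0 + config.duration_s
    by_kind: dict[str, list[EpisodeScript]] = {}
    for ep in script:
        if ep.start < config.t0 or ep.end > t_end:
            raise ValueError(
                f"episode [{ep.start}, {ep.end}) exceeds run span [{config.t0}, {t_end})"
            )
        by_kind.setdefault(ep.kind, []).append(ep)
    for kind, eps in by_kind.items():
        eps = sorted(eps, key=lambda e: e.start)
        for a, b in zip(eps, eps[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping {kind!r} episodes at t={b.start}")


def _active_episode(script: Sequence[EpisodeScript], t: float) -> Optional[EpisodeScript]:
    """Most severe non-quiet episode covering t (smoke outranks exercise on
    equal intensity); None when quiet."""
    hits = [ep for ep in script if ep.start <= t < ep.end and ep.kind != "quiet"]
    if not hits:
        return None
    return max(hits, key=lambda ep: (ep.intensity, ep.kind == "smoke"))


def _risk_for(config: GeneratorConfig, ep: Optional[EpisodeScript]) -> RiskLevel:
    if ep is None or ep.intensity == 0:
        return RiskLevel.LOW
    if ep.intensity >= config.severe_intensity_threshold:
        return RiskLevel.HIGH
    return RiskLevel.MEDIUM


_ACT_BINS = {
    RiskLevel.LOW: (20, 25),
    RiskLevel.MEDIUM: (15, 19),
    RiskLevel.HIGH: (5, 14),
}


def _times(t0: float, duration: float, hz: float) -> np.ndarray:
    n = int(math.floor(duration * hz))
    return t0 + np.arange(n) / hz


def _episode_arrays(
    script: Sequence[EpisodeScript], config: GeneratorConfig, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (smoke_intensity, exercise_intensity) arrays."""
    smoke = np.zeros_like(t)
    exercise = np.zeros_like(t)
    for ep in script:
        if ep.kind == "quiet":
            continue
        mask = (t >= ep.start) & (t < ep.end)
        if ep.kind == "smoke":
            smoke[mask] = np.maximum(smoke[mask], ep.intensity)
        else:
            exercise[mask] = np.maximum(exercise[mask], ep.intensity)
    return smoke, exercise


def generate(
    config: GeneratorConfig,
    script: Sequence[EpisodeScript] = (),
    profile: SubjectProfile | None = None,
    window_s: float = 60.0,
) -> SyntheticDataset:
    """Generate one synthetic run.

    Returns sensor records (time-sorted), the online fixture table, hourly
    ACT observations, and per-window ground-truth risk for consecutive
    ``window_s`` windows (labeled by the episode state at the window
    midpoint).  Identical config+script+profile give identical output.
    """
    _validate_script(config, script)
    if profile is None:
        profile = default_profile()
    rng = np.random.default_rng(config.seed)
    hrr = hr_reserve(profile)
    t0, dur = config.t0, config.duration_s
    records: list[SensorRecord] = []
    sid = profile.subject_id

    def add_scalar(channel: str, t: np.ndarray, v: np.ndarray) -> None:
        drop = rng.random(t.size) < config.dropout_probability
        v = np.where(drop, config.sentinel, v)
        records.extend(
            SensorRecord(sid, channel, float(ti), float(vi)) for ti, vi in zip(t, v)
        )

    # dust raw voltage and PM2.5: multiplicative elevation under smoke
    for channel, hz, base, sd, mult in (
        ("dust_raw", config.dust_hz, config.dust_raw_baseline, config.dust_raw_sd,
         config.smoke_dust_multiplier),
        ("pm25", config.pm_hz, config.pm25_baseline, config.pm25_sd,
         config.smoke_pm_multiplier),
    ):
        t = _times(t0, dur, hz)
        smoke, _ = _episode_arrays(script, config, t)
        level = base * (1.0 + (mult - 1.0) * np.minimum(smoke, 1.0))
        add_scalar(channel, t, level + rng.normal(0.0, sd, t.size))

    # ambient temperature / humidity: slow drift around baseline
    for channel, base, sd in (
        ("temperature", config.temperature_baseline, config.temperature_sd),
        ("humidity", config.humidity_baseline, config.humidity_sd),
    ):
        t = _times(t0, dur, config.env_hz)
        add_scalar(channel, t, base + rng.normal(0.0, sd, t.size))

    # heart rate: exercise drives toward rest + intensity * HRR;
    # smoke adds a mild bpm rise
    t = _times(t0, dur, config.hr_hz)
    smoke, exercise = _episode_arrays(script, config, t)
    hr = (
        profile.hr_rest
        + config.exercise_hr_fraction * np.minimum(exercise, 1.0) * hrr
        + config.smoke_hr_rise_bpm * np.minimum(smoke, 1.0)
        + rng.normal(0.0, config.heart_rate_sd, t.size)
    )
    add_scalar("heart_rate", t, hr)

    # tri-axial acceleration about gravity; exercise scales the variance
    t = _times(t0, dur, config.accel_hz)
    _, exercise = _episode_arrays(script, config, t)
    var_scale = 1.0 + (config.accel_variance_multiplier - 1.0) * np.minimum(exercise, 1.0)
    sd = config.accel_sd * np.sqrt(var_scale)
    xyz = rng.normal(0.0, 1.0, (t.size, 3)) * sd[:, None]
    xyz[:, 2] += 9.81
    drop = rng.random(t.size) < config.dropout_probability
    for ti, row, d in zip(t, xyz, drop):
        value = (config.sentinel,) * 3 if d else tuple(float(v) for v in row)
        records.append(SensorRecord(sid, "accel", float(ti), value))

    # episodic spirometry, depressed by the active episode
    t = np.arange(t0, t0 + dur, config.spiro_period_s, dtype=float)
    smoke, exercise = _episode_arrays(script, config, t)
    drop_frac = (
        config.smoke_spiro_drop_frac * np.minimum(smoke, 1.0)
        + config.exercise_spiro_drop_frac * np.minimum(exercise, 1.0)
    )
    drop_frac = np.minimum(drop_frac, 0.9)
    pef_base = float(np.mean(profile.baseline_pef))
    fev1_base = float(np.mean(profile.baseline_fev1))
    pef = pef_base * (1.0 - drop_frac) * (1.0 + rng.normal(0.0, config.spiro_frac_sd, t.size))
    fev1 = fev1_base * (1.0 - drop_frac) * (1.0 + rng.normal(0.0, config.spiro_frac_sd, t.size))
    add_scalar("pef", t, pef)
    add_scalar("fev1", t, fev1)

    records.sort(key=lambda r: r.t)

    # Online fixture rows: outdoor sources on a calm steady day, constant at
    # their baselines.  Rows are shared by every window in a 15-min block, so
    # any per-row noise would act as a covert block identifier correlated
    # with the hourly labels; constants keep these features honestly
    # uninformative about indoor episodes.
    t_online = np.arange(t0, t0 + dur + config.online_period_s, config.online_period_s)
    online = [
        OnlineFeatureRow(
            t=float(ti),
            ozone=30.0,
            pressure=1013.0,
            cloud_cover=0.3,
            wind_speed=3.0,
            precip_probability=0.1,
            precip_intensity=0.0,
            traffic_density=50.0,
            aqi=40.0,
        )
        for ti in t_online
    ]

    # ACT at each mid-period, scored from the episode state at that moment
    acts: list[ACTObservation] = []
    t_act = t0 + config.act_period_s / 2.0
    while t_act < t0 + dur:
        risk = _risk_for(config, _active_episode(script, t_act))
        lo, hi = _ACT_BINS[risk]
        acts.append(ACTObservation(t=float(t_act), score=int(rng.integers(lo, hi + 1))))
        t_act += config.act_period_s

    # ground truth per consecutive window, from the state at the midpoint
    windows: list[tuple[float, float]] = []
    truth: list[RiskLevel] = []
    s = t0
    while s + window_s <= t0 + dur:
        windows.append((s, s + window_s))
        truth.append(_risk_for(config, _active_episode(script, s + window_s / 2.0)))
        s += window_s

    return SyntheticDataset(
        records=records,
        online=online,
        acts=acts,
        windows=windows,
        window_truth=truth,
        profile=profile,
        config=config,
        script=list(script),
    )


#: Canonical fixture scenarios: name -> (config, script builder).  Fixtures
#: run the accelerometer at a reduced 5 Hz to keep files small; seeds are
#: embedded so regeneration is bit-identical.
def _fixture_scenarios() -> dict[str, tuple[GeneratorConfig, list[EpisodeScript]]]:
    quiet = GeneratorConfig(duration_s=2 * 3600.0, seed=11, accel_hz=5.0)
    smoky = GeneratorConfig(duration_s=3600.0, seed=12, accel_hz=5.0)
    exercise = GeneratorConfig(duration_s=3600.0, seed=13, accel_hz=5.0)
    mixed_cfg, mixed_script = default_mixed_script()
    mixed_cfg = replace(mixed_cfg, seed=14, accel_hz=5.0)
    return {
        "quiet_day": (quiet, []),
        "smoky_hour": (smoky, [EpisodeScript("smoke", 600.0, 3000.0, intensity=1.0)]),
        "exercise_hour": (
            exercise,
            [EpisodeScript("exercise", 600.0, 3000.0, intensity=0.6)],
        ),
        "mixed_week": (mixed_cfg, mixed_script),
    }


def make_fixture_suite(out_dir: str | Path) -> dict[str, dict[str, Path]]:
    """Write the canonical fixture files used by the test suite.

    For each scenario writes ``<name>_records.jsonl``, ``<name>_online.csv``,
    ``<name>_acts.csv`` and ``<name>_truth.csv`` (window bounds + true risk).
    Running twice produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, dict[str, Path]] = {}
    for name, (config, script) in _fixture_scenarios().items():
        ds = generate(config, script)
        p = {
            "records": out / f"{name}_records.jsonl",
            "online": out / f"{name}_online.csv",
            "acts": out / f"{name}_acts.csv",
            "truth": out / f"{name}_truth.csv",
        }
        write_stream(ds.records, p["records"], format="jsonl")
        write_online_table(ds.online, p["online"])
        write_act_table(ds.acts, p["acts"])
        with p["truth"].open("w") as fh:
            fh.write("window_start,window_end,label\n")
            for (ws, we), lbl in zip(ds.windows, ds.window_truth):
                fh.write(f"{ws!r},{we!r},{lbl.value}\n")
        paths[name] = p
    return paths
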