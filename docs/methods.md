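# Methods

`asthmawatch` re-creates, at desk scale, the analytics core of a
smartwatch-based asthma-risk platform: multi-sensor ingestion, dust-sensor
calibration, signal cleaning, physiological/environmental feature
engineering, risk labeling from the Asthma Control Test (ACT), and a
cross-validated three-class random-forest risk classifier — plus a
synthetic stream generator and a hybrid AES/RSA record envelope so that the
whole pipeline runs and is testable without hardware, cloud services or
subject data.

## Data model

A stream is a time-sorted sequence of `SensorRecord`s: subject id, channel,
UTC epoch-second timestamp, and a scalar value (or a 3-vector for
`accel`/`gyro`, a lat/lon pair for `location`). Windows are half-open
`[start, end)` so a sample at a boundary is counted exactly once. A
`SubjectProfile` carries age, resting heart rate, the three resting
spirometry baselines, and per-channel valid ranges. "Online source"
features (ozone, pressure, cloud cover, wind, precipitation, traffic, AQI)
are replayed from a fixture table and joined to windows by last observation
carried forward (LOCF); live API access is explicitly out of scope, as is
nearest-location matching (one fixture table per run). The gyroscope
channel is accepted on ingest but unused: it does not appear in the
feature set.

## Dust calibration

The optical dust sensor's raw voltage `x` maps to dust density through a
five-case piecewise formula selected by the signs of the humidity and
temperature changes ΔH, ΔT relative to bench-calibration conditions:

| ΔH | ΔT | ρc |
|----|----|----|
| 0  | 0  | 5.4·10⁻⁴·x − 0.15 |
| >0 | >0 | αH·H + βH − (αT1·T + βT1) |
| >0 | <0 | αH·H + βH − (αT2·T + βT2) |
| <0 | >0 | 5.4·10⁻⁴·x − 0.15 − (αT1 + βT1) |
| <0 | <0 | 5.4·10⁻⁴·x − 0.15 − (αT2 + βT2) |

with αH = 2.8·10⁻³, βH = 0.1647, αT1 = 0.0005, βT1 = 0.0133,
αT2 = 0.0002, βT2 = 0.0329. Three aspects of the published table are
implemented exactly as printed and deliberately not "repaired": the rising-
humidity cases contain no voltage term, and the falling-humidity cases
subtract a bare (α + β) with no temperature multiplier. An audit switch
(`humid_branch_adds_affine`) re-adds the affine voltage term in the
rising-humidity cases for sensitivity studies; it defaults off.

Design choices where the source is silent:

* **Reference conditions.** ΔH and ΔT need a baseline; none is published.
  They are stored in `CalibrationCoefficients` with defaults 25 °C and
  40 %RH (typical indoor bench conditions), overridable in config.
* **Zero deltas.** ΔH = ΔT = 0 uses the plain affine case. ΔH = 0 with
  ΔT ≠ 0 joins the ΔH < 0 family, because those branches retain the
  voltage signal a pure temperature change should not erase. ΔT = 0 joins
  the T1 (ΔT > 0) sub-branch; the choice is arbitrary between two adjacent
  constants and is fixed here once.
* **Units.** Raw voltage is treated as the sensor's native opaque unit;
  dust density and PM2.5 units are carried as labels and never converted.
* **Clamping.** The affine fit goes negative below ≈278 raw units; since
  density is physically non-negative, calibrated values are clamped to zero
  after calibration and flagged.

## Preprocessing

* **Cleaning.** Sensors signal missing data with far-out-of-range sentinel
  values. `remove_invalid` drops samples that are non-finite or outside the
  per-channel closed valid range (vector channels checked per component),
  preserving order and producing an exactly reconciling `CleanReport`
  (n_input = n_kept + out-of-bound + missing). Ranges are closed because a
  reading at the range limit is legitimate sensor saturation. Removed
  samples are not imputed.
* **Smoothing.** Environmental channels get a trailing 6-second moving
  mean over `(t − 6, t]`. Trailing (causal) rather than centered, matching
  real-time operation; with tied timestamps a sample averages only samples
  at or before its own position. Implemented with a cumulative-sum window
  so irregular sampling is handled exactly; variance never increases.
* **Baseline-deviation scaling** is formalized as an affine gain about a
  baseline, `v → b + g·(v − b)`, with default gain 1 (off). The source
  describes "increasing sensitivity by scaling" without a formula; this is
  the package's interpretation and is disabled unless configured.

## Features (16 per window)

Classification windows are 60 s trailing with a 60 s hop (the window is
described as "fixed size" without a stated size; 60 s balances feature
stability against label granularity, and both are configurable).

1–2. **percent FEV1 / percent PEF** — 100·current / mean(three resting
baseline measurements). Spirometry is episodic, so the most recent
measurement is carried forward, with a 24 h staleness horizon after which
the feature is flagged missing.

3–6. **dust density, particulate matter, temperature, humidity** — trailing
window means of the calibrated, smoothed series.

7. **heart rate reserve** — HRR = HRmax − HRrest with HRmax = 208 − 0.7·age
(an age-predicted maximum valid down to childhood). HRR itself is a
per-subject constant with no within-subject signal, so the per-window
feature is the *fraction of HRR in use*, (HR̄ − HRrest)/HRR, clipped to
[0, 1.5] to tolerate transient optical-HR overshoot. The raw constant is
exposed separately (`hr_reserve`).

8. **total energy expenditure** — the composite acceleration statistic

   Km = (1/(n−1)) · (Q − P/n),  Q = Σx² + Σy² + Σz²,  P = (Σx)² + (Σy)² + (Σz)²

   over 5-s accelerometer sub-windows; the classification window reports
   the mean over its complete sub-windows (sum available behind a flag).
   Km is exactly the summed per-axis sample variance written in its
   one-pass computational form, which makes it translation-invariant
   (gravity and orientation offsets drop out) and quadratic under amplitude
   scaling. Two printed-form quirks are preserved behind flags: the
   published P duplicates Q typographically (`as_printed=True` keeps the
   literal degenerate Q/n reading), and no square root is applied despite
   the statistic being introduced as a "vector norm" — the formula as
   printed has none.

9–16. the eight online-source features copied from the LOCF-joined row.

Missing features are NaN plus an explicit flag — never silently
zero-filled. At training and prediction time they are median-imputed, with
medians learned from training data only and stored in the model bundle.

## Labels

ACT total scores (integers 5–25) bin into risk levels: **low 20–25,
medium 15–19, high ≤14**. The published ranges double-list 19 (under both
low and medium); it is resolved to medium, consistent with the instrument's
"19 or less" meaning imperfectly controlled asthma. Score 15 likewise stays
medium per the explicit bin listing even though "15 or less" is described
as poorly controlled. Hourly ACT observations label windows by nearest
observation to the window end within ±30 min (half the hourly cadence),
ties breaking toward the earlier observation; unlabeled windows are
reported and excluded from training.

## Classifier and evaluation

A random-forest classifier (scikit-learn) over the 16 features, evaluated
by 10-fold cross-validation: a seeded random partition into subsamples
whose sizes differ by at most one, every sample validated exactly once.
Hyperparameter grid search — trees {100, 300}, max depth {∞, 5, 10},
features per split {√p, p} — runs *nested* inside each outer training fold
(inner 5-fold CV), so imputation and model selection never see validation
data and the reported outer accuracy is unbiased. A Gaussian naive Bayes
baseline runs through the identical harness. The chance level for three
classes is 1/3 (33.33 %). Class imbalance is reported in `CVResult` but not
reweighted. Prediction returns the three class probabilities and the
argmax label, with exact ties broken deterministically toward the higher
risk level (a safety-first convention). All fits are single-threaded and
fully reproducible from the seed.

## Synthetic generator

The generator is the package's study-conditions definition, emulating the
qualitative behaviors the platform was validated against: baseline quiet
streams; smoky-room episodes (dust and PM2.5 elevated multiplicatively,
PEF/FEV1 depressed, mild heart-rate rise); exercise episodes (accelerometer
variance scaled up, heart rate driven toward rest + intensity·HRR); sensor
dropout as out-of-range sentinels; and hourly ACT scores.

Defaults (one place, `GeneratorConfig`): accelerometer 20 Hz, heart rate
1 Hz, dust/PM 0.2 Hz, temperature/humidity 0.1 Hz, spirometry every minute
(the cadence of the original validation protocol), online rows every
15 min, ACT hourly at mid-hour; quiet baselines
dust 300 raw units, PM2.5 10 µg/m³, 25 °C, 40 %RH, resting HR from the
profile (synthetic adult: age 29, HRrest 60 bpm, PEF personal best
≈320 L/min); full-intensity smoke multiplies dust and PM by 5 and depresses
spirometry 30 %; full-intensity exercise multiplies accelerometer variance
by 10; dropout probability 1 % with sentinel 65535. Episode-to-label
mapping mirrors the ACT bins by construction: quiet draws scores 20–25,
mild episodes (intensity < 1) 15–19, severe (≥ 1) 5–14, uniformly within
the bin. ACT is administered mid-hour so hourly labels align cleanly with
the ±30 min horizon. The canonical mixed scenario is 6 h of hour-long
quiet / mild-exercise / severe-smoke episodes, twice each, giving balanced
classes. `zeroed_effects()` nulls every effect size, making features
statistically independent of the scripted labels — the negative control
under which cross-validated accuracy must return to chance.

One generator design rule deserves emphasis: per-sample noise is
independent across classification windows. Any noise value shared by
several windows (a slow sensor carried forward, a noisy online row reused
within its 15-min block) would act as a covert block identifier perfectly
correlated with the hourly labels, and a forest will happily memorize it —
inflating accuracy through temporal pseudo-replication rather than signal.
For this reason spirometry is drawn fresh every minute (one draw per
window) and the online fixture rows are constants: they represent calm,
steady outdoor conditions and are deliberately uninformative about indoor
episodes.

What the generator does **not** emulate: real sensor spectra and drift,
autocorrelated physiology, circadian structure, gradual episode onset,
location movement, or the original subjects' data distributions — the
published 80.10 ± 14.13 % accuracy was computed on unpublished subject data
and is not a reproduction target. Passing the recovery tests shows the
pipeline can extract a planted signal of realistic shape and size, not that
it achieves any particular accuracy on real patients.

## Record envelopes

Transport sealing generates a fresh random 128-bit AES key per envelope,
encrypts with AES-CTR, authenticates with an HMAC-SHA256 tag
(encrypt-then-MAC; both subkeys derived from the envelope key), wraps the
AES key with the recipient's 2048-bit RSA key under OAEP(SHA-256), and
stores a SHA-256 plaintext digest for end-to-end verification. Storage
re-encryption uses 256-bit AES in CBC mode with the digest sealed inside
the ciphertext. Tampering, truncation or a mismatched key always raises;
there is no silent-corruption path. Key pairs live in an in-memory
registry keyed by opaque ids — no HSM, no network key exchange, no user
access control. The AES and RSA-OAEP primitives are implemented in-package
(numpy-vectorized block transforms, stdlib hashing and entropy) and are
validated against the standard AES known-answer vectors in the test suite.

## Numerical and testing choices

* Tolerances: Km is checked against an independent two-pass variance
  oracle at 1e-10 relative; smoothing against a brute-force windowed mean
  at 1e-9 absolute; calibration arithmetic exactly or at float precision.
* Stochastic checks use fixed seeds and standard-error bands: the
  shuffled-label chance check uses n = 3000 windows and a 3-SE band; the
  zero-effect negative control uses the 6 h mixed scenario (~360 windows)
  and a 4-SE band (CV fold correlation makes the binomial SE slightly
  optimistic).
* Problem sizes: pipeline-level tests run the 6 h mixed scenario
  (~467 000 records, 360 windows); fixture files use a reduced 5 Hz
  accelerometer rate to stay small. RSA test keys are seeded 1024-bit;
  the 2048-bit default is exercised once.
* Degenerate inputs fail loudly and early: unknown channels, non-finite
  values, empty windows, single-class training data, undersized
  accelerometer windows (Km divides by n − 1), non-positive heart-rate
  reserve.

## Known limitations

* The published calibration branches are discontinuous at ΔH = 0 and
  ΔT = 0 and discard the voltage term under rising humidity; with ambient
  humidity hovering near the reference this makes calibrated dust density a
  noisy feature. This is faithful to the source; the audit switches exist
  precisely to quantify it.
* Percent-of-baseline spirometry assumes the three baseline measurements
  were taken symptom-free; no drift or re-baselining is modeled.
* The label-alignment horizon and the 60 s window are interacting
  granularity choices; windows near episode boundaries can carry a
  neighboring hour's label.
* `ModelBundle` serialization uses joblib and is a versioned artifact of
  this package + scikit-learn combination, not an interchange format.
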