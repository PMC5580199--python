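"""Feature engineering: Km vs a naive variance oracle, HRR, spirometry
percent-of-baseline, window assembly."""

from __future__ import annotations

import math

import numpy as np
import pytest

from asthmawatch.features import (
    FEATURE_ORDER,
    AccelWindow,
    FeatureVector,
    build_feature_vector,
    composite_accel_km,
    energy_expenditure,
    heart_rate_reserve_fraction,
    hr_max,
    hr_reserve,
    percent_of_baseline,
    read_feature_table,
    write_feature_table,
)
from asthmawatch.records import OnlineFeatureRow, SubjectProfile
from asthmawatch.synth import default_profile


def naive_summed_axis_variance(samples: np.ndarray) -> float:
    """Independent two-pass oracle: sum of per-axis sample variances."""
    return sum(float(np.var(samples[:, ax], ddof=1)) for ax in range(3))


class TestCompositeAccelKm:
    def test_all_zero_samples_give_zero(self):
        assert composite_accel_km(np.zeros((10, 3))) == 0.0

    def test_constant_samples_give_zero(self):
        samples = np.tile([3.7, 0.0, 0.0], (8, 1))
        assert composite_accel_km(samples) == pytest.approx(0.0, abs=1e-12)

    def test_two_sample_hand_case(self):
        # var({1, 3}) = 2 on the x axis, zero elsewhere
        assert composite_accel_km(np.array([[1.0, 0, 0], [3.0, 0, 0]])) == 2.0

    def test_matches_naive_variance_oracle_on_random_windows(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = int(rng.integers(2, 120))
            samples = rng.normal(rng.uniform(-10, 10), rng.uniform(0.01, 5), (n, 3))
            km = composite_accel_km(samples)
            oracle = naive_summed_axis_variance(samples)
            assert km == pytest.approx(oracle, rel=1e-10, abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        samples = rng.normal(0, 1, (50, 3))
        shifted = samples + np.array([5.0, -3.0, 9.81])
        assert composite_accel_km(shifted) == pytest.approx(
            composite_accel_km(samples), rel=1e-9
        )

    @pytest.mark.parametrize("k", [1.0, 2.0, 3.5])
    def test_amplitude_scaling_is_quadratic(self, k):
        rng = np.random.default_rng(9)
        samples = rng.normal(0, 1, (40, 3))
        mean = samples.mean(axis=0)
        scaled = mean + k * (samples - mean)
        assert composite_accel_km(scaled) == pytest.approx(
            k**2 * composite_accel_km(samples), rel=1e-9
        )

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            AccelWindow(np.zeros((1, 3)))

    def test_as_printed_variant_degenerates_to_mean_square(self):
        samples = np.array([[1.0, 0, 0], [3.0, 0, 0]])
        # with P duplicating Q the statistic collapses to Q/n
        assert composite_accel_km(samples, as_printed=True) == pytest.approx(5.0)


class TestEnergyExpenditure:
    def test_zero_motion_gives_zero(self):
        t = np.arange(0, 10, 0.1)
        accel = np.tile([0.0, 0.0, 9.81], (t.size, 1))
        assert energy_expenditure(t, accel, (0.0, 10.0)) == pytest.approx(0.0, abs=1e-12)

    def test_mean_of_subwindow_kms(self):
        # two 5-s sub-windows engineered to Km = 2 and Km = 4 exactly:
        # two samples each, per-axis variances var({1,3}) = 2, var({1,5}) = 8 -> Km 8? no:
        # var({a, b}) = (b-a)^2 / 2, so pairs (0,2) -> 2 and (0,2.828..) -> 4
        t = np.array([0.0, 1.0, 5.0, 6.0])
        d2 = 2.0  # (d2)^2/2 = 2
        d4 = math.sqrt(8.0)  # (d4)^2/2 = 4
        accel = np.array([[0, 0, 0], [d2, 0, 0], [0, 0, 0], [d4, 0, 0]], dtype=float)
        assert energy_expenditure(t, accel, (0.0, 10.0)) == pytest.approx(3.0)
        assert energy_expenditure(t, accel, (0.0, 10.0), aggregate="sum") == pytest.approx(6.0)

    def test_vigorous_stream_scores_higher_than_stationary(self):
        rng = np.random.default_rng(10)
        t = np.arange(0, 60, 0.05)
        quiet = rng.normal(0, 0.05, (t.size, 3))
        vigorous = rng.normal(0, 0.5, (t.size, 3))
        assert energy_expenditure(t, vigorous, (0.0, 60.0)) > energy_expenditure(
            t, quiet, (0.0, 60.0)
        )

    def test_no_accel_data_flags_missing(self):
        val = energy_expenditure(np.array([]), np.zeros((0, 3)), (0.0, 10.0))
        assert math.isnan(val)


class TestHeartRateReserve:
    def test_printed_formula_at_age_29(self):
        profile = SubjectProfile("a", 29.0, 60.0, (310, 320, 330), (2.9, 3.0, 3.1))
        assert hr_max(29.0) == pytest.approx(187.7)
        assert hr_reserve(profile) == pytest.approx(127.7)

    def test_resting_heart_rate_gives_zero_fraction(self):
        profile = default_profile()
        assert heart_rate_reserve_fraction(profile, profile.hr_rest) == 0.0

    def test_formula_at_age_zero(self):
        # profile validation rejects age 0, but the formula itself is total
        assert hr_max(0.0) == 208.0

    def test_fraction_clipped_to_bounds(self):
        profile = default_profile()
        assert heart_rate_reserve_fraction(profile, 1000.0) == 1.5
        assert heart_rate_reserve_fraction(profile, 0.0) == 0.0

    def test_rest_above_max_is_profile_error(self):
        profile = SubjectProfile("a", 29.0, 200.0, (310, 320, 330), (2.9, 3.0, 3.1))
        with pytest.raises(ValueError):
            hr_reserve(profile)


class TestPercentOfBaseline:
    def test_current_equal_to_baseline_mean_is_100(self):
        assert percent_of_baseline(320.0, (310, 320, 330)) == pytest.approx(100.0)

    def test_half_of_baseline_mean_is_50(self):
        assert percent_of_baseline(160.0, (300, 320, 340)) == pytest.approx(50.0)

    def test_zero_current_is_zero_percent(self):
        assert percent_of_baseline(0.0, (300, 320, 340)) == 0.0

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_of_baseline(100.0, (0.0, 0.0, 0.0))


def _streams():
    t_env = np.arange(0.0, 60.0, 5.0)
    t_acc = np.arange(0.0, 60.0, 0.5)
    rng = np.random.default_rng(3)
    return {
        "dust_density": (t_env, np.full(t_env.size, 0.2)),
        "pm25": (t_env, np.full(t_env.size, 12.0)),
        "temperature": (t_env, np.full(t_env.size, 25.0)),
        "humidity": (t_env, np.full(t_env.size, 40.0)),
        "heart_rate": (t_env, np.full(t_env.size, 80.0)),
        "accel": (t_acc, rng.normal(0, 0.1, (t_acc.size, 3))),
        "pef": (np.array([10.0]), np.array([320.0])),
        "fev1": (np.array([10.0]), np.array([3.0])),
    }


def _online_row():
    return OnlineFeatureRow(
        t=0.0, ozone=30, pressure=1013, cloud_cover=0.2, wind_speed=3,
        precip_probability=0.1, precip_intensity=0.0, traffic_density=50, aqi=40,
    )


class TestBuildFeatureVector:
    def test_fully_populated_window_is_finite(self):
        fv = build_feature_vector(_streams(), default_profile(), _online_row(), (0.0, 60.0))
        assert fv.missing == frozenset()
        assert np.all(np.isfinite(fv.as_array()))
        assert fv.features["percent_pef"] == pytest.approx(100.0)
        assert fv.features["heart_rate_reserve"] == pytest.approx(20.0 / 127.7, rel=1e-6)

    def test_no_spirometry_flags_percent_features_missing(self):
        streams = _streams()
        del streams["pef"], streams["fev1"]
        fv = build_feature_vector(streams, default_profile(), _online_row(), (0.0, 60.0))
        assert {"percent_pef", "percent_fev1"} <= fv.missing

    def test_stale_spirometry_flagged_missing(self):
        streams = _streams()
        fv = build_feature_vector(
            streams, default_profile(), _online_row(), (0.0, 60.0),
            spiro_staleness_s=5.0,
        )
        assert {"percent_pef", "percent_fev1"} <= fv.missing

    def test_identical_inputs_give_identical_vectors(self):
        a = build_feature_vector(_streams(), default_profile(), _online_row(), (0.0, 60.0))
        b = build_feature_vector(_streams(), default_profile(), _online_row(), (0.0, 60.0))
        assert a == b

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            build_feature_vector({}, default_profile(), _online_row(), (0.0, 60.0))

    def test_feature_order_is_stable_declared_order(self):
        fv = build_feature_vector(_streams(), default_profile(), _online_row(), (0.0, 60.0))
        assert tuple(fv.features) == FEATURE_ORDER

    def test_csv_round_trip_preserves_order_and_values(self, tmp_path):
        fv = build_feature_vector(_streams(), default_profile(), _online_row(), (0.0, 60.0))
        path = tmp_path / "features.csv"
        write_feature_table([fv], path)
        header = path.read_text().splitlines()[0]
        assert header == "window_start,window_end," + ",".join(FEATURE_ORDER)
        back = read_feature_table(path)
        assert back == [fv]

    def test_vector_with_wrong_feature_names_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(0.0, 60.0, {"bogus": 1.0})
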