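import math

import numpy as np
import pandas as pd
import pytest

from behaviorome import features as ft
from behaviorome.vocab import WATCH_CHANNELS


def _window_events(sensors, start="2024-03-04 08:00:00", spacing_s=10.0):
    n = len(sensors)
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(n) * spacing_s, unit="s")
    return pd.DataFrame({"timestamp": ts, "sensor": sensors, "message": ["ON"] * n})


class TestSegmentation:
    def test_one_ambient_window_per_event(self):
        idx = ft.segment_ambient(100)
        assert idx.shape == (100, 30)

    def test_first_window_left_padded_with_first_event(self):
        idx = ft.segment_ambient(50)
        assert (idx[0] == 0).all()
        assert idx[5, :25].tolist() == [0] * 25 and idx[5, -1] == 5

    def test_sixty_seconds_gives_twelve_mobile_windows(self):
        assert ft.segment_mobile(60) == 12
        assert ft.segment_mobile(4) == 0

    def test_samples_inherit_window_labels(self):
        lab = ft.expand_window_labels(np.array(["a", "b"], dtype=object), 13)
        assert lab.tolist() == ["a"] * 5 + ["b"] * 5 + ["b"] * 3


class TestAmbientFeatures:
    def test_single_sensor_window_entropy_zero(self):
        w = _window_events(["Kitchen-Motion-1"] * 30)
        f = ft.extract_ambient_features(w)
        assert f["window_entropy"] == 0.0
        assert f["n_distinct_sensors"] == 1.0
        assert f["count_Kitchen-Motion"] == 30.0

    def test_two_sensor_window_entropy_one_bit(self):
        w = _window_events(["Kitchen-Motion-1", "Bedroom-Motion-1"] * 15)
        f = ft.extract_ambient_features(w)
        assert f["window_entropy"] == pytest.approx(1.0)
        assert f["n_location_changes"] == 29.0

    def test_counts_match_hand_tally(self):
        sensors = (
            ["Kitchen-Motion-1"] * 12
            + ["Kitchen-Door-1"] * 3
            + ["DiningRoom-Motion-2"] * 10
            + ["LivingRoom-Light-1"] * 5
        )
        w = _window_events(sensors, spacing_s=7.0)
        f = ft.extract_ambient_features(w)
        assert f["count_Kitchen-Motion"] == 12.0
        assert f["count_Kitchen-Door"] == 3.0
        assert f["count_DiningRoom-Motion"] == 10.0
        assert f["count_LivingRoom-Light"] == 5.0
        assert f["n_distinct_sensors"] == 4.0
        assert f["dominant_current_Kitchen-Motion"] == 1.0
        assert f["window_duration"] == pytest.approx(29 * 7.0)
        assert f["time_since_previous"] == pytest.approx(7.0)
        assert f["n_location_changes"] == 2.0  # kitchen -> dining -> living
        # hand-tallied entropy of {12, 3, 10, 5}/30
        p = np.array([12, 3, 10, 5]) / 30
        assert f["window_entropy"] == pytest.approx(float(-(p * np.log2(p)).sum()))
        assert f["hour"] == 8.0
        # last motion sensor fired in the dining room
        assert f["last_motion_region_DiningRoom"] == 1.0

    def test_batch_matches_single_window_view(self):
        rng = np.random.default_rng(0)
        sensors = rng.choice(["Kitchen-Motion-1", "Bedroom-Motion-1", "Entry-Door-1"], size=80)
        events = _window_events(sensors, spacing_s=13.0)
        batch = ft.extract_ambient_features_batch(events)
        single = ft.extract_ambient_features(events.iloc[50 - 29 : 51])
        pd.testing.assert_series_equal(batch.iloc[50], single, check_names=False)

    def test_extraction_is_pure(self):
        events = _window_events(["Kitchen-Motion-1", "Hall-Motion-2"] * 20)
        a = ft.extract_ambient_features_batch(events)
        b = ft.extract_ambient_features_batch(events)
        pd.testing.assert_frame_equal(a, b)

    def test_time_translation_moves_only_clock_features(self):
        events = _window_events(["Kitchen-Motion-1", "Bedroom-Motion-1"] * 20)
        shifted = events.assign(timestamp=events["timestamp"] + pd.Timedelta(hours=3))
        a = ft.extract_ambient_features_batch(events)
        b = ft.extract_ambient_features_batch(shifted)
        clock = ["hour", "seconds_past_midnight", "day_of_week"]
        pd.testing.assert_frame_equal(a.drop(columns=clock), b.drop(columns=clock))
        assert (b["hour"] - a["hour"] == 3).all()


def _mobile_window(values):
    """A 5-sample watch frame with identical values in every IMU channel."""
    data = {"timestamp": pd.date_range("2024-03-04 09:00:00", periods=5, freq="s")}
    for ch in ("ax", "ay", "az", "gx", "gy", "gz"):
        data[ch] = values
    data["course"] = [0.0, 10.0, 20.0, 30.0, 40.0]
    data["speed"] = [0.0, 0.4, 1.0, 1.2, 0.0]
    data["location_type"] = ["home"] * 5
    return pd.DataFrame(data)


class TestMobileFeatures:
    def test_zero_window_conventions(self):
        w = _mobile_window([0.0] * 5)
        f = ft.extract_mobile_features(w)
        for ch in ("ax", "gz"):
            assert f[f"{ch}_energy"] == 0.0
            assert f[f"{ch}_sd"] == 0.0
            assert f[f"{ch}_autocorr"] == 0.0
            assert f[f"{ch}_skewness"] == 0.0
            assert f[f"{ch}_cv"] == 0.0

    def test_statistics_match_textbook_formulas(self):
        vals = [0.3, -1.2, 2.5, 0.9, -0.4]
        f = ft.extract_mobile_features(_mobile_window(vals))
        # independent longhand evaluation
        n = 5
        mean = sum(vals) / n
        med = sorted(vals)[2]
        cent = [v - mean for v in vals]
        m2 = sum(c**2 for c in cent) / n
        m3 = sum(c**3 for c in cent) / n
        m4 = sum(c**4 for c in cent) / n
        sd = math.sqrt(m2)
        energy = sum(v**2 for v in vals)
        assert f["ax_max"] == pytest.approx(max(vals))
        assert f["ax_min"] == pytest.approx(min(vals))
        assert f["ax_sum"] == pytest.approx(sum(vals))
        assert f["ax_mean"] == pytest.approx(mean)
        assert f["ax_median"] == pytest.approx(med)
        assert f["ax_mean_abs"] == pytest.approx(sum(abs(v) for v in vals) / n)
        assert f["ax_median_abs"] == pytest.approx(sorted(abs(v) for v in vals)[2])
        assert f["ax_sd"] == pytest.approx(sd)
        assert f["ax_mean_abs_dev"] == pytest.approx(sum(abs(c) for c in cent) / n)
        assert f["ax_median_abs_dev"] == pytest.approx(sorted(abs(v - med) for v in vals)[2])
        assert f["ax_moment2"] == pytest.approx(m2)
        assert f["ax_moment3"] == pytest.approx(m3)
        assert f["ax_moment4"] == pytest.approx(m4)
        assert f["ax_cv"] == pytest.approx(sd / abs(mean))
        assert f["ax_skewness"] == pytest.approx(m3 / sd**3)
        assert f["ax_kurtosis"] == pytest.approx(m4 / m2**2)
        assert f["ax_energy"] == pytest.approx(energy)
        assert f["ax_log_energy"] == pytest.approx(math.log(energy))
        assert f["ax_power"] == pytest.approx(energy / n)
        # lag-1 autocorrelation, longhand
        a, b = vals[:-1], vals[1:]
        am, bm = sum(a) / 4, sum(b) / 4
        num = sum((x - am) * (y - bm) for x, y in zip(a, b))
        den = math.sqrt(sum((x - am) ** 2 for x in a) * sum((y - bm) ** 2 for y in b))
        assert f["ax_autocorr"] == pytest.approx(num / den)
        assert f["ax_mean_abs_succ_diff"] == pytest.approx(
            sum(abs(y - x) for x, y in zip(vals[:-1], vals[1:])) / 4
        )
        # Fourier magnitudes of the 5-point transform
        mags = np.abs(np.fft.rfft(vals))
        assert f["ax_fft_mag_mean"] == pytest.approx(mags.mean())
        assert f["ax_fft_mag_var"] == pytest.approx(mags.var())
        # identical channels correlate perfectly
        assert f["corr_ax_ay"] == pytest.approx(1.0)

    def test_stopped_window_forced_values(self):
        w = _mobile_window([0.1] * 5)
        w["speed"] = 0.0
        f = ft.extract_mobile_features(w)
        assert f["stop_rate"] == 1.0
        assert f["distance_traveled"] == 0.0
        assert f["trajectory"] == 0.0

    def test_stop_rate_and_distance(self):
        f = ft.extract_mobile_features(_mobile_window([0.1] * 5))
        assert f["stop_rate"] == pytest.approx(3 / 5)  # speeds 0, 0.4, 0 below 0.5
        assert f["distance_traveled"] == pytest.approx(2.6)
        assert f["heading_change_rate"] == pytest.approx(10.0)

    def test_context_top_location_indicator(self):
        w = _mobile_window([0.1] * 5)
        ctx = ft.PersonContext(top_locations={"night": (), "morning": ("home",), "afternoon": (), "evening": ()})
        f = ft.extract_mobile_features(w, ctx)
        assert f["in_top_locations"] == 1.0
        ctx2 = ft.PersonContext(top_locations={"night": (), "morning": ("work",), "afternoon": (), "evening": ()})
        assert ft.extract_mobile_features(w, ctx2)["in_top_locations"] == 0.0

    def test_person_context_top3_by_time_of_day(self, one_day):
        _, watch = one_day
        ctx = ft.person_context(watch)
        assert "home" in ctx.top_locations["night"]  # everyone sleeps at home
        assert ctx.distance_scale >= 1.0

    def test_no_missing_values_on_simulated_day(self, one_day):
        _, watch = one_day
        from behaviorome.filters import lowpass_stream

        f = ft.extract_mobile_features_batch(lowpass_stream(watch.iloc[: 3600]), ft.person_context(watch))
        assert not f.isna().any().any()
        assert len(f) == 720
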