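import numpy as np
import pandas as pd
import pytest

from behaviorome import markers as mk
from behaviorome.assemble import assemble_behaviorome, behaviorome_schema, subset_features
from behaviorome.markers import overall_statistics


class TestOverallStatistics:
    def test_constant_series(self):
        s = overall_statistics([1, 1, 1, 1])
        assert s["mean"] == 1 and s["sd"] == 0 and s["iqr"] == 0
        assert s["energy"] == 4 and s["zero_crossings"] == 0 and s["mean_crossings"] == 0
        assert s["skewness"] == 0 and s["kurtosis"] == 0

    def test_alternating_series(self):
        s = overall_statistics([-1, 1, -1, 1])
        assert s["mean"] == 0 and s["zero_crossings"] == 3 and s["energy"] == 4

    def test_matches_textbook_formulas(self):
        x = np.random.default_rng(8).normal(2.0, 1.5, 60)
        s = overall_statistics(x)
        mean = x.sum() / len(x)
        cent = x - mean
        sd = np.sqrt((cent**2).mean())
        assert s["mean"] == pytest.approx(mean)
        assert s["median"] == pytest.approx(np.sort(x)[29:31].mean())
        assert s["sd"] == pytest.approx(sd)
        assert s["max"] == x.max() and s["min"] == x.min()
        assert s["iqr"] == pytest.approx(np.percentile(x, 75) - np.percentile(x, 25))
        assert s["skewness"] == pytest.approx((cent**3).mean() / sd**3)
        assert s["kurtosis"] == pytest.approx((cent**4).mean() / sd**4)
        assert s["energy"] == pytest.approx((x**2).sum())
        assert s["mean_crossings"] == sum(
            1 for a, b in zip(cent[:-1], cent[1:]) if a * b < 0
        )

    def test_length_one_conventions(self):
        s = overall_statistics([3.0])
        assert s["sd"] == 0 and s["zero_crossings"] == 0 and s["skewness"] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overall_statistics([])


def _events(rows, date="2024-03-04"):
    base = pd.Timestamp(date)
    return pd.DataFrame(
        {
            "timestamp": [base + pd.Timedelta(seconds=s) for s, *_ in rows],
            "sensor": [r[1] for r in rows],
            "message": ["ON"] * len(rows),
            "activity": [r[2] for r in rows],
        }
    )


class TestHomeMarkers:
    def test_three_block_fixture_matches_hand_tally(self):
        # 2h sleep in bedroom, then hygiene in bathroom, then cooking
        rows = [
            (600, "Bedroom-Motion-1", "Sleep"),
            (3600, "Bedroom-Motion-2", "Sleep"),
            (7200, "Bedroom-Motion-1", "Sleep"),
            (7500, "Bathroom-Motion-1", "Personal hygiene"),
            (7800, "Bathroom-Motion-1", "Personal hygiene"),
            (8000, "Kitchen-Motion-1", "Cook"),
            (8600, "Kitchen-Temperature-1", "Cook"),
        ]
        daily, hourly = mk.compute_home_markers(_events(rows), "2024-03-04")
        assert daily["n_readings"] == 7
        assert daily["n_distinct_activities"] == 3
        assert daily["n_distinct_locations"] == 3
        # interval accrual to the later reading's label; first absorbs midnight
        assert daily["sec_activity_sleep"] == pytest.approx(7200)
        assert daily["sec_activity_personal_hygiene"] == pytest.approx(600)
        assert daily["sec_activity_cook"] == pytest.approx(800)
        assert daily["first_activity_sleep"] == 600
        assert daily["first_activity_cook"] == 8000
        assert daily["first_activity_eat"] == 86400  # sentinel: never occurred
        assert daily["sec_location_bedroom"] == pytest.approx(7200)
        assert hourly.loc[0, "n_readings"] == 1  # the 600 s event
        assert hourly.loc[1, "n_readings"] == 1  # the 3600 s event
        assert hourly.loc[2, "n_readings"] == 5
        assert hourly.loc[2, "sec_activity_personal_hygiene"] == pytest.approx(600)

    def test_empty_day_all_zero_with_sentinels(self):
        daily, hourly = mk.compute_home_markers(_events([]), "2024-03-04")
        assert daily["n_readings"] == 0
        assert daily["first_activity_sleep"] == 86400
        assert (hourly["n_readings"] == 0).all()


def _watch_day(n=86400, speed=0.0, activity="Sleep", date="2024-03-04"):
    return pd.DataFrame(
        {
            "timestamp": pd.date_range(date, periods=n, freq="s"),
            "ax": 0.0, "ay": 0.0, "az": 1.0,
            "gx": 0.0, "gy": 0.0, "gz": 0.0,
            "course": 0.0, "speed": speed,
            "location_type": "home",
            "activity": activity,
        }
    )


class TestWatchMarkers:
    def test_full_sleep_day(self):
        daily, hourly = mk.compute_watch_markers(_watch_day(), "2024-03-04")
        assert daily["sec_activity_sleep"] == 86400
        assert daily["sec_activity_work"] == 0
        assert daily["n_missing"] == 0
        assert daily["total_acceleration"] == pytest.approx(86400.0)  # 1 g per sample
        assert (hourly["sec_activity_sleep"] == 3600).all()

    def test_constant_speed_distance_integration(self):
        stream = _watch_day(speed=1.0).drop(index=range(600)).reset_index(drop=True)
        daily, _ = mk.compute_watch_markers(stream, "2024-03-04")
        assert daily["total_distance"] == pytest.approx(86400 - 600)
        assert daily["n_missing"] == 600

    def test_imputed_rows_count_as_missing(self):
        stream = _watch_day(n=7200).assign(imputed=False)
        stream.loc[100:399, "imputed"] = True
        daily, _ = mk.compute_watch_markers(stream, "2024-03-04")
        assert daily["n_missing"] == 86400 - 7200 + 300

    def test_empty_day(self):
        daily, hourly = mk.compute_watch_markers(_watch_day(0), "2024-03-04")
        assert daily["n_missing"] == 86400
        assert (hourly["n_missing"] == 3600).all()


@pytest.fixture(scope="module")
def tables():
    daily_rows, hourly_rows = {}, {}
    wd_rows, wh_rows = {}, {}
    rng = np.random.default_rng(0)
    for d in range(14):
        date = pd.Timestamp("2024-03-04") + pd.Timedelta(days=d)
        rows = [
            (3600 * h, "Bedroom-Motion-1", "Sleep") for h in range(0, 7)
        ] + [(3600 * h + int(rng.integers(0, 3000)), "Kitchen-Motion-1", "Cook") for h in range(8, 20)]
        daily_rows[date], hourly_rows[date] = mk.compute_home_markers(
            _events(sorted(rows), date), date
        )
        wd_rows[date], wh_rows[date] = mk.compute_watch_markers(
            _watch_day(3600 * 20, date=date), date
        )
    return mk.stack_days(daily_rows, hourly_rows), mk.stack_days(wd_rows, wh_rows)


class TestBehavioromeAssembly:

    def test_schema_enumeration_matches_assembled_vector(self, tables):
        home, watch = tables
        vec = assemble_behaviorome(home=home, watch=watch)
        assert list(vec.index) == behaviorome_schema()
        assert not vec.isna().any()

    def test_home_only_contains_no_watch_names(self, tables):
        home, watch = tables
        vec = assemble_behaviorome(home=home, modalities=("home",))
        assert all(name.startswith("home_") for name in vec.index)

    def test_missing_modality_rejected(self, tables):
        home, _ = tables
        with pytest.raises(ValueError, match="watch"):
            assemble_behaviorome(home=home, modalities=("home", "watch"))

    def test_day_order_invariance(self, tables):
        (hd, hh), _ = tables
        daily_rows = {d: hd.loc[d] for d in hd.index}
        hourly_rows = {d: hh.loc[d] for d in hd.index}
        rev_d, rev_h = mk.stack_days(
            dict(reversed(list(daily_rows.items()))), dict(reversed(list(hourly_rows.items())))
        )
        pd.testing.assert_frame_equal(rev_d, hd)

    def test_subset_features_prefix_filter(self, tables):
        home, watch = tables
        vec = assemble_behaviorome(home=home, watch=watch)
        frame = vec.to_frame().T
        assert all(c.startswith("home_") for c in subset_features(frame, "home").columns)
        assert all(c.startswith("watch_") for c in subset_features(frame, "watch").columns)
        assert subset_features(frame, "fusion").shape[1] == len(vec)
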