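"""Daily and hourly digital behavior markers from activity-labeled streams.

Home (ambient) markers per day: number of sensor readings, numbers of
distinct activities and locations, seconds spent on each activity and in each
region, and the time of day of the first occurrence of each activity / first
visit to each region.  Watch markers per day: total acceleration and rotation
(sums of per-sample vector norms), missing-reading count, distance traveled,
seconds per primary activity / one-class category / location type, and first
occurrences.  Hourly analogues are computed for every marker that is
meaningful within an hour.

Conventions:

* ambient durations accrue the inter-reading interval to the **later**
  reading's label (the reading that closes the interval); seconds after the
  last reading of a day are unattributed;
* watch durations accrue 1 s per 1 Hz sample;
* an activity or location never observed in a day gets duration 0 and the
  first-occurrence sentinel 86400 s (preserves "later = larger" ordering);
* watch rows carrying an ``imputed`` flag count toward the missing-reading
  markers, not toward observed time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import split_sensor
from .vocab import (
    HOME_ACTIVITIES,
    HOME_REGIONS,
    LOCATION_TYPES,
    MOBILE_ACTIVITIES,
    ONE_CLASS_CATEGORIES,
)

DAY_SECONDS = 86400
FIRST_OCCURRENCE_SENTINEL = 86400.0

STAT_NAMES = (
    "mean",
    "median",
    "sd",
    "max",
    "min",
    "zero_crossings",
    "mean_crossings",
    "iqr",
    "skewness",
    "kurtosis",
    "energy",
)


def overall_statistics(series: np.ndarray) -> dict[str, float]:
    """Summary statistics of a marker series.

    sd is the population standard deviation; skewness and kurtosis are the
    standardized 3rd/4th central moments (kurtosis is not excess); crossings
    count strict sign changes about zero / about the mean; signal energy is
    the sum of squares.  Zero-variance or length-1 series report 0 for sd,
    crossings, skewness, and kurtosis by convention.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("overall_statistics requires a nonempty series")
    sd = float(np.std(x))
    degenerate = x.size < 2 or sd == 0.0

    def crossings(values: np.ndarray) -> float:
        return float(np.count_nonzero(values[:-1] * values[1:] < 0))

    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "sd": sd,
        "max": float(np.max(x)),
        "min": float(np.min(x)),
        "zero_crossings": 0.0 if x.size < 2 else crossings(x),
        "mean_crossings": 0.0 if x.size < 2 else crossings(x - np.mean(x)),
        "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "skewness": 0.0 if degenerate else float(sps.skew(x)),
        "kurtosis": 0.0 if degenerate else float(sps.kurtosis(x, fisher=False)),
        "energy": float(np.sum(x * x)),
    }


# ---------------------------------------------------------------------------
# marker column schemas
# ---------------------------------------------------------------------------


def _slug(label: str) -> str:
    return label.replace(" ", "_").replace("-", "_").lower()


HOME_DAILY_COLUMNS: tuple[str, ...] = (
    "n_readings",
    "n_distinct_activities",
    "n_distinct_locations",
    *(f"sec_activity_{_slug(a)}" for a in HOME_ACTIVITIES),
    *(f"sec_location_{_slug(r)}" for r in HOME_REGIONS),
    *(f"first_activity_{_slug(a)}" for a in HOME_ACTIVITIES),
    *(f"first_location_{_slug(r)}" for r in HOME_REGIONS),
)

HOME_HOURLY_COLUMNS: tuple[str, ...] = (
    "n_readings",
    "n_distinct_activities",
    "n_distinct_locations",
    *(f"sec_activity_{_slug(a)}" for a in HOME_ACTIVITIES),
    *(f"sec_location_{_slug(r)}" for r in HOME_REGIONS),
)

WATCH_DAILY_COLUMNS: tuple[str, ...] = (
    "total_acceleration",
    "total_rotation",
    "n_missing",
    "total_distance",
    *(f"sec_oneclass_{c}" for c in ONE_CLASS_CATEGORIES),
    *(f"sec_activity_{_slug(a)}" for a in MOBILE_ACTIVITIES),
    *(f"sec_loctype_{lt}" for lt in LOCATION_TYPES),
    *(f"first_activity_{_slug(a)}" for a in MOBILE_ACTIVITIES),
    *(f"first_loctype_{lt}" for lt in LOCATION_TYPES),
)

# hourly distance is carried although the daily row is the printed marker,
# because regularity and circadian summaries need hourly distance values
WATCH_HOURLY_COLUMNS: tuple[str, ...] = (
    "total_acceleration",
    "total_rotation",
    "n_missing",
    "total_distance",
    *(f"sec_oneclass_{c}" for c in ONE_CLASS_CATEGORIES),
    *(f"sec_activity_{_slug(a)}" for a in MOBILE_ACTIVITIES),
    *(f"sec_loctype_{lt}" for lt in LOCATION_TYPES),
)

#: hourly metrics feeding regularity indices and circadian strength
HOME_RHYTHM_METRICS = ("n_readings", "n_distinct_activities", "n_distinct_locations")
WATCH_RHYTHM_METRICS = ("total_acceleration", "total_rotation", "total_distance")


def _seconds_past_midnight(ts: pd.Series, date: pd.Timestamp) -> np.ndarray:
    return ((ts - date) / pd.Timedelta(seconds=1)).to_numpy()


def _first_occurrence(seconds: np.ndarray, codes: np.ndarray, n_codes: int) -> np.ndarray:
    first = np.full(n_codes, FIRST_OCCURRENCE_SENTINEL)
    valid = codes >= 0
    if valid.any():
        np.minimum.at(first, codes[valid], seconds[valid])
    return first


def _per_hour_sum(hours: np.ndarray, codes: np.ndarray, n_codes: int, weights=None) -> np.ndarray:
    """(24, n_codes) sums of weights bucketed by hour and code."""
    valid = codes >= 0
    flat = hours[valid] * n_codes + codes[valid]
    w = None if weights is None else np.asarray(weights)[valid]
    return np.bincount(flat, weights=w, minlength=24 * n_codes).reshape(24, n_codes)


def compute_home_markers(
    events: pd.DataFrame, date: str | pd.Timestamp
) -> tuple[pd.Series, pd.DataFrame]:
    """Daily and 24 hourly home marker rows for one labeled participant-day."""
    date = pd.Timestamp(date).normalize()
    daily = pd.Series(0.0, index=list(HOME_DAILY_COLUMNS))
    hourly = pd.DataFrame(
        0.0, index=pd.RangeIndex(24, name="hour"), columns=list(HOME_HOURLY_COLUMNS)
    )
    if len(events) == 0:
        daily[[c for c in daily.index if c.startswith("first_")]] = FIRST_OCCURRENCE_SENTINEL
        return daily, hourly

    sec = _seconds_past_midnight(events["timestamp"], date)
    hours = np.clip((sec // 3600).astype(int), 0, 23)
    act_codes = pd.Categorical(events["activity"], categories=HOME_ACTIVITIES).codes.astype(int)
    regions = [split_sensor(s)[0] for s in events["sensor"]]
    reg_codes = pd.Categorical(regions, categories=HOME_REGIONS).codes.astype(int)

    # interval accrual: the gap between consecutive readings belongs to the
    # later reading's label; the first reading absorbs the span since midnight
    intervals = np.diff(sec, prepend=0.0)

    act_sec = np.bincount(act_codes[act_codes >= 0], weights=intervals[act_codes >= 0], minlength=len(HOME_ACTIVITIES))
    reg_sec = np.bincount(reg_codes[reg_codes >= 0], weights=intervals[reg_codes >= 0], minlength=len(HOME_REGIONS))
    first_act = _first_occurrence(sec, act_codes, len(HOME_ACTIVITIES))
    first_reg = _first_occurrence(sec, reg_codes, len(HOME_REGIONS))
    daily = pd.Series(
        np.concatenate(
            [
                [
                    float(len(events)),
                    float(len(np.unique(act_codes[act_codes >= 0]))),
                    float(len(np.unique(reg_codes[reg_codes >= 0]))),
                ],
                act_sec,
                reg_sec,
                first_act,
                first_reg,
            ]
        ),
        index=list(HOME_DAILY_COLUMNS),
    )

    # hourly rows: interval seconds are accrued to the hour of the later
    # reading (intervals spanning hour boundaries are not split)
    act_hour = _per_hour_sum(hours, act_codes, len(HOME_ACTIVITIES), weights=intervals)
    reg_hour = _per_hour_sum(hours, reg_codes, len(HOME_REGIONS), weights=intervals)
    act_count = _per_hour_sum(hours, act_codes, len(HOME_ACTIVITIES))
    reg_count = _per_hour_sum(hours, reg_codes, len(HOME_REGIONS))
    hourly = pd.DataFrame(
        np.column_stack(
            [
                np.bincount(hours, minlength=24).astype(float),
                (act_count > 0).sum(axis=1).astype(float),
                (reg_count > 0).sum(axis=1).astype(float),
                act_hour,
                reg_hour,
            ]
        ),
        index=pd.RangeIndex(24, name="hour"),
        columns=list(HOME_HOURLY_COLUMNS),
    )
    return daily, hourly


def compute_watch_markers(
    stream: pd.DataFrame, date: str | pd.Timestamp
) -> tuple[pd.Series, pd.DataFrame]:
    """Daily and 24 hourly watch marker rows for one labeled participant-day.

    ``stream`` holds the day's 1 Hz samples; absent grid seconds (and rows
    flagged ``imputed``) count as missing readings.
    """
    date = pd.Timestamp(date).normalize()
    if len(stream) == 0:
        return _watch_markers_core(
            sec=np.empty(0), acc=np.empty(0), rot=np.empty(0), speed=np.empty(0),
            act_codes=np.empty(0, dtype=int), loc_codes=np.empty(0, dtype=int),
            oc_codes=np.empty(0, dtype=int),
        )
    observed = ~stream["imputed"].to_numpy(dtype=bool) if "imputed" in stream.columns else np.ones(len(stream), dtype=bool)
    obs = stream.loc[observed]
    sec = _seconds_past_midnight(obs["timestamp"], date)
    acc = np.linalg.norm(obs[["ax", "ay", "az"]].to_numpy(dtype=float), axis=1)
    rot = np.linalg.norm(obs[["gx", "gy", "gz"]].to_numpy(dtype=float), axis=1)
    speed = obs["speed"].to_numpy(dtype=float)
    act_codes = pd.Categorical(obs["activity"], categories=MOBILE_ACTIVITIES).codes.astype(int)
    loc_codes = pd.Categorical(obs["location_type"], categories=LOCATION_TYPES).codes.astype(int)
    if "one_class" in obs.columns:
        oc_codes = pd.Categorical(obs["one_class"], categories=ONE_CLASS_CATEGORIES).codes.astype(int)
    else:
        oc_codes = np.full(len(obs), -1)
    return _watch_markers_core(sec, acc, rot, speed, act_codes, loc_codes, oc_codes)


def watch_markers_from_arrays(
    arrays: dict[str, np.ndarray], observed_mask: np.ndarray | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Fast marker path over an array-form complete watch day
    (:func:`behaviorome.synthetic.simulate_watch_day_arrays`); sample ``i``
    is second ``i`` past midnight, optionally masked to the observed subset."""
    n = len(arrays["ax"])
    sec = np.arange(n, dtype=float)
    mask = slice(None) if observed_mask is None else observed_mask
    acc = np.sqrt(arrays["ax"] ** 2 + arrays["ay"] ** 2 + arrays["az"] ** 2)
    rot = np.sqrt(arrays["gx"] ** 2 + arrays["gy"] ** 2 + arrays["gz"] ** 2)
    return _watch_markers_core(
        sec[mask], acc[mask], rot[mask], arrays["speed"][mask],
        arrays["act_codes"][mask].astype(int), arrays["loc_codes"][mask].astype(int),
        arrays["oc_codes"][mask].astype(int),
    )


def _watch_markers_core(
    sec: np.ndarray,
    acc: np.ndarray,
    rot: np.ndarray,
    speed: np.ndarray,
    act_codes: np.ndarray,
    loc_codes: np.ndarray,
    oc_codes: np.ndarray,
) -> tuple[pd.Series, pd.DataFrame]:
    daily = pd.Series(0.0, index=list(WATCH_DAILY_COLUMNS))
    hourly = pd.DataFrame(
        0.0, index=pd.RangeIndex(24, name="hour"), columns=list(WATCH_HOURLY_COLUMNS)
    )
    if len(sec) == 0:
        daily["n_missing"] = float(DAY_SECONDS)
        daily[[c for c in daily.index if c.startswith("first_")]] = FIRST_OCCURRENCE_SENTINEL
        hourly["n_missing"] = 3600.0
        return daily, hourly
    hours = np.clip((sec // 3600).astype(int), 0, 23)

    def counts(codes: np.ndarray, n: int) -> np.ndarray:
        return np.bincount(codes[codes >= 0], minlength=n).astype(float)

    daily = pd.Series(
        np.concatenate(
            [
                [float(acc.sum()), float(rot.sum()), float(DAY_SECONDS - len(sec)), float(speed.sum())],
                counts(oc_codes, len(ONE_CLASS_CATEGORIES)),
                counts(act_codes, len(MOBILE_ACTIVITIES)),
                counts(loc_codes, len(LOCATION_TYPES)),
                _first_occurrence(sec, act_codes, len(MOBILE_ACTIVITIES)),
                _first_occurrence(sec, loc_codes, len(LOCATION_TYPES)),
            ]
        ),
        index=list(WATCH_DAILY_COLUMNS),
    )

    hourly = pd.DataFrame(
        np.column_stack(
            [
                np.bincount(hours, weights=acc, minlength=24),
                np.bincount(hours, weights=rot, minlength=24),
                3600.0 - np.bincount(hours, minlength=24).astype(float),
                np.bincount(hours, weights=speed, minlength=24),
                _per_hour_sum(hours, oc_codes, len(ONE_CLASS_CATEGORIES)),
                _per_hour_sum(hours, act_codes, len(MOBILE_ACTIVITIES)),
                _per_hour_sum(hours, loc_codes, len(LOCATION_TYPES)),
            ]
        ),
        index=pd.RangeIndex(24, name="hour"),
        columns=list(WATCH_HOURLY_COLUMNS),
    )
    return daily, hourly


def stack_days(
    daily_rows: dict[pd.Timestamp, pd.Series],
    hourly_rows: dict[pd.Timestamp, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine per-day marker rows into participant-level tables.

    Returns ``daily`` (days x markers, sorted date index) and ``hourly``
    (MultiIndex (date, hour) x markers).  Sorting makes the result invariant
    to the order in which days were supplied.
    """
    dates = sorted(daily_rows)
    daily = pd.DataFrame({d: daily_rows[d] for d in dates}).T
    daily.index = pd.DatetimeIndex(dates, name="date")
    hourly = pd.concat([hourly_rows[d] for d in dates], keys=dates, names=["date", "hour"])
    return daily, hourly
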