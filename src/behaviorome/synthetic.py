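"""Synthetic cohort generator.

Real deployments of this kind of study use instrumented homes and a worn
smartwatch; no such data can ship with a package.  This module emulates the
three inputs the analysis needs — ambient sensor event logs, a 1 Hz watch
stream, and per-participant demographics/clinical scores — from an explicit
generative model:

* each participant has a :class:`RoutineProfile`, a block schedule of daily
  activities (sleep, meals, work, trips out of the home, ...) with Gaussian
  start-time jitter and duration noise;
* ambient motion/door/temperature/light events fire in the region of the
  active block, at a rate tied to the activity's movement intensity, plus a
  low rate of background noise firings;
* watch acceleration/rotation noise scales with the activity's intensity,
  the participant's overall movement level, and a 24-hour circadian sinusoid,
  on top of a fixed 1 g gravity baseline on the vertical axis;
* watch-transition gaps remove one or two contiguous spans per day with a
  configurable total-minutes distribution (defaults 5.59 / 5.33 min per day);
* clinical scores are noisy linear functions of the routine parameters, and
  supplemental scores are built to correlate with assigned targets, so joint
  inference has structure to exploit.

Every generated reading carries its true activity label, so the recognition,
marker, and inference stages can all be tested without any external corpus.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .vocab import (
    HOME_ACTIVITIES,
    HOME_REGIONS,
    LOCATION_TYPES,
    MOBILE_ACTIVITIES,
    TARGET_SCORES,
)

DAY_SECONDS = 86400
GRAVITY_G = 1.0  # vertical-axis baseline acceleration, in g


class ConfigurationError(ValueError):
    """Invalid generator configuration; message names the offending field."""


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


@dataclass
class ActivityBlock:
    """One scheduled activity block of a daily routine."""

    home_activity: str | None  # label in the ambient vocabulary, None if silent
    mobile_activity: str  # label in the watch vocabulary
    region: str | None  # home region hosting the block, None when out of home
    location_type: str  # home | road | work | other
    start_hour: float  # mean start, hours past midnight
    jitter_sd_min: float  # start-time jitter sd, minutes
    duration_min: float  # mean duration, minutes
    duration_sd_min: float
    days: str = "all"  # all | weekday | weekend
    intensity: float = 0.2  # accelerometer noise scale (g)
    gyro_scale: float = 30.0  # deg/s of rotation noise per unit intensity
    speed: float = 0.0  # mean speed, m/s
    one_class: str | None = None  # specialized context category, if any

    def __post_init__(self) -> None:
        if self.home_activity is not None and self.home_activity not in HOME_ACTIVITIES:
            raise ConfigurationError(f"home_activity {self.home_activity!r} not in vocabulary")
        if self.mobile_activity not in MOBILE_ACTIVITIES:
            raise ConfigurationError(f"mobile_activity {self.mobile_activity!r} not in vocabulary")
        if self.region is not None and self.region not in HOME_REGIONS:
            raise ConfigurationError(f"region {self.region!r} not in vocabulary")
        if self.location_type not in LOCATION_TYPES:
            raise ConfigurationError(f"location_type {self.location_type!r} not in vocabulary")


@dataclass
class RoutineProfile:
    """Per-participant routine parameters driving both sensor modalities."""

    participant_id: str
    wake_hour: float
    sleep_hour: float
    schedule: list[ActivityBlock]
    circadian_amplitude: float
    movement_intensity: float
    out_of_home_trips_per_day: int
    noise_event_interval_s: float = 3600.0  # mean gap between background firings

    def __post_init__(self) -> None:
        if not 0.0 <= self.circadian_amplitude <= 1.0:
            raise ConfigurationError("circadian_amplitude must lie in [0, 1]")
        if not (self.wake_hour % 24) < (self.sleep_hour % 24):
            raise ConfigurationError("wake_hour must precede sleep_hour within the day")

    def parameters(self) -> dict[str, float]:
        """The routine parameters clinical scores are derived from."""
        return {
            "wake_hour": self.wake_hour,
            "sleep_hour": self.sleep_hour,
            "sleep_duration": 24.0 - self.sleep_hour + self.wake_hour,
            "circadian_amplitude": self.circadian_amplitude,
            "movement_intensity": self.movement_intensity,
            "out_of_home_trips_per_day": float(self.out_of_home_trips_per_day),
        }


# Population-scale location of each routine parameter, used to standardize
# before applying effect maps.  Matches the sampling ranges in default_profile.
PARAMETER_SCALE: dict[str, tuple[float, float]] = {
    "wake_hour": (6.5, 0.75),
    "sleep_hour": (22.5, 0.75),
    "sleep_duration": (8.0, 1.0),
    "circadian_amplitude": (0.65, 0.145),
    "movement_intensity": (1.0, 0.173),
    "out_of_home_trips_per_day": (1.5, 0.5),
}

# Default mapping from standardized routine parameters to each target score's
# mean shift around 0.5 on the [0, 1] scale.  Cognitive scores load on
# circadian strength and schedule; mobility (TUG) loads negatively on
# movement intensity; functional self-reports load on both.
DEFAULT_EFFECT_MAP: dict[str, dict[str, float]] = {
    "WTAR": {"circadian_amplitude": 0.12, "movement_intensity": 0.05},
    "TICS": {"circadian_amplitude": 0.10, "wake_hour": -0.06},
    "RBANS": {"circadian_amplitude": 0.12, "out_of_home_trips_per_day": 0.05},
    "FAS": {"movement_intensity": 0.08, "circadian_amplitude": 0.06},
    "TUG": {"movement_intensity": -0.14},
    "DEX": {"circadian_amplitude": -0.08, "movement_intensity": -0.05},
    "ADLC": {"movement_intensity": 0.10, "out_of_home_trips_per_day": 0.05},
}


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_participants: int
    n_days: int = 30
    seed: int = 0
    gap_minutes_mean: float = 5.59
    gap_minutes_sd: float = 5.33
    n_supplemental_scores: int = 20
    score_noise_sd: float = 0.1
    score_correlation: float = 0.8
    effect_map: Mapping[str, Mapping[str, float]] | None = None
    start_date: str = "2024-03-04"  # a Monday, so calendar weeks align
    inject_gaps: bool = True
    separability: float = 1.0  # spread of activity intensity signatures

    def __post_init__(self) -> None:
        if self.n_participants < 3:
            raise ConfigurationError("n_participants must be >= 3 (LOSO needs >= 2 training subjects)")
        if self.n_days < 7:
            raise ConfigurationError("n_days must be >= 7 (weekly regularity needs a full week)")
        if self.gap_minutes_mean < 0 or self.gap_minutes_sd < 0:
            raise ConfigurationError("gap_minutes_mean/sd must be nonnegative")
        if not -1.0 <= self.score_correlation <= 1.0:
            raise ConfigurationError("score_correlation must lie in [-1, 1]")
        if self.n_supplemental_scores < 0:
            raise ConfigurationError("n_supplemental_scores must be nonnegative")
        emap = self.effect_map if self.effect_map is not None else DEFAULT_EFFECT_MAP
        missing = [t for t in TARGET_SCORES if t not in emap]
        if missing:
            raise ConfigurationError(f"effect_map missing target scores {missing}")


@dataclass
class GroundTruth:
    """Everything the generator knows that a real study would not observe."""

    profiles: dict[str, RoutineProfile]
    gap_spans: pd.DataFrame  # participant_id, date, start_s, n_seconds
    true_scores: pd.DataFrame  # noise-free target scores per participant


@dataclass
class ParticipantData:
    participant_id: str
    ambient: pd.DataFrame
    watch: pd.DataFrame
    demographics: pd.Series
    scores: pd.Series


# ---------------------------------------------------------------------------
# default routine
# ---------------------------------------------------------------------------


def default_profile(
    participant_id: str,
    rng: np.random.Generator,
    separability: float = 1.0,
) -> RoutineProfile:
    """Sample a realistic daily-routine profile for one participant.

    ``separability`` widens (>1) or narrows (<1) the gaps between activity
    intensity signatures; 1.0 is the default cohort condition.
    """
    wake = float(np.clip(rng.normal(6.5, 0.75), 5.0, 9.0))
    sleep = float(np.clip(rng.normal(22.5, 0.75), 21.0, 23.9))
    circ = float(rng.uniform(0.4, 0.9))
    mov = float(rng.uniform(0.7, 1.3))
    trips = int(rng.integers(1, 3))

    def inten(base: float) -> float:
        return base**(1.0 / separability) if separability != 1.0 else base

    B = ActivityBlock
    sched: list[ActivityBlock] = [
        # overnight sleep, split at midnight into two blocks
        B("Sleep", "Sleep", "Bedroom", "home", 0.0, 0.0, wake * 60, 10, intensity=inten(0.005), gyro_scale=10),
        B("Sleep", "Sleep", "Bedroom", "home", sleep, 12, (24 - sleep) * 60, 10, intensity=inten(0.005), gyro_scale=10),
        B("Bed-toilet transition", "Sleep", "Bathroom", "home", 3.0, 25, 6, 2, intensity=inten(0.05), gyro_scale=20),
        B("Personal hygiene", "Hygiene", "Bathroom", "home", wake + 0.05, 6, 25, 5, intensity=inten(0.22), gyro_scale=60, one_class="groom"),
        B("Cook", "Chores", "Kitchen", "home", wake + 0.6, 8, 25, 5, intensity=inten(0.45), gyro_scale=70, one_class="cook"),
        B("Eat", "Eat", "DiningRoom", "home", wake + 1.1, 8, 25, 5, intensity=inten(0.14), gyro_scale=45),
        B("Work", "Work", "Office", "home", 9.0, 15, 170, 20, days="weekday", intensity=inten(0.09), gyro_scale=12, one_class="computer"),
        B("Cook", "Chores", "Kitchen", "home", 12.1, 8, 15, 4, intensity=inten(0.45), gyro_scale=70, one_class="cook"),
        B("Eat", "Eat", "DiningRoom", "home", 12.5, 8, 25, 5, intensity=inten(0.14), gyro_scale=45, one_class="lunch"),
        B("Relax", "Chores", "Other", "home", 10.2, 15, 55, 10, days="weekend", intensity=inten(0.5), gyro_scale=75, one_class="chores"),
        B("Relax", "Relax", "LivingRoom", "home", 15.1, 15, 45, 10, intensity=inten(0.03), gyro_scale=8, one_class="relax"),
        B("Relax", "Exercise", "LivingRoom", "home", 16.4, 12, 40, 8, intensity=inten(1.0), gyro_scale=120, one_class="sport"),
        B("Cook", "Chores", "Kitchen", "home", 17.5, 10, 30, 6, intensity=inten(0.45), gyro_scale=70, one_class="cook"),
        B("Eat", "Eat", "DiningRoom", "home", 18.15, 8, 28, 5, intensity=inten(0.14), gyro_scale=45),
        B("Wash dishes", "Chores", "Kitchen", "home", 18.8, 8, 14, 3, intensity=inten(0.3), gyro_scale=55),
        B("Relax", "Entertainment", "LivingRoom", "home", 19.6, 15, 110, 15, intensity=inten(0.055), gyro_scale=15, one_class="entertainment"),
        B("Personal hygiene", "Hygiene", "Bathroom", "home", sleep - 0.35, 8, 15, 3, intensity=inten(0.22), gyro_scale=60, one_class="bathe"),
    ]
    # out-of-home trips: leave -> travel -> errands -> travel -> enter.
    # Sub-blocks share tight jitter and contiguous means so later-painted
    # segments do not swallow the short door-transition blocks.
    trip_starts = (13.6, 10.9)
    for k in range(min(trips, 2)):
        t0 = trip_starts[k]
        sched.extend(
            [
                B("Leave home", "Travel", "Entry", "home", t0, 1.5, 3, 0.5, intensity=inten(0.2), gyro_scale=40),
                B(None, "Travel", None, "road", t0 + 3 / 60, 1.5, 14, 2, intensity=inten(0.12), gyro_scale=25, speed=8.0, one_class="car"),
                B(None, "Errands", None, "other", t0 + 17 / 60, 1.5, 42, 4, intensity=inten(0.35), gyro_scale=65, speed=0.9, one_class="shop"),
                B(None, "Travel", None, "road", t0 + 59 / 60, 1.5, 14, 2, intensity=inten(0.12), gyro_scale=25, speed=8.0, one_class="car"),
                B("Enter home", "Travel", "Entry", "home", t0 + 73 / 60, 1.5, 3, 0.5, intensity=inten(0.2), gyro_scale=40),
            ]
        )
    return RoutineProfile(
        participant_id=participant_id,
        wake_hour=wake,
        sleep_hour=sleep,
        schedule=sched,
        circadian_amplitude=circ,
        movement_intensity=mov,
        out_of_home_trips_per_day=trips,
    )


# ---------------------------------------------------------------------------
# schedule resolution
# ---------------------------------------------------------------------------

#: filler block covering unscheduled at-home time
_FILLER = ActivityBlock("Relax", "Relax", "LivingRoom", "home", 0, 0, 0, 0, intensity=0.03, gyro_scale=8)


@dataclass
class ResolvedBlock:
    start_s: int
    end_s: int
    block: ActivityBlock


def resolve_schedule(
    profile: RoutineProfile, date: pd.Timestamp, rng: np.random.Generator
) -> list[ResolvedBlock]:
    """Realize one day of the profile's schedule.

    Start times and durations get Gaussian jitter.  Overlaps are resolved by
    painting blocks onto the day in schedule-list order, so a block listed
    later interrupts (truncates) an earlier one — e.g. a night bathroom visit
    cuts into the sleep block.  Uncovered time is filled with an at-home
    Relax filler, so every second has exactly one block.
    """
    weekday = pd.Timestamp(date).dayofweek < 5
    # paint block indices onto a per-minute canvas (-1 = filler)
    canvas = np.full(1440, -1, dtype=np.int32)
    active: list[ActivityBlock] = []
    for blk in profile.schedule:
        if blk.days == "weekday" and not weekday:
            continue
        if blk.days == "weekend" and weekday:
            continue
        start = blk.start_hour * 60 + rng.normal(0, blk.jitter_sd_min)
        dur = max(1.0, rng.normal(blk.duration_min, blk.duration_sd_min))
        s = int(np.clip(start, 0, 1439))
        e = int(np.clip(start + dur, s + 1, 1440))
        canvas[s:e] = len(active)
        active.append(blk)
    resolved: list[ResolvedBlock] = []
    boundaries = np.flatnonzero(np.diff(canvas) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [1440]))
    for s, e in zip(starts, ends):
        blk = _FILLER if canvas[s] < 0 else active[canvas[s]]
        resolved.append(ResolvedBlock(int(s) * 60, int(e) * 60, blk))
    return resolved


def _circadian_factor(profile: RoutineProfile, seconds: np.ndarray) -> np.ndarray:
    """Multiplicative 24-h modulation of movement, peaking mid-afternoon."""
    hours = seconds / 3600.0
    return 1.0 + 0.25 * profile.circadian_amplitude * np.cos(2 * np.pi * (hours - 14.0) / 24.0)


# ---------------------------------------------------------------------------
# watch stream
# ---------------------------------------------------------------------------


def simulate_watch_day_arrays(
    profile: RoutineProfile,
    date: str | pd.Timestamp,
    rng: np.random.Generator,
    schedule: list[ResolvedBlock] | None = None,
) -> dict[str, np.ndarray]:
    """Array form of one complete watch day (the fast internal path).

    Returns float channels plus integer label codes: ``loc_codes`` into the
    location-type vocabulary, ``act_codes`` into the watch activity
    vocabulary, and ``oc_codes`` into the one-class categories (-1 = none).
    Sample ``i`` is second ``i`` past local midnight.
    """
    from .vocab import MOBILE_ACTIVITIES as MACT
    from .vocab import ONE_CLASS_CATEGORIES as OCC

    date = pd.Timestamp(date).normalize()
    blocks = schedule if schedule is not None else resolve_schedule(profile, date, rng)
    n = DAY_SECONDS
    t = np.arange(n)

    intensity = np.empty(n)
    gyro_sd = np.empty(n)
    speed_mean = np.empty(n)
    loc_codes = np.empty(n, dtype=np.int8)
    act_codes = np.empty(n, dtype=np.int8)
    oc_codes = np.empty(n, dtype=np.int8)
    for rb in blocks:
        sl = slice(rb.start_s, rb.end_s)
        b = rb.block
        intensity[sl] = b.intensity
        gyro_sd[sl] = b.intensity * b.gyro_scale
        speed_mean[sl] = b.speed
        loc_codes[sl] = LOCATION_TYPES.index(b.location_type)
        act_codes[sl] = MACT.index(b.mobile_activity)
        oc_codes[sl] = OCC.index(b.one_class) if b.one_class else -1

    mod = profile.movement_intensity * _circadian_factor(profile, t)
    acc_sd = intensity * mod
    g_sd = gyro_sd * mod
    ax = rng.normal(0.0, 1.0, n) * acc_sd * 0.8
    ay = rng.normal(0.0, 1.0, n) * acc_sd * 0.8
    az = GRAVITY_G + rng.normal(0.0, 1.0, n) * acc_sd
    gx = rng.normal(0.0, 1.0, n) * g_sd
    gy = rng.normal(0.0, 1.0, n) * g_sd
    gz = rng.normal(0.0, 1.0, n) * g_sd * 0.6

    speed = np.maximum(0.0, speed_mean + rng.normal(0.0, 1.0, n) * (0.15 * speed_mean))
    moving = speed_mean > 0
    course = np.zeros(n)
    if moving.any():
        steps = rng.normal(0.0, 4.0, n) * moving
        course = np.mod(np.cumsum(steps), 360.0) * moving

    return {
        "ax": ax, "ay": ay, "az": az, "gx": gx, "gy": gy, "gz": gz,
        "course": course, "speed": speed,
        "loc_codes": loc_codes, "act_codes": act_codes, "oc_codes": oc_codes,
    }


def watch_frame_from_arrays(arrays: dict[str, np.ndarray], date: str | pd.Timestamp) -> pd.DataFrame:
    """DataFrame view of an array-form watch day (public representation)."""
    from .vocab import MOBILE_ACTIVITIES as MACT
    from .vocab import ONE_CLASS_CATEGORIES as OCC

    date = pd.Timestamp(date).normalize()
    n = len(arrays["ax"])
    oc_names = np.asarray(["", *OCC], dtype=object)
    return pd.DataFrame(
        {
            "timestamp": date + pd.to_timedelta(np.arange(n), unit="s"),
            **{k: arrays[k] for k in ("ax", "ay", "az", "gx", "gy", "gz", "course", "speed")},
            "location_type": np.asarray(LOCATION_TYPES, dtype=object)[arrays["loc_codes"]],
            "activity": np.asarray(MACT, dtype=object)[arrays["act_codes"]],
            "one_class": oc_names[arrays["oc_codes"] + 1],
        }
    )


def simulate_watch_day(
    profile: RoutineProfile,
    date: str | pd.Timestamp,
    rng: np.random.Generator,
    schedule: list[ResolvedBlock] | None = None,
) -> pd.DataFrame:
    """One complete day of 1 Hz watch samples with true labels.

    Columns: timestamp, ax..az (g), gx..gz (deg/s), course (deg),
    speed (m/s), location_type, activity (watch vocabulary), one_class.
    """
    date = pd.Timestamp(date).normalize()
    arrays = simulate_watch_day_arrays(profile, date, rng, schedule)
    return watch_frame_from_arrays(arrays, date)


# ---------------------------------------------------------------------------
# ambient events
# ---------------------------------------------------------------------------


def simulate_ambient_day(
    profile: RoutineProfile,
    date: str | pd.Timestamp,
    rng: np.random.Generator,
    schedule: list[ResolvedBlock] | None = None,
) -> pd.DataFrame:
    """One day of ambient sensor events with true labels.

    Motion firings cluster in the active block's region at a rate tied to the
    activity's intensity (each firing is an ON/OFF pair); Cook adds stove
    temperature readings and a cabinet door pair; hygiene toggles the bathroom
    light; entering/leaving home fires the entry door.  Background noise
    firings occur at a low rate while the participant is at home.
    """
    date = pd.Timestamp(date).normalize()
    blocks = schedule if schedule is not None else resolve_schedule(profile, date, rng)
    times: list[float] = []
    sensors: list[str] = []
    messages: list[str] = []
    labels: list[str] = []

    def emit(ts: float, sensor: str, message: str, label: str) -> None:
        times.append(ts)
        sensors.append(sensor)
        messages.append(message)
        labels.append(label)

    for rb in blocks:
        b = rb.block
        if b.location_type != "home" or b.region is None:
            continue
        label = b.home_activity or "Relax"
        span = rb.end_s - rb.start_s
        if b.home_activity in ("Enter home", "Leave home"):
            # door pair plus an entry motion firing at the transition
            t0 = rb.start_s + rng.uniform(0, max(1.0, span / 4))
            emit(t0, "Entry-Door-1", "OPEN", label)
            emit(t0 + rng.uniform(2, 8), "Entry-Door-1", "CLOSE", label)
            emit(t0 + rng.uniform(1, 6), "Entry-Motion-1", "ON", label)
            emit(t0 + rng.uniform(8, 14), "Entry-Motion-1", "OFF", label)
            continue
        interval = float(np.clip(12.0 / max(b.intensity * profile.movement_intensity, 0.01), 20.0, 600.0))
        n_fire = rng.poisson(span / interval)
        fire_t = np.sort(rng.uniform(rb.start_s, rb.end_s, n_fire))
        units = rng.integers(1, 3, n_fire)
        for ts, u in zip(fire_t, units):
            sensor = f"{b.region}-Motion-{u}"
            emit(ts, sensor, "ON", label)
            emit(ts + rng.uniform(1.5, 6.0), sensor, "OFF", label)
        if b.home_activity == "Cook":
            emit(rb.start_s + rng.uniform(5, 30), "Kitchen-Door-1", "OPEN", label)
            emit(rb.start_s + rng.uniform(35, 70), "Kitchen-Door-1", "CLOSE", label)
            for ts in np.arange(rb.start_s + 60, rb.end_s, 120.0):
                temp = 22.0 + 8.0 * (ts - rb.start_s) / max(span, 1)
                emit(ts + rng.uniform(-5, 5), "Kitchen-Temperature-1", f"{temp:.1f}", label)
        elif b.home_activity == "Personal hygiene":
            emit(rb.start_s + rng.uniform(0, 10), "Bathroom-Light-1", "ON", label)
            emit(rb.end_s - rng.uniform(0, 10), "Bathroom-Light-1", "OFF", label)
        # background noise firings while at home
        n_noise = rng.poisson(span / profile.noise_event_interval_s)
        for ts in rng.uniform(rb.start_s, rb.end_s, n_noise):
            region = HOME_REGIONS[rng.integers(0, len(HOME_REGIONS))]
            emit(ts, f"{region}-Motion-{rng.integers(1, 3)}", "ON", label)

    order = np.argsort(np.asarray(times), kind="stable")
    ts = np.asarray(times)[order]
    # enforce strictly increasing at millisecond resolution
    ts = np.round(ts, 3)
    for i in range(1, len(ts)):
        if ts[i] <= ts[i - 1]:
            ts[i] = ts[i - 1] + 0.001
    ts = np.minimum(ts, DAY_SECONDS - 0.001)
    for i in range(len(ts) - 2, -1, -1):
        if ts[i] >= ts[i + 1]:
            ts[i] = ts[i + 1] - 0.001
    return pd.DataFrame(
        {
            "timestamp": date + pd.to_timedelta(np.round(ts * 1000).astype(np.int64), unit="ms"),
            "sensor": np.asarray(sensors, dtype=object)[order],
            "message": np.asarray(messages, dtype=object)[order],
            "activity": np.asarray(labels, dtype=object)[order],
        }
    )


# ---------------------------------------------------------------------------
# watch gaps
# ---------------------------------------------------------------------------


def draw_gap_spans(
    dates: Sequence[pd.Timestamp],
    config: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample per-day gap placements (one or two contiguous spans per day)."""
    rows = []
    for date in dates:
        total_min = max(0.0, rng.normal(config.gap_minutes_mean, config.gap_minutes_sd))
        total_s = int(round(total_min * 60))
        if total_s <= 0:
            continue
        if total_s > DAY_SECONDS:
            raise ConfigurationError("daily gap exceeds the day length")
        n_gaps = 1 if total_s < 120 else int(rng.integers(1, 3))
        if n_gaps == 2:
            cut = int(rng.integers(60, total_s - 59))
            lengths = [cut, total_s - cut]
        else:
            lengths = [total_s]
        # place spans without overlap so removed samples equal the drawn total
        if len(lengths) == 1:
            starts = [int(rng.integers(0, DAY_SECONDS - lengths[0]))]
        else:
            l1, l2 = lengths
            s1 = int(rng.integers(0, DAY_SECONDS - l1 - l2))
            s2 = int(rng.integers(s1 + l1, DAY_SECONDS - l2))
            starts = [s1, s2]
        for start, length in zip(starts, lengths):
            rows.append({"date": pd.Timestamp(date).normalize(), "start_s": start, "n_seconds": length})
    return pd.DataFrame(rows, columns=["date", "start_s", "n_seconds"])


def inject_watch_gaps(
    stream: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove watch-transition gap spans from a complete 1 Hz stream.

    Returns the gapped stream and the realized gap spans.  Overlapping spans
    within a day are merged by the row mask, so the number of removed samples
    equals the total masked seconds exactly.
    """
    ts = stream["timestamp"]
    dates = sorted(ts.dt.normalize().unique())
    spans = draw_gap_spans(dates, config, rng)
    if spans.empty:
        return stream.copy(), spans
    sec = (ts - ts.dt.normalize()).dt.total_seconds().to_numpy()
    day = ts.dt.normalize().to_numpy()
    keep = np.ones(len(stream), dtype=bool)
    for row in spans.itertuples(index=False):
        mask = (day == np.datetime64(row.date)) & (sec >= row.start_s) & (sec < row.start_s + row.n_seconds)
        keep &= ~mask
    return stream.loc[keep].reset_index(drop=True), spans


# ---------------------------------------------------------------------------
# clinical scores and demographics
# ---------------------------------------------------------------------------


def _standardized_parameters(profile: RoutineProfile) -> dict[str, float]:
    out = {}
    for name, value in profile.parameters().items():
        mu, sd = PARAMETER_SCALE[name]
        out[name] = (value - mu) / sd
    return out


def derive_clinical_scores(
    profile: RoutineProfile,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Targets, supplementals, and noise-free targets for one participant.

    Each target is 0.5 plus a linear combination of standardized routine
    parameters (the effect map) plus Gaussian noise, clipped to [0, 1].
    Supplemental score ``k`` is built from its assigned target's standardized
    value so that corr(supplemental, target) ~= ``score_correlation``.
    """
    emap = config.effect_map if config.effect_map is not None else DEFAULT_EFFECT_MAP
    z = _standardized_parameters(profile)
    true_vals: dict[str, float] = {}
    noisy_vals: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name in TARGET_SCORES:
        weights = emap[name]
        unknown = [p for p in weights if p not in z and p != "intercept"]
        if unknown:
            raise ConfigurationError(f"effect_map for {name} uses unknown parameters {unknown}")
        mean = 0.5 + weights.get("intercept", 0.0) + sum(w * z[p] for p, w in weights.items() if p != "intercept")
        noise = rng.normal(0.0, config.score_noise_sd) if config.score_noise_sd > 0 else 0.0
        true_vals[name] = float(np.clip(mean, 0.0, 1.0))
        noisy_vals[name] = float(np.clip(mean + noise, 0.0, 1.0))
        sds[name] = float(
            np.sqrt(sum(w**2 for p, w in weights.items() if p != "intercept") + config.score_noise_sd**2)
        )

    rho = config.score_correlation
    sup_vals: dict[str, float] = {}
    for k in range(config.n_supplemental_scores):
        target = TARGET_SCORES[k % len(TARGET_SCORES)]
        zt = (noisy_vals[target] - 0.5) / max(sds[target], 1e-12)
        eps = rng.normal()
        sup_vals[f"sup_{k:02d}"] = float(
            np.clip(0.5 + 0.15 * (rho * zt + np.sqrt(max(0.0, 1 - rho**2)) * eps), 0.0, 1.0)
        )
    return (
        pd.Series(noisy_vals, name=profile.participant_id),
        pd.Series(sup_vals, name=profile.participant_id),
        pd.Series(true_vals, name=profile.participant_id),
    )


def sample_demographics(participant_id: str, rng: np.random.Generator) -> pd.Series:
    """A small numeric demographic vector (age, gender, education, race,
    count of preexisting conditions)."""
    return pd.Series(
        {
            "age": float(np.clip(rng.normal(69.0, 10.9), 45.0, 95.0)),
            "gender_female": float(rng.random() < 16 / 21),
            "education_years": float(np.clip(rng.normal(16.0, 2.5), 8.0, 22.0)),
            "race_category": float(rng.integers(0, 5)),
            "n_conditions": float(min(int(rng.poisson(0.8)), 3)),
        },
        name=participant_id,
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def participant_rng(seed: int, p_idx: int, *extra: int) -> np.random.Generator:
    """Deterministic child generator for (seed, participant, ...) keys."""
    return np.random.default_rng([seed, p_idx, *extra])


def cohort_dates(config: CohortConfig) -> pd.DatetimeIndex:
    return pd.date_range(config.start_date, periods=config.n_days, freq="D")


def cohort_profiles(config: CohortConfig) -> dict[str, RoutineProfile]:
    profiles = {}
    for p in range(config.n_participants):
        pid = f"P{p:03d}"
        profiles[pid] = default_profile(pid, participant_rng(config.seed, p, 0), config.separability)
    return profiles


def iter_participant_days(
    config: CohortConfig,
    profile: RoutineProfile,
    p_idx: int,
) -> Iterator[tuple[pd.Timestamp, pd.DataFrame, dict[str, np.ndarray]]]:
    """Yield (date, ambient events, complete watch day in array form), one
    day at a time.

    Memory-friendly generator used by the marker pipeline at cohort scale;
    gap injection is applied separately so the complete stream is available
    to ground truth.  Convert the array form with
    :func:`watch_frame_from_arrays` when a DataFrame is needed.
    """
    for d, date in enumerate(cohort_dates(config)):
        rng = participant_rng(config.seed, p_idx, 1, d)
        schedule = resolve_schedule(profile, date, rng)
        ambient = simulate_ambient_day(profile, date, rng, schedule)
        watch = simulate_watch_day_arrays(profile, date, rng, schedule)
        yield date, ambient, watch


def generate_cohort(config: CohortConfig) -> tuple[list[ParticipantData], GroundTruth]:
    """Materialize the full synthetic cohort.

    Deterministic in ``config.seed``; every sensor reading carries its true
    activity label.  For large cohorts prefer :func:`iter_participant_days`
    plus the marker pipeline, which does not hold whole streams in memory.
    """
    profiles = cohort_profiles(config)
    participants: list[ParticipantData] = []
    all_gaps = []
    true_rows = []
    for p, (pid, profile) in enumerate(profiles.items()):
        ambient_days = []
        watch_days = []
        for date, ambient, watch_arrays in iter_participant_days(config, profile, p):
            ambient_days.append(ambient)
            watch_days.append(watch_frame_from_arrays(watch_arrays, date))
        ambient = pd.concat(ambient_days, ignore_index=True)
        watch = pd.concat(watch_days, ignore_index=True)
        if config.inject_gaps:
            watch, spans = inject_watch_gaps(watch, config, participant_rng(config.seed, p, 2))
            spans.insert(0, "participant_id", pid)
            all_gaps.append(spans)
        targets, sups, true = derive_clinical_scores(profile, config, participant_rng(config.seed, p, 3))
        demo = sample_demographics(pid, participant_rng(config.seed, p, 4))
        participants.append(
            ParticipantData(
                participant_id=pid,
                ambient=ambient,
                watch=watch,
                demographics=demo,
                scores=pd.concat([targets, sups]),
            )
        )
        true_rows.append(true)
    gap_spans = (
        pd.concat(all_gaps, ignore_index=True)
        if all_gaps
        else pd.DataFrame(columns=["participant_id", "date", "start_s", "n_seconds"])
    )
    truth = GroundTruth(profiles=profiles, gap_spans=gap_spans, true_scores=pd.DataFrame(true_rows))
    return participants, truth


def cohort_scores(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Demographics, scores, and noise-free targets without simulating streams."""
    profiles = cohort_profiles(config)
    demo_rows, score_rows, true_rows = [], [], []
    for p, (pid, profile) in enumerate(profiles.items()):
        targets, sups, true = derive_clinical_scores(profile, config, participant_rng(config.seed, p, 3))
        demo_rows.append(sample_demographics(pid, participant_rng(config.seed, p, 4)))
        score_rows.append(pd.concat([targets, sups]))
        true_rows.append(true)
    return pd.DataFrame(demo_rows), pd.DataFrame(score_rows), pd.DataFrame(true_rows)


def replace_profile(profile: RoutineProfile, **updates) -> RoutineProfile:
    """Dataclass-style copy with field updates (schedule list is shared)."""
    return dataclasses.replace(profile, **updates)
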