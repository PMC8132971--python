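"""Windowing and per-window feature extraction for activity recognition.

Ambient streams are segmented into sliding windows of the 30 most recent
events ending at the event being labeled (stride 1; the start of a stream is
left-padded by replicating its first event, so every reading gets a window).
Watch streams are segmented into consecutive non-overlapping 5 s windows (5
samples at 1 Hz); every sample inherits its window's label.

Feature vectors have a fixed documented ordering per modality and never
contain missing values: statistics that are undefined on a degenerate window
(autocorrelation or skewness of a constant window, direction at zero
distance, ...) are 0 by convention.

All extractors are pure functions of the window (plus, for the watch, a
per-person location context), implemented as vectorized batch operations
over whole streams; the single-window entry points delegate to the batch
path so both views are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vocab import (
    HOME_REGIONS,
    LOCATION_TYPES,
    SENSOR_KEYS,
    SENSOR_TYPES,
    TIME_OF_DAY_BINS,
    WATCH_CHANNELS,
)

AMBIENT_WINDOW_EVENTS = 30
MOBILE_WINDOW_SECONDS = 5
STOP_SPEED_THRESHOLD = 0.5  # m/s
ELAPSED_SENTINEL = 86400.0

_N_SENSOR_KEYS = len(SENSOR_KEYS)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_ambient(n_events: int) -> np.ndarray:
    """(n, 30) event-index matrix; one stride-1 window per event, left-padded
    by replicating index 0."""
    if n_events == 0:
        return np.empty((0, AMBIENT_WINDOW_EVENTS), dtype=int)
    offsets = np.arange(-(AMBIENT_WINDOW_EVENTS - 1), 1)
    return np.maximum(np.arange(n_events)[:, None] + offsets[None, :], 0)


def segment_mobile(n_samples: int) -> int:
    """Number of complete non-overlapping 5 s windows in a sample count."""
    return n_samples // MOBILE_WINDOW_SECONDS


def window_labels_mobile(labels: np.ndarray) -> np.ndarray:
    """Ground-truth label of each 5 s window: the modal label of its samples."""
    n_win = segment_mobile(len(labels))
    lab = np.asarray(labels, dtype=object)[: n_win * MOBILE_WINDOW_SECONDS]
    lab = lab.reshape(n_win, MOBILE_WINDOW_SECONDS)
    out = np.empty(n_win, dtype=object)
    for i in range(n_win):
        vals, counts = np.unique(lab[i], return_counts=True)
        out[i] = vals[np.argmax(counts)]
    return out


def expand_window_labels(window_labels: np.ndarray, n_samples: int) -> np.ndarray:
    """Per-sample labels from per-window labels; trailing remainder samples
    inherit the final window's label."""
    if len(window_labels) == 0:
        return np.empty(0, dtype=object)
    idx = np.minimum(np.arange(n_samples) // MOBILE_WINDOW_SECONDS, len(window_labels) - 1)
    return np.asarray(window_labels, dtype=object)[idx]


# ---------------------------------------------------------------------------
# ambient features
# ---------------------------------------------------------------------------


def ambient_feature_names() -> list[str]:
    names = ["hour", "seconds_past_midnight", "day_of_week", "window_duration", "time_since_previous"]
    names += [f"dominant_current_{k}" for k in SENSOR_KEYS]
    names += [f"dominant_previous_{k}" for k in SENSOR_KEYS]
    names += [f"last_sensor_{k}" for k in SENSOR_KEYS]
    names += [f"last_motion_region_{r}" for r in HOME_REGIONS]
    names += ["window_entropy", "n_location_changes", "n_distinct_sensors"]
    names += [f"count_{k}" for k in SENSOR_KEYS]
    names += [f"elapsed_{k}" for k in SENSOR_KEYS]
    return names


def _sensor_codes(sensors: pd.Series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(region code, type code, region x type code) per event."""
    parts = sensors.str.split("-", n=2, expand=True)
    region = pd.Categorical(parts[0], categories=HOME_REGIONS).codes.astype(int)
    stype = pd.Categorical(parts[1], categories=SENSOR_TYPES).codes.astype(int)
    if (region < 0).any() or (stype < 0).any():
        bad = int(np.flatnonzero((region < 0) | (stype < 0))[0])
        raise ValueError(f"unknown sensor identifier {sensors.iloc[bad]!r}")
    return region, stype, region * len(SENSOR_TYPES) + stype


def extract_ambient_features_batch(events: pd.DataFrame) -> pd.DataFrame:
    """Feature matrix with one row per event (per sliding window)."""
    n = len(events)
    names = ambient_feature_names()
    if n == 0:
        return pd.DataFrame(columns=names)
    ts = events["timestamp"]
    abs_sec = (ts - ts.dt.normalize().min()) / pd.Timedelta(seconds=1)
    abs_sec = abs_sec.to_numpy(dtype=float)
    day_sec = ((ts - ts.dt.normalize()) / pd.Timedelta(seconds=1)).to_numpy(dtype=float)
    region, stype, rt = _sensor_codes(events["sensor"])

    start_idx = np.maximum(np.arange(n) - (AMBIENT_WINDOW_EVENTS - 1), 0)
    pad = (AMBIENT_WINDOW_EVENTS - 1) - (np.arange(n) - start_idx)  # replicated copies of event 0

    onehot_cum = np.zeros((n + 1, _N_SENSOR_KEYS))
    np.add.at(onehot_cum, (np.arange(n) + 1, rt), 1.0)
    np.cumsum(onehot_cum, axis=0, out=onehot_cum)
    counts = onehot_cum[np.arange(n) + 1] - onehot_cum[start_idx]
    counts[:, rt[0]] += pad  # left padding replicates the first event

    dominant = np.argmax(counts, axis=1)
    dominant_prev = np.concatenate(([dominant[0]], dominant[:-1]))

    probs = counts / AMBIENT_WINDOW_EVENTS
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    entropy = -plogp.sum(axis=1)

    change = np.concatenate(([0], (region[1:] != region[:-1]).astype(float)))
    change_cum = np.concatenate(([0.0], np.cumsum(change)))
    n_changes = change_cum[np.arange(n) + 1] - change_cum[start_idx + 1] + 0.0
    # padded (replicated) events introduce no changes

    distinct = (counts > 0).sum(axis=1).astype(float)

    # last observed time per sensor key, at or before each event
    time_by_sensor = np.full((n, _N_SENSOR_KEYS), -np.inf)
    time_by_sensor[np.arange(n), rt] = abs_sec
    np.maximum.accumulate(time_by_sensor, axis=0, out=time_by_sensor)
    prev_time = np.vstack([np.full(_N_SENSOR_KEYS, -np.inf), time_by_sensor[:-1]])
    # elapsed since that sensor's previous reading (excluding the current one)
    own_prev = prev_time.copy()
    elapsed = abs_sec[:, None] - own_prev
    elapsed[~np.isfinite(elapsed)] = ELAPSED_SENTINEL
    elapsed = np.minimum(elapsed, ELAPSED_SENTINEL)

    # last motion-sensor region (forward-filled)
    is_motion = stype == SENSOR_TYPES.index("Motion")
    motion_region = np.where(is_motion, region, -1)
    motion_ffill = np.maximum.accumulate(
        np.where(is_motion, np.arange(n), -1)
    )
    last_motion_region = np.where(motion_ffill >= 0, region[np.maximum(motion_ffill, 0)], -1)

    data: dict[str, np.ndarray] = {
        "hour": np.floor(day_sec / 3600.0),
        "seconds_past_midnight": day_sec,
        "day_of_week": ts.dt.dayofweek.to_numpy(dtype=float),
        "window_duration": abs_sec - abs_sec[start_idx],
        "time_since_previous": np.diff(abs_sec, prepend=abs_sec[0]),
    }
    eye = np.eye(_N_SENSOR_KEYS)
    dom_oh = eye[dominant]
    dom_prev_oh = eye[dominant_prev]
    last_oh = eye[rt]
    for j, k in enumerate(SENSOR_KEYS):
        data[f"dominant_current_{k}"] = dom_oh[:, j]
    for j, k in enumerate(SENSOR_KEYS):
        data[f"dominant_previous_{k}"] = dom_prev_oh[:, j]
    for j, k in enumerate(SENSOR_KEYS):
        data[f"last_sensor_{k}"] = last_oh[:, j]
    region_eye = np.eye(len(HOME_REGIONS))
    lm_oh = np.where(
        (last_motion_region >= 0)[:, None],
        region_eye[np.maximum(last_motion_region, 0)],
        0.0,
    )
    for j, r in enumerate(HOME_REGIONS):
        data[f"last_motion_region_{r}"] = lm_oh[:, j]
    data["window_entropy"] = entropy
    data["n_location_changes"] = n_changes
    data["n_distinct_sensors"] = distinct
    for j, k in enumerate(SENSOR_KEYS):
        data[f"count_{k}"] = counts[:, j]
    for j, k in enumerate(SENSOR_KEYS):
        data[f"elapsed_{k}"] = elapsed[:, j]
    del motion_region
    return pd.DataFrame(data, columns=names)


def extract_ambient_features(window: pd.DataFrame) -> pd.Series:
    """Features of one 30-event window (the label attaches to its last event)."""
    if len(window) != AMBIENT_WINDOW_EVENTS:
        raise ValueError(f"ambient window must hold exactly {AMBIENT_WINDOW_EVENTS} events")
    return extract_ambient_features_batch(window.reset_index(drop=True)).iloc[-1]


# ---------------------------------------------------------------------------
# person location context
# ---------------------------------------------------------------------------


@dataclass
class PersonContext:
    """Per-person location statistics used by mobile feature extraction.

    Positions are dead-reckoned from speed and heading within each day (the
    package carries no raw coordinates), so the mean location and distance
    scale are in meters relative to the daily start point.
    """

    mean_position: tuple[float, float] = (0.0, 0.0)
    distance_scale: float = 1.0
    top_locations: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {b: () for b in TIME_OF_DAY_BINS}
    )


def _dead_reckon(stream: pd.DataFrame) -> np.ndarray:
    """(n, 2) cumulative positions from speed (m/s) and course (deg),
    restarted at each day boundary."""
    theta = np.deg2rad(stream["course"].to_numpy(dtype=float))
    speed = stream["speed"].to_numpy(dtype=float)
    dx = speed * np.cos(theta)
    dy = speed * np.sin(theta)
    days = stream["timestamp"].dt.normalize().to_numpy()
    pos = np.empty((len(stream), 2))
    pos[:, 0] = np.cumsum(dx)
    pos[:, 1] = np.cumsum(dy)
    # subtract the day-start offset so each day starts at the origin (home)
    starts = np.flatnonzero(np.concatenate(([True], days[1:] != days[:-1])))
    day_idx = np.searchsorted(starts, np.arange(len(stream)), side="right") - 1
    base = np.vstack([[0.0, 0.0], pos[starts[1:] - 1]]) if len(starts) > 1 else np.zeros((1, 2))
    pos -= base[day_idx]
    return pos


def person_context(stream: pd.DataFrame) -> PersonContext:
    """Mean location, distance scale, and top-3 frequented location types per
    time-of-day bin, from a person's (possibly multi-day) watch history."""
    if len(stream) == 0:
        return PersonContext()
    pos = _dead_reckon(stream)
    mean_pos = pos.mean(axis=0)
    dist = np.linalg.norm(pos - mean_pos, axis=1)
    scale = float(max(dist.max(), 1.0))
    hours = ((stream["timestamp"] - stream["timestamp"].dt.normalize()).dt.total_seconds() / 3600).to_numpy()
    bins = np.select(
        [hours < 6, hours < 12, hours < 18], ["night", "morning", "afternoon"], "evening"
    )
    top: dict[str, tuple[str, ...]] = {}
    loc = stream["location_type"].to_numpy()
    for b in TIME_OF_DAY_BINS:
        mask = bins == b
        if not mask.any():
            top[b] = ()
            continue
        counts = pd.Series(loc[mask]).value_counts()
        top[b] = tuple(counts.index[:3])
    return PersonContext((float(mean_pos[0]), float(mean_pos[1])), scale, top)


# ---------------------------------------------------------------------------
# mobile features
# ---------------------------------------------------------------------------

_CHANNEL_STATS = (
    "max",
    "min",
    "sum",
    "mean",
    "median",
    "mean_abs",
    "median_abs",
    "sd",
    "mean_abs_dev",
    "median_abs_dev",
    "moment2",
    "moment3",
    "moment4",
    "fft_mag_mean",
    "fft_mag_var",
    "cv",
    "skewness",
    "kurtosis",
    "energy",
    "log_energy",
    "power",
    "autocorr",
    "mean_abs_succ_diff",
    "time_between_peaks",
)

_AXIS_PAIRS = (
    ("ax", "ay"),
    ("ax", "az"),
    ("ay", "az"),
    ("gx", "gy"),
    ("gx", "gz"),
    ("gy", "gz"),
)


def mobile_feature_names() -> list[str]:
    names = [f"{ch}_{st}" for ch in WATCH_CHANNELS for st in _CHANNEL_STATS]
    names += [f"corr_{a}_{b}" for a, b in _AXIS_PAIRS]
    names += ["heading_change_rate", "stop_rate", "trajectory", "distance_traveled"]
    names += [f"loctype_{lt}" for lt in LOCATION_TYPES]
    names += ["dist_from_mean_location", "direction_from_mean_location", "in_top_locations"]
    return names


def _channel_stats(W: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized per-window statistics of one channel, W of shape (n, 5)."""
    n_w = W.shape[1]
    mean = W.mean(axis=1)
    med = np.median(W, axis=1)
    centered = W - mean[:, None]
    m2 = (centered**2).mean(axis=1)
    sd = np.sqrt(m2)
    m3 = (centered**3).mean(axis=1)
    m4 = (centered**4).mean(axis=1)
    nonzero_sd = sd > 0
    energy = (W**2).sum(axis=1)
    fft_mag = np.abs(np.fft.rfft(W, axis=1))
    succ = np.abs(np.diff(W, axis=1))

    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(nonzero_sd, m3 / np.where(nonzero_sd, sd, 1.0) ** 3, 0.0)
        kurt = np.where(nonzero_sd, m4 / np.where(nonzero_sd, m2, 1.0) ** 2, 0.0)
        cv = np.where(mean != 0, sd / np.abs(np.where(mean != 0, mean, 1.0)), 0.0)

    # lag-1 autocorrelation within the window; 0 for constant windows
    a, b = W[:, :-1], W[:, 1:]
    am = a.mean(axis=1)[:, None]
    bm = b.mean(axis=1)[:, None]
    num = ((a - am) * (b - bm)).sum(axis=1)
    den = np.sqrt(((a - am) ** 2).sum(axis=1) * ((b - bm) ** 2).sum(axis=1))
    autocorr = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    # peaks: interior local maxima exceeding mean + 1 sd; mean spacing of
    # consecutive peaks reduces to (last - first) / (count - 1)
    interior = W[:, 1:-1]
    is_peak = (interior > W[:, :-2]) & (interior > W[:, 2:]) & (interior > (mean + sd)[:, None])
    pk_count = is_peak.sum(axis=1)
    pos = np.arange(1, n_w - 1)
    first = np.where(is_peak.any(axis=1), np.argmax(is_peak, axis=1) + 1, 0)
    last = np.where(is_peak.any(axis=1), n_w - 2 - np.argmax(is_peak[:, ::-1], axis=1), 0)
    tbp = np.where(pk_count >= 2, (last - first) / np.maximum(pk_count - 1, 1), 0.0)
    del pos

    with np.errstate(divide="ignore"):
        log_energy = np.where(energy > 0, np.log(np.where(energy > 0, energy, 1.0)), 0.0)

    return {
        "max": W.max(axis=1),
        "min": W.min(axis=1),
        "sum": W.sum(axis=1),
        "mean": mean,
        "median": med,
        "mean_abs": np.abs(W).mean(axis=1),
        "median_abs": np.median(np.abs(W), axis=1),
        "sd": sd,
        "mean_abs_dev": np.abs(centered).mean(axis=1),
        "median_abs_dev": np.median(np.abs(W - med[:, None]), axis=1),
        "moment2": m2,
        "moment3": m3,
        "moment4": m4,
        "fft_mag_mean": fft_mag.mean(axis=1),
        "fft_mag_var": fft_mag.var(axis=1),
        "cv": cv,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": energy,
        "log_energy": log_energy,
        "power": energy / n_w,
        "autocorr": autocorr,
        "mean_abs_succ_diff": succ.mean(axis=1),
        "time_between_peaks": tbp,
    }


def extract_mobile_features_batch(
    stream: pd.DataFrame, context: PersonContext | None = None
) -> pd.DataFrame:
    """Feature matrix with one row per complete 5 s window of a watch stream.

    The stream should already be low-pass filtered
    (:func:`behaviorome.filters.lowpass_stream`).
    """
    context = context or PersonContext()
    n_win = segment_mobile(len(stream))
    names = mobile_feature_names()
    if n_win == 0:
        return pd.DataFrame(columns=names)
    m = n_win * MOBILE_WINDOW_SECONDS
    data: dict[str, np.ndarray] = {}
    for ch in WATCH_CHANNELS:
        W = stream[ch].to_numpy(dtype=float)[:m].reshape(n_win, MOBILE_WINDOW_SECONDS)
        for st, vals in _channel_stats(W).items():
            data[f"{ch}_{st}"] = vals

    wins = {
        ch: stream[ch].to_numpy(dtype=float)[:m].reshape(n_win, MOBILE_WINDOW_SECONDS)
        for ch in WATCH_CHANNELS
    }
    for a, b in _AXIS_PAIRS:
        A, B = wins[a], wins[b]
        Ac = A - A.mean(axis=1)[:, None]
        Bc = B - B.mean(axis=1)[:, None]
        den = np.sqrt((Ac**2).sum(axis=1) * (Bc**2).sum(axis=1))
        data[f"corr_{a}_{b}"] = np.where(den > 0, (Ac * Bc).sum(axis=1) / np.where(den > 0, den, 1.0), 0.0)

    course = wins["course"]
    dc = np.abs(np.diff(course, axis=1))
    dc = np.minimum(dc, 360.0 - dc)  # wrap
    data["heading_change_rate"] = dc.mean(axis=1)
    speed = wins["speed"]
    data["stop_rate"] = (speed < STOP_SPEED_THRESHOLD).mean(axis=1)
    theta = np.deg2rad(course)
    data["trajectory"] = np.hypot(
        (speed * np.cos(theta)).sum(axis=1), (speed * np.sin(theta)).sum(axis=1)
    )
    data["distance_traveled"] = speed.sum(axis=1)

    loc = stream["location_type"].to_numpy()[:m].reshape(n_win, MOBILE_WINDOW_SECONDS)
    loc_codes = pd.Categorical(loc.ravel(), categories=LOCATION_TYPES).codes.reshape(
        n_win, MOBILE_WINDOW_SECONDS
    )
    modal = np.empty(n_win, dtype=int)
    counts = np.zeros((n_win, len(LOCATION_TYPES)))
    for j in range(len(LOCATION_TYPES)):
        counts[:, j] = (loc_codes == j).sum(axis=1)
    modal = counts.argmax(axis=1)
    eye = np.eye(len(LOCATION_TYPES))
    loc_oh = eye[modal]
    for j, lt in enumerate(LOCATION_TYPES):
        data[f"loctype_{lt}"] = loc_oh[:, j]

    pos = _dead_reckon(stream)[:m]
    end_pos = pos[MOBILE_WINDOW_SECONDS - 1 :: MOBILE_WINDOW_SECONDS][:n_win]
    rel = end_pos - np.asarray(context.mean_position)
    dist = np.linalg.norm(rel, axis=1)
    data["dist_from_mean_location"] = dist / max(context.distance_scale, 1e-9)
    data["direction_from_mean_location"] = np.where(dist > 0, np.arctan2(rel[:, 1], rel[:, 0]), 0.0)

    ts = stream["timestamp"].iloc[MOBILE_WINDOW_SECONDS - 1 :: MOBILE_WINDOW_SECONDS][:n_win]
    hours = ((ts - ts.dt.normalize()).dt.total_seconds() / 3600).to_numpy()
    bins = np.select([hours < 6, hours < 12, hours < 18], ["night", "morning", "afternoon"], "evening")
    modal_names = np.asarray(LOCATION_TYPES, dtype=object)[modal]
    in_top = np.array(
        [1.0 if modal_names[i] in context.top_locations.get(bins[i], ()) else 0.0 for i in range(n_win)]
    )
    data["in_top_locations"] = in_top
    return pd.DataFrame(data, columns=names)


def extract_mobile_features(window: pd.DataFrame, context: PersonContext | None = None) -> pd.Series:
    """Features of one 5-sample window."""
    if len(window) != MOBILE_WINDOW_SECONDS:
        raise ValueError(f"mobile window must hold exactly {MOBILE_WINDOW_SECONDS} samples")
    return extract_mobile_features_batch(window.reset_index(drop=True), context).iloc[0]
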