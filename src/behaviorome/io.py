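"""Readers and writers for the package's plain-text artifacts.

Two stream dialects are defined:

* **Event log** — one ambient sensor state change per row:
  ``timestamp,sensor,message[,activity]``.  ``sensor`` is ``Region-Type`` with
  an optional trailing unit index (``Kitchen-Motion-2``); region and type must
  come from the fixed vocabularies.  Timestamps are timezone-naive ISO-8601
  with millisecond precision.
* **Watch stream** — one 1 Hz sample per row:
  ``timestamp,ax,ay,az,gx,gy,gz,course,speed,location_type[,activity]``.
  Numeric channels round-trip exactly at 6 decimal places.  Missing grid
  seconds are represented by absent rows and surfaced as explicit gap spans.

Both readers validate vocabulary tokens and report offending line numbers;
out-of-order timestamps produce a warning and a stable sort rather than a
silent reorder.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .vocab import HOME_REGIONS, LOCATION_TYPES, SENSOR_TYPES, WATCH_CHANNELS

TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M:%S.%f"

EVENT_COLUMNS = ["timestamp", "sensor", "message"]
WATCH_COLUMNS = ["timestamp", *WATCH_CHANNELS, "location_type"]


class ParseError(ValueError):
    """Malformed artifact file; message carries the file and line number."""


def split_sensor(sensor: str) -> tuple[str, str]:
    """Return (region, type) of a sensor identifier, validating both tokens."""
    parts = sensor.split("-")
    if len(parts) < 2:
        raise ParseError(f"sensor id {sensor!r} is not Region-Type[-index]")
    region, stype = parts[0], parts[1]
    if region not in HOME_REGIONS:
        raise ParseError(f"unknown region {region!r} in sensor id {sensor!r}")
    if stype not in SENSOR_TYPES:
        raise ParseError(f"unknown sensor type {stype!r} in sensor id {sensor!r}")
    return region, stype


def _check_sorted(df: pd.DataFrame, path: object) -> pd.DataFrame:
    if not df["timestamp"].is_monotonic_increasing:
        warnings.warn(f"{path}: timestamps out of order; applying stable sort")
        df = df.sort_values("timestamp", kind="stable", ignore_index=True)
    return df


def read_event_log(path: str | Path, permissive: bool = False) -> pd.DataFrame:
    """Read an ambient event log.

    With ``permissive=True``, whitespace-separated legacy lines
    (``date time sensor message [activity]``) are also accepted.
    """
    path = Path(path)
    if permissive:
        rows = []
        with open(path) as fh:
            header = fh.readline()
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                toks = line.replace(",", " ").split()
                if len(toks) < 4:
                    raise ParseError(f"{path}:{lineno}: expected at least 4 fields")
                rows.append(
                    [f"{toks[0]} {toks[1]}", toks[2], toks[3]]
                    + ([" ".join(toks[4:])] if len(toks) > 4 else [])
                )
        ncol = max(len(r) for r in rows) if rows else 3
        cols = EVENT_COLUMNS + (["activity"] if ncol > 3 else [])
        df = pd.DataFrame([r + [""] * (len(cols) - len(r)) for r in rows], columns=cols)
        del header
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="mixed")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: unparseable timestamp: {exc}") from None
    for i, sensor in enumerate(df["sensor"]):
        try:
            split_sensor(sensor)
        except ParseError as exc:
            raise ParseError(f"{path}:{i + 2}: {exc}") from None
    return _check_sorted(df, path)


def write_event_log(events: pd.DataFrame, path: str | Path) -> None:
    df = events.copy()
    df["timestamp"] = df["timestamp"].dt.strftime(TIMESTAMP_FORMAT).str[:-3]
    df.to_csv(path, index=False)


def read_watch_stream(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = [c for c in WATCH_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="mixed")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: unparseable timestamp: {exc}") from None
    bad = ~df["location_type"].isin(LOCATION_TYPES)
    if bad.any():
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(
            f"{path}:{lineno}: unknown location_type "
            f"{df['location_type'].iloc[lineno - 2]!r}"
        )
    for ch in WATCH_CHANNELS:
        df[ch] = df[ch].astype(float)
    return _check_sorted(df, path)


def write_watch_stream(stream: pd.DataFrame, path: str | Path) -> None:
    df = stream.copy()
    df["timestamp"] = df["timestamp"].dt.strftime(TIMESTAMP_FORMAT).str[:-3]
    for ch in WATCH_CHANNELS:
        df[ch] = df[ch].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)


def watch_gap_spans(stream: pd.DataFrame) -> pd.DataFrame:
    """Missing 1 Hz grid seconds between the stream's first and last sample.

    Returns a frame with ``start`` (first missing second), ``end`` (first
    present second after the gap) and ``n_seconds``.
    """
    ts = stream["timestamp"].to_numpy()
    if len(ts) < 2:
        return pd.DataFrame(columns=["start", "end", "n_seconds"])
    deltas = np.diff(ts) / np.timedelta64(1, "s")
    idx = np.flatnonzero(deltas > 1.0)
    return pd.DataFrame(
        {
            "start": ts[idx] + np.timedelta64(1, "s"),
            "end": ts[idx + 1],
            "n_seconds": (deltas[idx] - 1).astype(int),
        }
    )


def read_table(path: str | Path, index_col: str = "participant_id") -> pd.DataFrame:
    """Read a demographics / scores table keyed by participant."""
    return pd.read_csv(path).set_index(index_col)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=True)
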