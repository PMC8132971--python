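"""Fusing daily/hourly markers into one behaviorome vector per participant.

The behaviorome concatenates the smart-home block and the smartwatch block in
a fixed, documented order.  Each block contains:

* the summary statistics of every **daily** marker series (one value per day
  over the collection period);
* the summary statistics of every **hourly** marker series, pooled over all
  hours of all days;
* nine regularity indices: {within_week, within_weekday, between_weeks} x
  three hourly rhythm metrics (home: reading count, activities performed,
  locations visited; watch: total acceleration, rotation, distance);
* three circadian strengths, one per rhythm metric.

Feature names are ``{modality}_{daily|hourly}_{marker}_{stat}``,
``{modality}_ri_{metric}_{mode}`` and ``{modality}_circadian_{metric}``, so
modality subsetting is a prefix filter.  The schema is a pure function of the
configuration (vocabularies and statistic list); two participants under the
same configuration always share it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circadian import MIN_SAMPLES, circadian_strength
from .markers import (
    HOME_DAILY_COLUMNS,
    HOME_HOURLY_COLUMNS,
    HOME_RHYTHM_METRICS,
    STAT_NAMES,
    WATCH_DAILY_COLUMNS,
    WATCH_HOURLY_COLUMNS,
    WATCH_RHYTHM_METRICS,
    overall_statistics,
)
from .regularity import RI_MODES, aggregate_regularity, scale_for_regularity

MODALITIES = ("home", "watch")


def behaviorome_schema(modalities: tuple[str, ...] = MODALITIES) -> list[str]:
    """Enumerate the behaviorome feature names for a modality configuration."""
    names: list[str] = []
    spec = {
        "home": (HOME_DAILY_COLUMNS, HOME_HOURLY_COLUMNS, HOME_RHYTHM_METRICS),
        "watch": (WATCH_DAILY_COLUMNS, WATCH_HOURLY_COLUMNS, WATCH_RHYTHM_METRICS),
    }
    for mod in modalities:
        if mod not in spec:
            raise ValueError(f"unknown modality {mod!r}")
        daily_cols, hourly_cols, metrics = spec[mod]
        for col in daily_cols:
            names.extend(f"{mod}_daily_{col}_{stat}" for stat in STAT_NAMES)
        for col in hourly_cols:
            names.extend(f"{mod}_hourly_{col}_{stat}" for stat in STAT_NAMES)
        for metric in metrics:
            names.extend(f"{mod}_ri_{metric}_{mode}" for mode in RI_MODES)
        names.extend(f"{mod}_circadian_{metric}" for metric in metrics)
    return names


def overall_markers(daily: pd.DataFrame, hourly: pd.DataFrame, modality: str) -> pd.Series:
    """Overall behavior markers of one modality for one participant.

    ``daily`` is (days x markers); ``hourly`` is ((date, hour) x markers).
    Hourly statistics pool all hours of all days into one series.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    metrics = HOME_RHYTHM_METRICS if modality == "home" else WATCH_RHYTHM_METRICS
    feats: dict[str, float] = {}
    for col in daily.columns:
        for stat, value in overall_statistics(daily[col].to_numpy()).items():
            feats[f"{modality}_daily_{col}_{stat}"] = value
    for col in hourly.columns:
        for stat, value in overall_statistics(hourly[col].to_numpy()).items():
            feats[f"{modality}_hourly_{col}_{stat}"] = value
    for metric in metrics:
        matrix = hourly[metric].unstack("hour").sort_index()
        scaled = scale_for_regularity(matrix)
        for mode in RI_MODES:
            feats[f"{modality}_ri_{metric}_{mode}"] = aggregate_regularity(scaled, mode)
        series = matrix.to_numpy(dtype=float).ravel()  # chronological hourly series
        feats[f"{modality}_circadian_{metric}"] = (
            circadian_strength(series) if series.size >= MIN_SAMPLES else 0.0
        )
    return pd.Series(feats)


def assemble_behaviorome(
    home: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    watch: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    modalities: tuple[str, ...] = MODALITIES,
) -> pd.Series:
    """Concatenate per-modality overall markers into one behaviorome vector.

    ``home``/``watch`` are (daily, hourly) marker tables.  Raises when a
    requested modality's markers are absent; the result always follows
    :func:`behaviorome_schema` exactly (order and names).
    """
    available = {"home": home, "watch": watch}
    parts = []
    for mod in modalities:
        tables = available.get(mod)
        if tables is None:
            raise ValueError(f"markers for requested modality {mod!r} not provided")
        parts.append(overall_markers(tables[0], tables[1], mod))
    vector = pd.concat(parts)
    schema = behaviorome_schema(modalities)
    missing = set(schema) - set(vector.index)
    if missing:
        raise AssertionError(f"behaviorome missing schema features: {sorted(missing)[:5]} ...")
    vector = vector.reindex(schema)
    if vector.isna().any():
        bad = vector.index[vector.isna()][:5].tolist()
        raise AssertionError(f"behaviorome contains missing values: {bad} ...")
    return vector


def subset_features(frame: pd.DataFrame, modality: str) -> pd.DataFrame:
    """Columns of a participant x feature table belonging to one modality
    configuration (``home``, ``watch``, or ``fusion``)."""
    if modality == "fusion":
        return frame
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality configuration {modality!r}")
    keep = [c for c in frame.columns if c.startswith(f"{modality}_")]
    return frame[keep]
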