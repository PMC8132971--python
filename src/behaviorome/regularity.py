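"""Schedule regularity indices over scaled hourly behavior series.

The regularity index comparing two days ``a`` and ``b`` of an hourly metric
is the mean hourwise product

.. math::

    RI_{a,b} = \\frac{1}{T} \\sum_{t=1}^{T} x_t^a \\, x_t^b, \\qquad T = 24,

where :math:`x_t^a` is the metric for hour ``t`` of day ``a`` after scaling
the participant's whole collection period to [-0.5, 0.5].  Two days with the
same schedule at the scale extremes score +0.25; opposite schedules score
-0.25.  Three aggregation modes summarize a collection period:

* ``within_week`` — all unordered pairs of distinct days inside each calendar
  week, averaged over weeks;
* ``within_weekday`` — the same, restricted to Monday–Friday days (how
  regular is the workweek schedule);
* ``between_weeks`` — pairs of same-weekday days in consecutive calendar
  weeks (longer-term uniformity).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

HOURS_PER_DAY = 24

RI_MODES = ("within_week", "within_weekday", "between_weeks")

#: value reported when a mode has no eligible day pair
UNDEFINED_RI = 0.0


def scale_for_regularity(hourly: pd.DataFrame) -> pd.DataFrame:
    """Affinely map a (days x 24) hourly metric onto [-0.5, 0.5].

    The min-max map is computed per participant and metric over the whole
    collection period (all days pooled); a constant series maps to all zeros.
    """
    values = hourly.to_numpy(dtype=float)
    lo, hi = np.nanmin(values), np.nanmax(values)
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("hourly metric contains no finite values")
    if hi == lo:
        scaled = np.zeros_like(values)
    else:
        scaled = (values - lo) / (hi - lo) - 0.5
    return pd.DataFrame(scaled, index=hourly.index, columns=hourly.columns)


def regularity_index(day_a: np.ndarray, day_b: np.ndarray) -> float:
    """RI of two scaled 24-hour day vectors; symmetric, bounded by ±0.25."""
    a = np.asarray(day_a, dtype=float)
    b = np.asarray(day_b, dtype=float)
    if a.shape != (HOURS_PER_DAY,) or b.shape != (HOURS_PER_DAY,):
        raise ValueError("regularity_index expects two 24-hour vectors")
    return float(a @ b / HOURS_PER_DAY)


def _week_key(dates: pd.DatetimeIndex) -> np.ndarray:
    iso = dates.isocalendar()
    return (iso["year"].to_numpy() * 100 + iso["week"].to_numpy()).astype(int)


def aggregate_regularity(scaled: pd.DataFrame, mode: str) -> float:
    """Mean RI over the day pairs selected by ``mode``.

    ``scaled`` is a (days x 24) frame of scaled values indexed by date.
    Returns the sentinel 0.0 (with a warning) when no pair is eligible.
    """
    if mode not in RI_MODES:
        raise ValueError(f"unknown regularity mode {mode!r}; expected one of {RI_MODES}")
    dates = pd.DatetimeIndex(scaled.index)
    values = scaled.to_numpy(dtype=float)
    weeks = _week_key(dates)
    weekdays = dates.dayofweek.to_numpy()

    pair_means: list[float] = []
    if mode in ("within_week", "within_weekday"):
        for week in np.unique(weeks):
            idx = np.flatnonzero(weeks == week)
            if mode == "within_weekday":
                idx = idx[weekdays[idx] < 5]
            if len(idx) < 2:
                continue
            ris = [
                regularity_index(values[i], values[j]) for i, j in combinations(idx, 2)
            ]
            pair_means.append(float(np.mean(ris)))
    else:  # between_weeks
        uniq = np.unique(weeks)
        ris = []
        for w1, w2 in zip(uniq[:-1], uniq[1:]):
            for dow in range(7):
                i = np.flatnonzero((weeks == w1) & (weekdays == dow))
                j = np.flatnonzero((weeks == w2) & (weekdays == dow))
                if len(i) and len(j):
                    ris.append(regularity_index(values[i[0]], values[j[0]]))
        if ris:
            pair_means.append(float(np.mean(ris)))

    if not pair_means:
        warnings.warn(f"no eligible day pair for regularity mode {mode!r}; reporting sentinel 0")
        return UNDEFINED_RI
    return float(np.mean(pair_means))
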