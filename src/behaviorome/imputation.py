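"""Random-forest imputation of missing smartwatch spans.

Watch-transition gaps leave contiguous missing spans in the 1 Hz grid.  Each
numeric channel is filled by a 100-tree random-forest regression whose
features are (a) the ``k`` most recent observed samples of *all* channels
before the missing second and (b) the value of the target channel at the same
minute of day on up to seven prior days (minute-bin means; days without data
fall back to the channel's training mean).  Categorical columns
(location type, labels) are forward-filled.

Filled rows carry ``imputed=True`` so the marker stage can still count them
as missing readings.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .vocab import WATCH_CHANNELS

DEFAULT_K_RECENT = 5
DEFAULT_PRIOR_DAYS = 7
DEFAULT_TREES = 100


def _gather_lags(values: np.ndarray, anchor: np.ndarray, k: int) -> np.ndarray:
    """(len(anchor), k * n_channels) matrix of rows anchor-1 .. anchor-k,
    edge-padded at the stream start."""
    cols = [values[np.maximum(anchor - lag, 0)] for lag in range(1, k + 1)]
    return np.concatenate(cols, axis=1)


def _minute_grid(day_idx: np.ndarray, minutes: np.ndarray, values: np.ndarray, n_days: int) -> np.ndarray:
    """(n_days, 1440) per-minute channel means; NaN where a minute has no data."""
    flat = day_idx * 1440 + minutes
    sums = np.bincount(flat, weights=values, minlength=n_days * 1440)
    counts = np.bincount(flat, minlength=n_days * 1440)
    with np.errstate(invalid="ignore"):
        return (sums / counts).reshape(n_days, 1440)


def _prior_day_features(
    grid: np.ndarray,
    day_idx: np.ndarray,
    minutes: np.ndarray,
    n_prior: int,
    fallback: float,
) -> np.ndarray:
    """(n, n_prior) same-minute channel values on the previous days,
    falling back to the channel mean when a prior day has no reading."""
    out = np.full((len(day_idx), n_prior), fallback)
    for j in range(1, n_prior + 1):
        prior = day_idx - j
        ok = prior >= 0
        vals = grid[np.maximum(prior, 0), minutes]
        vals = np.where(ok & np.isfinite(vals), vals, fallback)
        out[:, j - 1] = vals
    return out


def impute_watch_gaps(
    stream: pd.DataFrame,
    k_recent: int = DEFAULT_K_RECENT,
    n_prior_days: int = DEFAULT_PRIOR_DAYS,
    n_estimators: int = DEFAULT_TREES,
    max_train_rows: int = 1500,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill every missing 1 Hz grid second between the stream's endpoints.

    Returns the completed stream (sorted, with an ``imputed`` flag column
    when anything was filled).  A gap-free stream is returned unchanged.
    With too few observed samples to train on, channels are median-filled
    and a warning is issued.
    """
    if len(stream) == 0:
        raise ValueError("cannot impute an empty stream")
    obs = stream.sort_values("timestamp", ignore_index=True)
    ts = obs["timestamp"]
    t0, t1 = ts.iloc[0], ts.iloc[-1]
    full_grid = pd.date_range(t0, t1, freq="s")
    missing = full_grid.difference(pd.DatetimeIndex(ts))
    if len(missing) == 0:
        return stream

    filled = pd.DataFrame({"timestamp": missing})
    channels = list(WATCH_CHANNELS)
    obs_vals = obs[channels].to_numpy(dtype=float)

    if len(obs) <= k_recent + 1:
        warnings.warn("too few observed samples for model-based imputation; using channel medians")
        for ch in channels:
            filled[ch] = float(obs[ch].median())
    else:
        rng = np.random.default_rng(seed)
        n_train = min(max_train_rows, len(obs))
        train_idx = np.sort(rng.choice(len(obs), size=n_train, replace=False))

        # (a) recent-readings features: the k observed rows before each target
        prev_idx = np.searchsorted(ts.to_numpy(), missing.to_numpy(), side="left")
        lag_train = _gather_lags(obs_vals, train_idx, k_recent)
        lag_missing = _gather_lags(obs_vals, prev_idx, k_recent)

        # (b) same-minute-of-day values on prior days
        base_day = ts.dt.normalize().iloc[0]
        obs_day = ((ts.dt.normalize() - base_day).dt.days).to_numpy()
        obs_minute = ((ts - ts.dt.normalize()).dt.total_seconds() // 60).astype(int).to_numpy()
        mis_day = ((missing.normalize() - base_day).days).to_numpy()
        mis_minute = ((missing - missing.normalize()).total_seconds() // 60).astype(int).to_numpy()
        n_days = int(max(obs_day.max(), mis_day.max())) + 1

        for c, ch in enumerate(channels):
            grid = _minute_grid(obs_day, obs_minute, obs_vals[:, c], n_days)
            fallback = float(obs_vals[:, c].mean())
            X_train = np.hstack(
                [
                    lag_train,
                    _prior_day_features(grid, obs_day[train_idx], obs_minute[train_idx], n_prior_days, fallback),
                ]
            )
            X_mis = np.hstack(
                [
                    lag_missing,
                    _prior_day_features(grid, mis_day, mis_minute, n_prior_days, fallback),
                ]
            )
            forest = RandomForestRegressor(
                n_estimators=n_estimators, random_state=int(seed) % (2**31), n_jobs=1
            )
            forest.fit(X_train, obs_vals[train_idx, c])
            filled[ch] = forest.predict(X_mis)

    out = pd.concat([obs, filled], ignore_index=True).sort_values("timestamp", ignore_index=True)
    out["imputed"] = out["timestamp"].isin(pd.DatetimeIndex(missing))
    # categorical columns carry forward the last observed value
    for col in out.columns:
        if col in ("timestamp", "imputed", *channels):
            continue
        out[col] = out[col].ffill().bfill()
    assert not out[channels].isna().to_numpy().any(), "imputation left missing values"
    return out


def mean_fill_baseline(stream: pd.DataFrame) -> pd.DataFrame:
    """Global per-channel mean fill over the same grid; comparison baseline."""
    obs = stream.sort_values("timestamp", ignore_index=True)
    ts = obs["timestamp"]
    full_grid = pd.date_range(ts.iloc[0], ts.iloc[-1], freq="s")
    missing = full_grid.difference(pd.DatetimeIndex(ts))
    filled = pd.DataFrame({"timestamp": missing})
    for ch in WATCH_CHANNELS:
        filled[ch] = float(obs[ch].mean())
    out = pd.concat([obs, filled], ignore_index=True).sort_values("timestamp", ignore_index=True)
    out["imputed"] = out["timestamp"].isin(pd.DatetimeIndex(missing))
    return out
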