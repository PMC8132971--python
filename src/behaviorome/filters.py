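"""Zero-phase low-pass filtering of wearable channels."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .vocab import ACCEL_CHANNELS, GYRO_CHANNELS

DEFAULT_CUTOFF_HZ = 0.3
DEFAULT_ORDER = 4


def lowpass_filter(
    samples: np.ndarray,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    fs_hz: float = 1.0,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass of a uniformly sampled channel.

    Applied forward and backward (``filtfilt``), so the output has no phase
    lag and the same length as the input.  ``cutoff_hz`` must lie below the
    Nyquist frequency ``fs_hz / 2``.
    """
    x = np.asarray(samples, dtype=float)
    nyquist = fs_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) for fs={fs_hz} Hz")
    b, a = butter(order, cutoff_hz / nyquist)
    padlen = min(3 * (max(len(a), len(b)) - 1), x.shape[-1] - 1)
    return filtfilt(b, a, x, axis=-1, padlen=max(padlen, 0))


def lowpass_stream(
    stream: pd.DataFrame,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> pd.DataFrame:
    """Filter the accelerometer and gyroscope columns of a 1 Hz watch frame.

    Course, speed, and location columns pass through untouched.  Filtering is
    applied per contiguous segment so explicit gaps do not bleed across.
    """
    out = stream.copy()
    ts = stream["timestamp"].to_numpy()
    breaks = np.flatnonzero(np.diff(ts) / np.timedelta64(1, "s") > 1.0) + 1
    segments = np.split(np.arange(len(stream)), breaks)
    for ch in (*ACCEL_CHANNELS, *GYRO_CHANNELS):
        col = out[ch].to_numpy(dtype=float)
        for seg in segments:
            if len(seg) > (DEFAULT_ORDER * 3 + 1):
                col[seg] = lowpass_filter(col[seg], cutoff_hz, 1.0, order)
        out[ch] = col
    return out
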