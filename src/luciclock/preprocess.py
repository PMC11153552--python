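"""Raw-count conditioning: background subtraction, initial truncation,
moving-average detrending and smoothing, and normalization.

The conditioning chain turns a raw luciferase record — a large accumulation
peak in the first day, a slowly decaying baseline, and counting noise — into
a zero-centred oscillation suitable for periodogram and cosinor analysis.
Stage order is fixed: background -> truncate -> detrend -> smooth ->
normalize.

Moving averages are time-window based (a point's window is
``[t - w/2, t + w/2]`` in hours, shrinking at the series edges), so they are
well defined on uneven grids and in the presence of missing points.  Points
falling exactly on a window boundary receive half weight (trapezoid rule);
this makes a one-cycle window annihilate a matched-period sinusoid exactly
and keeps the window symmetric for polynomial trends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .plate_io import PlateRecording, TimeSeries

__all__ = [
    "PreprocessConfig",
    "subtract_background",
    "estimate_background",
    "truncate_initial",
    "detrend_moving_average",
    "smooth_moving_average",
    "normalize_initial_max",
    "preprocess_well",
]

log = logging.getLogger(__name__)

_TOL = 1e-9


@dataclass
class PreprocessConfig:
    """Conditioning parameters.

    background
        Scalar counts to subtract, the string ``"from_blanks"`` to pool the
        median of blank wells, or None (treated as 0 with a warning).
    truncate_h
        Hours discarded from the start of the recording; the luciferase
        enzyme accumulates over the first 12-24 h, so the default is 24.
    detrend_window_h
        Centered moving-average window subtracted from the signal.  One full
        circadian cycle (24 h) removes baseline decay without attenuating a
        24-h component.
    smooth_window_h
        Centered moving-average window applied after detrending; 2.5 h
        (5 samples at 30-min sampling) suppresses integration noise.
    norm_window_h
        The signal is divided by its maximum over this window at the start
        of the (truncated) series.
    """

    background: float | str | None = None
    truncate_h: float = 24.0
    detrend_window_h: float = 24.0
    smooth_window_h: float = 2.5
    norm_window_h: float = 24.0

    def __post_init__(self) -> None:
        if self.truncate_h < 0:
            raise ValueError("truncate_h must be >= 0")
        for name in ("detrend_window_h", "smooth_window_h", "norm_window_h"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.smooth_window_h < self.detrend_window_h:
            raise ValueError("smooth_window_h must be smaller than detrend_window_h")
        if isinstance(self.background, str) and self.background != "from_blanks":
            raise ValueError('background must be a scalar, "from_blanks", or None')


def subtract_background(ts: TimeSeries, background: float) -> TimeSeries:
    """Subtract a constant background; negatives are kept (not clamped)."""
    if not np.isfinite(background):
        raise ValueError("background must be finite")
    return ts.with_values(ts.values - background)


def estimate_background(rec: PlateRecording) -> float:
    """Median of all readings of all blank wells, pooled across time."""
    pooled = [
        ts.finite()[1]
        for well, ts in rec.series.items()
        if rec.meta[well].is_blank
    ]
    pooled = [v for v in pooled if v.size]
    if not pooled:
        raise ValueError(
            "no blank wells in recording; pass a scalar background instead"
        )
    return float(np.median(np.concatenate(pooled)))


def truncate_initial(ts: TimeSeries, truncate_h: float) -> TimeSeries:
    """Drop points before ``truncate_h``; the time axis is not re-zeroed."""
    if truncate_h < 0:
        raise ValueError("truncate_h must be >= 0")
    keep = ts.times >= truncate_h - _TOL
    if not keep.any():
        raise ValueError(
            f"truncating the first {truncate_h} h removed every point "
            f"(series spans {ts.times[0] if len(ts) else 'nothing'}"
            f"..{ts.times[-1] if len(ts) else ''} h)"
        )
    return TimeSeries(ts.times[keep], ts.values[keep], ts.nominal_interval)


def _windowed_mean(times: np.ndarray, values: np.ndarray, window_h: float) -> np.ndarray:
    """Centered time-window mean with trapezoid boundary weights.

    Missing points (NaN) are excluded from every window.  Where a window
    contains no finite point the mean is NaN.
    """
    half = window_h / 2.0
    finite = np.isfinite(values)
    v0 = np.where(finite, values, 0.0)
    w0 = finite.astype(float)
    cv = np.concatenate(([0.0], np.cumsum(v0)))
    cw = np.concatenate(([0.0], np.cumsum(w0)))
    lo = np.searchsorted(times, times - half - _TOL, side="left")
    hi = np.searchsorted(times, times + half + _TOL, side="right")
    s = cv[hi] - cv[lo]
    w = cw[hi] - cw[lo]
    # Half-weight points landing exactly on a window edge.
    at_left = np.abs(times[lo] - (times - half)) <= _TOL
    s -= 0.5 * v0[lo] * at_left
    w -= 0.5 * w0[lo] * at_left
    at_right = np.abs(times[hi - 1] - (times + half)) <= _TOL
    s -= 0.5 * v0[hi - 1] * at_right
    w -= 0.5 * w0[hi - 1] * at_right
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(w > 0, s / np.where(w > 0, w, 1.0), np.nan)
    return mean


def detrend_moving_average(ts: TimeSeries, window_h: float) -> TimeSeries:
    """Subtract the centered moving average (window shrinks at the edges)."""
    if not window_h > 0:
        raise ValueError("window_h must be positive")
    if ts.span_h < window_h - _TOL:
        raise ValueError(
            f"series span {ts.span_h:.2f} h is shorter than the detrend window {window_h} h"
        )
    mean = _windowed_mean(ts.times, ts.values, window_h)
    return ts.with_values(ts.values - mean)


def smooth_moving_average(ts: TimeSeries, window_h: float) -> TimeSeries:
    """Centered moving average; preserves length, times, and missing points."""
    if not window_h > 0:
        raise ValueError("window_h must be positive")
    mean = _windowed_mean(ts.times, ts.values, window_h)
    out = np.where(np.isfinite(ts.values), mean, np.nan)
    return ts.with_values(out)


def normalize_initial_max(ts: TimeSeries, norm_window_h: float) -> TimeSeries:
    """Divide by the maximum over the first ``norm_window_h`` of the series."""
    if not norm_window_h > 0:
        raise ValueError("norm_window_h must be positive")
    if len(ts) == 0:
        raise ValueError("empty series")
    t0 = ts.times[0]
    win = ts.window(t0, t0 + norm_window_h)
    _, v = win.finite()
    if v.size == 0:
        raise ValueError("no finite values in the initial normalization window")
    m = float(np.max(v))
    if abs(m) <= np.finfo(float).eps * 100:
        raise ValueError(
            "initial-window maximum is ~0 (dead well); cannot normalize"
        )
    return ts.with_values(ts.values / m)


def preprocess_well(
    ts: TimeSeries,
    cfg: PreprocessConfig,
    *,
    background_override: float | None = None,
) -> TimeSeries:
    """Full conditioning chain for one well.

    Applies, in fixed order: subtract_background, truncate_initial,
    detrend_moving_average, smooth_moving_average, normalize_initial_max.
    ``background_override`` supplies the pooled blank-well estimate when the
    config says ``"from_blanks"``.
    """
    bg = cfg.background
    if background_override is not None:
        bg = background_override
    elif bg == "from_blanks":
        raise ValueError(
            'background "from_blanks" requires a background_override resolved '
            "from the plate's blank wells"
        )
    elif bg is None:
        log.warning("no background provided; assuming 0 counts")
        bg = 0.0
    out = subtract_background(ts, float(bg))
    out = truncate_initial(out, cfg.truncate_h)
    out = detrend_moving_average(out, cfg.detrend_window_h)
    out = smooth_moving_average(out, cfg.smooth_window_h)
    out = normalize_initial_max(out, cfg.norm_window_h)
    return out
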