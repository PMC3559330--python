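"""Tidal regime classification from a tide-gauge record.

Mixed tides alternate between diurnal episodes (one high tide per day) and
semidiurnal episodes (two highs per day) as the diurnal constituents (K1, O1)
beat against the semidiurnal ones (M2, K2). Each calendar day of the gauge
record is classified by counting detected high tides: exactly one high is a
diurnal day, two or more is semidiurnal, zero (gauge gap) is unclassified.
Daily tidal amplitude is half the day's height range.

A tide series is a DataFrame with columns ``time`` (UTC) and ``height_m``;
the regime calendar is a DataFrame with one row per date: ``date``, ``regime``
(``"diurnal"`` / ``"semidiurnal"`` / ``"unclassified"``), ``n_high_tides`` and
``amplitude_m``.

Calendar days are delimited in station-local time: times are shifted by
``day_offset_hours`` (default −3 h, the local offset used throughout) before
taking the date.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

DEFAULT_MIN_SEPARATION_H = 8.0
DEFAULT_MIN_PROMINENCE_M = 0.1
DEFAULT_DAY_OFFSET_H = -3.0

DIURNAL = "diurnal"
SEMIDIURNAL = "semidiurnal"
UNCLASSIFIED = "unclassified"

__all__ = [
    "detect_high_tides",
    "classify_days",
    "daily_amplitude",
    "build_regime_calendar",
    "assign_regime",
    "DIURNAL",
    "SEMIDIURNAL",
    "UNCLASSIFIED",
]


def _series_arrays(series: pd.DataFrame) -> tuple[pd.DatetimeIndex, np.ndarray]:
    times = pd.DatetimeIndex(series["time"])
    if not times.is_monotonic_increasing or times.has_duplicates:
        raise ValueError("tide series times must be strictly increasing")
    heights = series["height_m"].to_numpy(dtype=float)
    if np.any(~np.isfinite(heights)):
        raise ValueError("tide series heights must be finite")
    return times, heights


def detect_high_tides(
    series: pd.DataFrame,
    min_separation: float = DEFAULT_MIN_SEPARATION_H,
    min_prominence: float = DEFAULT_MIN_PROMINENCE_M,
) -> pd.DatetimeIndex:
    """Timestamps of high tides: local maxima separated by ``min_separation``
    hours with topographic prominence at least ``min_prominence`` metres.

    The 8 h default separation keeps the two highs of a ~12.4 h semidiurnal
    day distinct while suppressing ripple; series endpoints are never peaks.
    """
    times, heights = _series_arrays(series)
    dt_h = (times[1] - times[0]).total_seconds() / 3600.0 if len(times) > 1 else 0.0
    if dt_h <= 0:
        raise ValueError("series must contain at least two samples")
    span_h = (times[-1] - times[0]).total_seconds() / 3600.0
    if span_h < 2 * min_separation:
        raise ValueError("series shorter than twice the minimum peak separation")
    distance = max(1, int(np.ceil(min_separation / dt_h)))
    idx, _ = find_peaks(heights, distance=distance, prominence=min_prominence)
    return times[idx]


def _local_times(times: pd.DatetimeIndex, day_offset_hours: float) -> pd.DatetimeIndex:
    shifted = times + pd.Timedelta(hours=day_offset_hours)
    if shifted.tz is not None:
        shifted = shifted.tz_localize(None)
    return shifted


def _local_dates(times: pd.DatetimeIndex, day_offset_hours: float) -> np.ndarray:
    """Naive station-local calendar dates of the given (usually UTC) timestamps."""
    return _local_times(times, day_offset_hours).normalize().to_numpy()


def classify_days(
    high_tides: pd.DatetimeIndex,
    span: tuple,
    day_offset_hours: float = DEFAULT_DAY_OFFSET_H,
) -> pd.DataFrame:
    """Label every local date in ``span = (first_date, last_date)`` (inclusive)
    by its high-tide count: 1 → diurnal, ≥2 → semidiurnal, 0 → unclassified."""
    first, last = (pd.Timestamp(d).normalize() for d in span)
    dates = pd.date_range(first, last, freq="D")
    high_tides = pd.DatetimeIndex(high_tides).sort_values()
    counts = pd.Series(0, index=dates, dtype=int)
    if len(high_tides):
        ht_dates = pd.DatetimeIndex(_local_dates(high_tides, day_offset_hours))
        vc = ht_dates.value_counts()
        counts.loc[counts.index.intersection(vc.index)] = vc
    regime = np.where(
        counts == 1, DIURNAL, np.where(counts >= 2, SEMIDIURNAL, UNCLASSIFIED)
    )
    return pd.DataFrame(
        {"date": dates, "regime": regime, "n_high_tides": counts.to_numpy()}
    )


def daily_amplitude(
    series: pd.DataFrame,
    span: tuple | None = None,
    day_offset_hours: float = DEFAULT_DAY_OFFSET_H,
) -> pd.Series:
    """Per-day tidal amplitude, (max − min)/2 of the day's heights (metres)."""
    times, heights = _series_arrays(series)
    dates = _local_dates(times, day_offset_hours)
    df = pd.DataFrame({"date": dates, "h": heights})
    amp = df.groupby("date")["h"].agg(lambda h: (h.max() - h.min()) / 2.0)
    amp.name = "amplitude_m"
    if span is not None:
        first, last = (pd.Timestamp(d).normalize() for d in span)
        amp = amp.reindex(pd.date_range(first, last, freq="D"))
    return amp


def build_regime_calendar(
    series: pd.DataFrame,
    min_separation: float = DEFAULT_MIN_SEPARATION_H,
    min_prominence: float = DEFAULT_MIN_PROMINENCE_M,
    day_offset_hours: float = DEFAULT_DAY_OFFSET_H,
) -> pd.DataFrame:
    """High-tide detection + day classification + daily amplitude in one pass.

    Only whole local days fully inside the gauge record are classified; the
    (usually partial) first and last local dates are dropped so that peak
    counts and amplitudes are never computed on truncated days.
    """
    times, _ = _series_arrays(series)
    highs = detect_high_tides(series, min_separation, min_prominence)
    shifted = _local_times(times, day_offset_hours)
    dates = pd.Series(shifted.normalize()).unique()
    # keep only complete local days: drop partial first/last days
    first_ok = (
        dates[0]
        if shifted[0] <= pd.Timestamp(dates[0])
        else dates[0] + pd.Timedelta(days=1)
    )
    last_end = pd.Timestamp(dates[-1]) + pd.Timedelta(days=1)
    last_ok = (
        dates[-1]
        if shifted[-1] >= last_end - pd.Timedelta(minutes=30)
        else dates[-1] - pd.Timedelta(days=1)
    )
    cal = classify_days(highs, (first_ok, last_ok), day_offset_hours)
    amp = daily_amplitude(series, (first_ok, last_ok), day_offset_hours)
    cal["amplitude_m"] = amp.to_numpy()
    cal.attrs["day_offset_hours"] = day_offset_hours
    return cal


def assign_regime(times, calendar: pd.DataFrame) -> pd.DataFrame:
    """Map timestamps to their day's regime and amplitude.

    Timestamps whose local date is not in the calendar get regime
    ``"unclassified"`` and NaN amplitude. The day offset is taken from the
    calendar construction, so callers must pass the same offset used there via
    ``calendar.attrs['day_offset_hours']`` if non-default.
    """
    offset = calendar.attrs.get("day_offset_hours", DEFAULT_DAY_OFFSET_H)
    times = pd.DatetimeIndex(times)
    dates = pd.DatetimeIndex(_local_dates(times, offset))
    lookup = calendar.set_index("date")
    regime = []
    amplitude = []
    for d in dates:
        if d in lookup.index:
            row = lookup.loc[d]
            regime.append(row["regime"])
            amplitude.append(row.get("amplitude_m", np.nan))
        else:
            regime.append(UNCLASSIFIED)
            amplitude.append(np.nan)
    return pd.DataFrame({"time": times, "regime": regime, "amplitude_m": amplitude})
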