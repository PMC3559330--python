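"""Time–depth-recorder processing: zero-offset correction, dive detection,
and time-merging dives with location fixes.

TDR pressure sensors drift, so raw surface readings wander away from 0 m. The
correction here is a two-pass running filter: a low quantile of depth over a
short window tracks the surface level between dives, and a running minimum
over a longer window extends that surface estimate across dives; subtracting
the resulting baseline restores surface intervals to ~0 m without touching
dive depths. Foraging dives are excursions strictly deeper than 5 m; a
location fix within 150 s of any dive is labelled a foraging (diving) location.

A TDR series is a DataFrame with ``time`` (1 Hz, UTC) and ``depth_m``
(positive down); detected dives are rows of ``start``, ``end``,
``max_depth_m``, ``duration_s``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_W1_S = 120
DEFAULT_W2_S = 1800
DEFAULT_QUANTILE = 0.05
DEFAULT_DIVE_THRESHOLD_M = 5.0
DEFAULT_MERGE_WINDOW_S = 150.0

__all__ = ["zero_offset_correct", "detect_dives", "merge_dive_locations"]


def zero_offset_correct(
    series: pd.DataFrame,
    w1: int = DEFAULT_W1_S,
    w2: int = DEFAULT_W2_S,
    q: float = DEFAULT_QUANTILE,
) -> pd.DataFrame:
    """Subtract a running surface baseline from a 1 Hz depth series.

    Pass 1 takes the centred running ``q``-quantile of depth over ``w1``
    seconds (surface level between dives); pass 2 opens that morphologically
    over ``w2`` seconds (running minimum then running maximum), which removes
    dive excursions from the baseline while tracking monotone drift without
    lag. The defaults (120 s, 1800 s, q=0.05) span surface intervals but not
    whole foraging bouts.
    """
    n = len(series)
    if n < w1 + w2:
        raise ValueError("series shorter than the correction windows")
    if not 0.0 < q < 0.5:
        raise ValueError("quantile must lie in (0, 0.5)")
    depth = series["depth_m"].astype(float)
    base = depth.rolling(w1, center=True, min_periods=1).quantile(q)
    base = base.rolling(w2, center=True, min_periods=1).min()
    base = base.rolling(w2, center=True, min_periods=1).max()
    out = series.copy()
    out["depth_m"] = (depth - base).to_numpy()
    out.attrs["corrected"] = True
    return out


def detect_dives(
    series: pd.DataFrame, threshold: float = DEFAULT_DIVE_THRESHOLD_M
) -> pd.DataFrame:
    """Maximal contiguous runs with depth strictly greater than ``threshold``.

    Emits one event per run with its start/end times (the samples flanking the
    threshold crossings) and maximum depth. Warns if the series has not been
    zero-offset corrected.
    """
    if not series.attrs.get("corrected", False):
        warnings.warn("detecting dives on an uncorrected depth series", stacklevel=2)
    depth = series["depth_m"].to_numpy(dtype=float)
    times = pd.DatetimeIndex(series["time"])
    deep = depth > threshold  # strict: an excursion to exactly 5 m is not a dive
    if not deep.any():
        return pd.DataFrame(columns=["start", "end", "max_depth_m", "duration_s"])
    edges = np.diff(deep.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0]
    if deep[0]:
        starts = np.r_[0, starts]
    if deep[-1]:
        ends = np.r_[ends, len(deep) - 1]
    rows = []
    for s, e in zip(starts, ends):
        rows.append(
            {
                "start": times[s],
                "end": times[e],
                "max_depth_m": float(depth[s : e + 1].max()),
                "duration_s": (times[e] - times[s]).total_seconds() + 1.0,
            }
        )
    return pd.DataFrame(rows)


def merge_dive_locations(
    fixes: pd.DataFrame,
    events: pd.DataFrame,
    window: float = DEFAULT_MERGE_WINDOW_S,
) -> pd.DataFrame:
    """Label each fix diving/non-diving by temporal proximity to dives.

    A fix is a diving (foraging) location iff its minimum temporal gap to any
    dive interval is at most ``window`` seconds, boundary inclusive; the gap is
    zero when the fix time falls inside a dive. Enlarging the window can only
    add diving labels, never remove them.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    fixes = fixes.copy()
    if len(events) == 0 or len(fixes) == 0:
        fixes["diving"] = False
        return fixes
    t = pd.DatetimeIndex(fixes["time"]).astype("int64").to_numpy() / 1e9
    s = pd.DatetimeIndex(events["start"]).astype("int64").to_numpy() / 1e9
    e = pd.DatetimeIndex(events["end"]).astype("int64").to_numpy() / 1e9
    # gap(fix, event) = max(start - t, t - end, 0); min over events
    gap = np.maximum(s[None, :] - t[:, None], t[:, None] - e[None, :])
    gap = np.maximum(gap, 0.0).min(axis=1)
    fixes["diving"] = gap <= window
    return fixes
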