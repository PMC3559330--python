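"""Depth-integrated currents from glider dead-reckoning residuals.

A buoyancy glider navigating underwater by compass dead reckoning surfaces
every couple of hours for a GPS fix. The displacement between where it
believed it was (dead-reckoned position) and where GPS says it is, divided by
the submerged duration, is the depth-averaged current over that segment —
here a 0–100 m depth-integrated velocity estimate every ~2 h.

Velocities are (u, v) in m/s with u eastward and v northward; bearings are
the direction the current flows *toward*, degrees clockwise from true north.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .argos import EARTH_RADIUS_KM

_R_M = EARTH_RADIUS_KM * 1000.0

__all__ = [
    "tangent_plane_displacement",
    "estimate_segment_current",
    "estimate_currents",
    "bearing_from_uv",
    "quadrant_fractions",
    "compare_speed_regimes",
    "correlate_wind_current",
]


def tangent_plane_displacement(lat1, lon1, lat2, lon2):
    """(dx, dy) metres from point 1 to point 2 on a local tangent plane.

    Decomposes the great-circle range and initial bearing into east/north
    components — a tangent-plane displacement free of the meridian-convergence
    error that plain equirectangular differencing picks up at high latitude.
    Exact to second order at the few-kilometre scale of inter-surfacing
    displacements.
    """
    from .argos import great_circle_distance, initial_bearing

    d_m = great_circle_distance(lat1, lon1, lat2, lon2) * 1000.0
    theta = np.radians(initial_bearing(lat1, lon1, lat2, lon2))
    return d_m * np.sin(theta), d_m * np.cos(theta)


def bearing_from_uv(u, v):
    """Direction-toward bearing of velocity (u, v), degrees CW from north, in [0, 360)."""
    return np.degrees(np.arctan2(u, v)) % 360.0


def estimate_segment_current(
    lat_dr, lon_dr, lat_gps, lon_gps, duration_s: float
) -> dict:
    """One segment's depth-integrated current from the GPS − dead-reckoned offset."""
    if duration_s <= 0:
        raise ValueError("segment duration must be positive")
    dx, dy = tangent_plane_displacement(lat_dr, lon_dr, lat_gps, lon_gps)
    u = float(dx) / duration_s
    v = float(dy) / duration_s
    speed = float(np.hypot(u, v))
    return {
        "u": u,
        "v": v,
        "speed": speed,
        "bearing": float(bearing_from_uv(u, v)),
    }


def estimate_currents(segments: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per-segment current estimates.

    ``segments`` needs columns ``t0``, ``t1``, ``lat_dr``, ``lon_dr``,
    ``lat_gps``, ``lon_gps``. Returns one row per segment with ``t_mid``,
    ``u``, ``v``, ``speed`` and ``bearing``.
    """
    t0 = pd.DatetimeIndex(segments["t0"])
    t1 = pd.DatetimeIndex(segments["t1"])
    dur = (t1 - t0).total_seconds().to_numpy()
    if np.any(dur <= 0):
        raise ValueError("all segment durations must be positive")
    dx, dy = tangent_plane_displacement(
        segments["lat_dr"], segments["lon_dr"], segments["lat_gps"], segments["lon_gps"]
    )
    u = dx / dur
    v = dy / dur
    return pd.DataFrame(
        {
            "t_mid": t0 + (t1 - t0) / 2,
            "u": u,
            "v": v,
            "speed": np.hypot(u, v),
            "bearing": bearing_from_uv(u, v),
        }
    )


def quadrant_fractions(bearings) -> tuple[float, float, float, float]:
    """Fractions of bearings toward NE [0,90), SE [90,180), SW [180,270), NW [270,360)."""
    b = np.asarray(bearings, dtype=float) % 360.0
    if b.size == 0:
        raise ValueError("no bearings supplied")
    q = np.floor_divide(b, 90.0).astype(int)
    counts = np.bincount(q, minlength=4)[:4]
    frac = counts / b.size
    return tuple(float(f) for f in frac)


def compare_speed_regimes(speeds_a, speeds_b) -> tuple[float, float, float]:
    """Welch two-sample t-test on current speeds: returns (t, df, p).

    Unequal variances, Welch–Satterthwaite fractional degrees of freedom,
    two-sided p.
    """
    a = np.asarray(speeds_a, dtype=float)
    b = np.asarray(speeds_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("both groups are constant; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def correlate_wind_current(wind, current) -> tuple[float, float, float, float]:
    """Pearson correlation of paired wind and current speeds: (r, t, df, p)."""
    w = np.asarray(wind, dtype=float)
    c = np.asarray(current, dtype=float)
    if w.shape != c.shape:
        raise ValueError("wind and current series must be the same length")
    n = len(w)
    if n < 3:
        raise ValueError("need at least three pairs")
    if np.std(w) == 0 or np.std(c) == 0:
        raise ValueError("constant series; correlation undefined")
    r = float(stats.pearsonr(w, c).statistic)
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(t), float(df), float(p)
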