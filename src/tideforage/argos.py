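"""ARGOS track cleaning: geodesic primitives, land masking and the sequential speed filter.

Satellite (ARGOS) fixes from diving seabirds carry class-dependent positional
error — quality classes 3, 2, 1 are nominally accurate within 100 m, 250 m and
500–1500 m; classes 0, A and B carry no error estimate and can be wildly wrong.
Cleaning proceeds in two automatic steps: fixes that fall on land are rejected,
and a sequential filter removes fixes that would require the bird to exceed a
maximum sustained swimming speed (8 km/h for Adélie penguins) between
consecutive retained locations.

Fix tables are pandas DataFrames with columns ``animal_id``, ``time``
(timezone-aware UTC), ``lat``, ``lon``, ``quality`` and, after filtering,
boolean ``retained`` plus ``rejection_reason``.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

EARTH_RADIUS_KM = 6371.0088
"""IUGG mean Earth radius used for all great-circle arithmetic."""

ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B")

__all__ = [
    "EARTH_RADIUS_KM",
    "ARGOS_CLASSES",
    "great_circle_distance",
    "initial_bearing",
    "destination_point",
    "load_landmask",
    "apply_landmask",
    "speed_filter",
    "filter_track",
]


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of range [-180, 180]")


def great_circle_distance(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in kilometres.

    Accepts scalars or arrays (broadcast). Symmetric, zero iff the two points
    coincide, and satisfies the triangle inequality on the sphere of radius
    ``EARTH_RADIUS_KM``.
    """
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(a))


def initial_bearing(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, degrees clockwise from north."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return np.degrees(np.arctan2(y, x)) % 360.0


def destination_point(lat, lon, bearing_deg, distance_km):
    """Point reached travelling ``distance_km`` on ``bearing_deg`` along a great circle."""
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    theta = np.radians(bearing_deg)
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return np.degrees(phi2), (np.degrees(lam2) + 540.0) % 360.0 - 180.0


def load_landmask(path) -> BaseGeometry:
    """Read a GeoJSON file and return the union of its (multi)polygons."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [shape(gj["geometry"])]
    else:
        geoms = [shape(gj)]
    return unary_union(geoms)


def _ensure_filter_columns(fixes: pd.DataFrame) -> pd.DataFrame:
    fixes = fixes.copy()
    if "retained" not in fixes.columns:
        fixes["retained"] = True
    if "rejection_reason" not in fixes.columns:
        fixes["rejection_reason"] = None
    return fixes


def apply_landmask(fixes: pd.DataFrame, mask: BaseGeometry) -> pd.DataFrame:
    """Reject fixes strictly inside the land mask (reason ``"land"``).

    Points exactly on a polygon boundary are retained: a bird standing at the
    waterline is a legitimate position. Already-rejected fixes are left as is.
    """
    fixes = _ensure_filter_columns(fixes)
    on_land = np.zeros(len(fixes), dtype=bool)
    active = fixes["retained"].to_numpy()
    lats = fixes["lat"].to_numpy(dtype=float)
    lons = fixes["lon"].to_numpy(dtype=float)
    for i in np.nonzero(active)[0]:
        # shapely contains() is strict interior: boundary points stay retained
        if mask.contains(Point(lons[i], lats[i])):
            on_land[i] = True
    fixes.loc[on_land, "retained"] = False
    fixes.loc[on_land, "rejection_reason"] = "land"
    return fixes


def _speed_filter_indices(
    times_s: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    quality: Sequence[str],
    vmax: float,
) -> list[int]:
    """Greedy removal: return indices (into the passed arrays) to drop.

    Repeatedly, among fixes adjacent to a consecutive pair whose implied speed
    exceeds ``vmax``, drop the removable fix with the largest implied speed
    (ties broken toward the later fix). Class 3 fixes and the first/last fix
    of the track are never removed.
    """
    n = len(times_s)
    keep = list(range(n))
    removed: list[int] = []
    if n < 2:
        return removed
    protected = {i for i in range(n) if str(quality[i]) == "3"}
    protected |= {0, n - 1}
    while True:
        k = np.array(keep)
        if len(k) < 2:
            break
        dt = np.diff(times_s[k])
        dist = great_circle_distance(lat[k][:-1], lon[k][:-1], lat[k][1:], lon[k][1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            speed = np.where(dt > 0, dist / (dt / 3600.0), np.inf)
            speed = np.where(dist == 0.0, 0.0, speed)
        viol = speed > vmax
        if not viol.any():
            break
        # candidate fixes flank a violating pair; score = max adjacent-pair speed
        scores: dict[int, float] = {}
        for j in np.nonzero(viol)[0]:
            for pos in (j, j + 1):
                idx = keep[pos]
                if idx in protected:
                    continue
                left = speed[pos - 1] if pos > 0 else -np.inf
                right = speed[pos] if pos < len(speed) else -np.inf
                scores[idx] = max(left, right)
        if not scores:
            break  # every offender is protected; nothing more can be done
        worst = max(scores.values())
        drop = max(i for i, s in scores.items() if s == worst)  # tie -> later fix
        removed.append(drop)
        keep.remove(drop)
    return removed


def speed_filter(fixes: pd.DataFrame, vmax: float = 8.0) -> pd.DataFrame:
    """Sequential maximum-speed filter (default 8 km/h), applied per animal.

    Operates on currently retained fixes only; removals get
    ``rejection_reason == "speed"``. Idempotent, and the retained set is always
    a subsequence of the input.
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    fixes = _ensure_filter_columns(fixes)
    if len(fixes) < 2:
        return fixes
    for _, grp in fixes.groupby("animal_id", sort=False):
        sub = grp[grp["retained"]]
        if len(sub) < 2:
            continue
        times_s = sub["time"].astype("int64").to_numpy() / 1e9
        rem = _speed_filter_indices(
            times_s,
            sub["lat"].to_numpy(dtype=float),
            sub["lon"].to_numpy(dtype=float),
            sub["quality"].astype(str).to_list(),
            vmax,
        )
        if rem:
            idx = sub.index[rem]
            fixes.loc[idx, "retained"] = False
            fixes.loc[idx, "rejection_reason"] = "speed"
    return fixes


def filter_track(
    fixes: pd.DataFrame,
    mask: BaseGeometry | None = None,
    vmax: float = 8.0,
    manual_reject: Iterable | None = None,
) -> pd.DataFrame:
    """Full cleaning pass: land mask, then speed filter, then manual rejections.

    ``manual_reject`` is an optional iterable of DataFrame index labels standing
    in for case-by-case visual track inspection.
    """
    fixes = _ensure_filter_columns(fixes)
    if mask is not None:
        fixes = apply_landmask(fixes, mask)
    fixes = speed_filter(fixes, vmax=vmax)
    if manual_reject is not None:
        labels = [i for i in manual_reject if i in fixes.index]
        fixes.loc[labels, "retained"] = False
        fixes.loc[labels, "rejection_reason"] = "manual"
    return fixes
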