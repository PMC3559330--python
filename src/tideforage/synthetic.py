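"""Seeded synthetic field data with the statistical structure the analysis assumes.

No tracking, gauge, or glider records ship with the package, so every
downstream stage is exercised on synthetic inputs that emulate:

* a mixed tide built from the K1, O1, M2 and K2 harmonic constituents, whose
  diurnal episodes alternate with semidiurnal episodes on the ~13.7-day beat
  of K1 against O1 (weekly-scale regime switching);
* central-place foraging trips whose per-fix distance from the colony is
  β(regime) + b_trip + ε — the same random-intercept structure the mixed
  models estimate — wrapped in ARGOS fixes with class-dependent positional
  error (classes 3/2/1 Gaussian with 95% error radii 100/250/1500 m; classes
  0/A/B heavy-tailed);
* 1 Hz TDR depth records with linear sensor drift and square-wave dives;
* glider missions dead-reckoning through a known current field; and
* station wind speeds.

All draws come from ``numpy.random.default_rng`` seeded from the config, so
identical seed + config give byte-identical outputs. Trips are distance-draw
constructs matching the statistical model, not mechanistic movement paths.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping

from .argos import destination_point
from .tides import DIURNAL

# Constituent periods (hours): lunisolar diurnal, lunar diurnal,
# principal lunar semidiurnal, lunisolar semidiurnal.
PERIOD_K1_H = 23.9345
PERIOD_O1_H = 25.8193
PERIOD_M2_H = 12.4206
PERIOD_K2_H = 11.9672

COLONY_LAT = -(64 + 46 / 60)  # 64°46′S
COLONY_LON = -(64 + 4 / 60)  # 64°04′W

__all__ = [
    "TidalConstituent",
    "SimConfig",
    "default_constituents",
    "gen_tide_series",
    "gen_trips",
    "gen_spike_track",
    "gen_dive_record",
    "gen_tdr_for_trips",
    "gen_glider_mission",
    "gen_wind",
    "constant_current",
    "sinusoidal_current",
    "toy_island",
    "write_landmask_geojson",
    "write_manifest",
]


@dataclass(frozen=True)
class TidalConstituent:
    """One tidal harmonic: h(t) = amplitude · cos(2πt/period − phase)."""

    name: str
    amplitude_m: float
    period_h: float
    phase_rad: float = 0.0

    def __post_init__(self):
        if self.amplitude_m < 0:
            raise ValueError("amplitude must be non-negative")
        if self.period_h <= 0:
            raise ValueError("period must be positive")


def default_constituents() -> tuple[TidalConstituent, ...]:
    """K1/O1/M2/K2 amplitudes giving a mixed, regime-switching tide.

    The diurnal pair sums to ~1.05 m and beats against itself every ~13.7
    days; when in phase it dominates the 0.43 m semidiurnal pair (diurnal
    episodes, daily amplitude ~1.2 m), when out of phase the semidiurnal pair
    takes over (~0.9 m days).
    """
    return (
        TidalConstituent("K1", 0.55, PERIOD_K1_H),
        TidalConstituent("O1", 0.50, PERIOD_O1_H),
        TidalConstituent("M2", 0.38, PERIOD_M2_H, 0.7),
        TidalConstituent("K2", 0.12, PERIOD_K2_H, 1.1),
    )


def _default_class_probs() -> dict:
    return {"3": 0.10, "2": 0.15, "1": 0.20, "0": 0.15, "A": 0.20, "B": 0.20}


def _default_class_error_m() -> dict:
    # 3/2/1 per the ARGOS accuracy statements; 0/A/B are unstated -> heavy-tailed
    return {"3": 100.0, "2": 250.0, "1": 1500.0, "0": 1500.0, "A": 3000.0, "B": 10000.0}


HEAVY_TAIL_CLASSES = ("0", "A", "B")
_R95 = 2.447746830681  # sqrt(chi2.ppf(0.95, 2)): 95% radius of a unit 2-D Gaussian


@dataclass
class SimConfig:
    """Parameters of a synthetic field season.

    Defaults mirror the 2011 study conditions: a 23-day January deployment,
    30 foraging trips, ~22 fixes per trip at 30-min intervals (≈660 at-sea
    fixes), mean foraging distance 5.4 km in the diurnal regime and 9.1 km in
    the semidiurnal regime, trip-intercept SD 1.4 km and residual SD 2.0 km.
    """

    seed: int = 0
    colony_lat: float = COLONY_LAT
    colony_lon: float = COLONY_LON
    start: str = "2011-01-05"
    days: int = 23
    n_trips: int = 30
    fixes_per_trip: int = 22
    fix_interval_min: float = 30.0
    beta_diurnal_km: float = 5.4
    beta_semidiurnal_km: float = 9.1
    sigma_trip_km: float = 1.4
    sigma_resid_km: float = 2.0
    bearing_jitter_deg: float = 10.0
    heading_sector_deg: tuple = (10.0, 130.0)  # seaward sector toward the canyon
    class_probs: dict = field(default_factory=_default_class_probs)
    class_error_m: dict = field(default_factory=_default_class_error_m)
    land_fraction: float = 0.03
    tdr_drift_m_per_min: float = 0.005
    dive_fraction: float = 0.35
    n_animals: int = 11

    def __post_init__(self):
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("ARGOS class probabilities must sum to 1")
        if min(self.sigma_trip_km, self.sigma_resid_km) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.fixes_per_trip < 1:
            raise ValueError("fixes_per_trip must be at least 1")


def gen_tide_series(
    constituents,
    start,
    days: int,
    dt_min: float = 6.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Harmonic tide h(t) = Σ A_c cos(2πt/T_c − φ_c) + ε sampled every ``dt_min``.

    ``dt_min`` must divide 24 h evenly so day boundaries fall on samples.
    """
    constituents = list(constituents)
    if not constituents:
        raise ValueError("need at least one tidal constituent")
    if days < 1:
        raise ValueError("need at least one day")
    if dt_min <= 0 or (24 * 60) % dt_min != 0:
        raise ValueError("dt must be positive and divide 24 h evenly")
    n = int(days * 24 * 60 / dt_min) + 1
    t_h = np.arange(n) * dt_min / 60.0
    h = np.zeros(n)
    for c in constituents:
        h += c.amplitude_m * np.cos(2 * np.pi * t_h / c.period_h - c.phase_rad)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        h = h + rng.normal(0.0, noise_sd, size=n)
    times = pd.Timestamp(start, tz="UTC") + pd.to_timedelta(t_h, unit="h")
    return pd.DataFrame({"time": times, "height_m": h})


def _regime_of_day(calendar: pd.DataFrame) -> pd.Series:
    return calendar.set_index("date")["regime"]


def gen_trips(
    config: SimConfig, calendar: pd.DataFrame, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (true track, ARGOS track) for a season of foraging trips.

    Each trip starts and ends at the colony; its foraging fixes lie at
    distance β(regime) + b_trip + ε from the colony along the trip's mean
    bearing (with angular jitter). ARGOS fixes add class-dependent error and
    a ``land_fraction`` of non-class-3 foraging fixes are displaced onto the
    toy island to exercise the land mask.
    """
    if config.n_trips < 1:
        raise ValueError("need at least one trip")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    regimes = _regime_of_day(calendar)
    day0 = pd.Timestamp(config.start).normalize()
    n_days = config.days
    span_needed = (
        2 * max(90.0, config.fix_interval_min)
        + (config.fixes_per_trip - 1) * config.fix_interval_min
    ) / 60.0
    if span_needed > 20.0:
        raise ValueError("trip longer than a day; reduce fixes_per_trip or interval")
    island = toy_island(config.colony_lat, config.colony_lon)
    island_centroid = island.centroid

    true_rows, argos_rows = [], []
    classes = list(config.class_probs.keys())
    probs = np.array([config.class_probs[c] for c in classes])
    for j in range(config.n_trips):
        day = int(j * n_days / config.n_trips)
        date = day0 + pd.Timedelta(days=day)
        if date not in regimes.index:
            raise ValueError(f"calendar does not cover trip day {date.date()}")
        regime = regimes.loc[date]
        day_offset = calendar.attrs.get("day_offset_hours", -3.0)
        start = (
            date.tz_localize("UTC")
            - pd.Timedelta(hours=day_offset)  # calendar dates are local
            + pd.Timedelta(hours=float(rng.uniform(1.0, 20.0 - span_needed)))
        )
        beta = config.beta_diurnal_km if regime == DIURNAL else config.beta_semidiurnal_km
        b_trip = rng.normal(0.0, config.sigma_trip_km)
        heading = rng.uniform(*config.heading_sector_deg)
        animal = f"bird{(j % config.n_animals) + 1:02d}"
        n_fix = config.fixes_per_trip
        # colony fixes sit a transit gap before/after the at-sea run so the
        # departure and return legs stay below swimming speed
        transit_min = max(90.0, config.fix_interval_min)
        offsets_min = np.r_[
            0.0,
            transit_min + np.arange(n_fix) * config.fix_interval_min,
            2 * transit_min + (n_fix - 1) * config.fix_interval_min,
        ]
        times = start + pd.to_timedelta(offsets_min, unit="m")
        dists = np.empty(n_fix + 2)
        bearings = np.empty(n_fix + 2)
        dists[0] = dists[-1] = 0.0
        bearings[0] = bearings[-1] = 0.0
        eps = rng.normal(0.0, config.sigma_resid_km, size=n_fix)
        draws = np.maximum(beta + b_trip + eps, 0.6)
        # arrange the (exchangeable) draws as an out-and-back distance profile
        asc = np.sort(draws)
        dists[1:-1] = np.r_[asc[::2], asc[1::2][::-1]]
        bearings[1:-1] = heading + rng.normal(0.0, config.bearing_jitter_deg, size=n_fix)
        lat, lon = destination_point(
            config.colony_lat, config.colony_lon, bearings, dists
        )
        qual = rng.choice(classes, size=n_fix + 2, p=probs)
        qual[0] = qual[-1] = "3"  # birds are seen at the colony
        err_lat, err_lon = _argos_error(lat, lon, qual, config.class_error_m, rng)
        onto_land = (
            (rng.random(n_fix + 2) < config.land_fraction)
            & (qual != "3")
            & (dists > 0.5)
        )
        err_lat[onto_land] = island_centroid.y
        err_lon[onto_land] = island_centroid.x
        for k in range(n_fix + 2):
            true_rows.append(
                {
                    "animal_id": animal,
                    "trip": j + 1,
                    "time": times[k],
                    "lat": lat[k],
                    "lon": lon[k],
                    "dist_km": dists[k],
                    "regime": regime,
                    "at_colony": k in (0, n_fix + 1),
                }
            )
            argos_rows.append(
                {
                    "animal_id": animal,
                    "time": times[k],
                    "lat": err_lat[k],
                    "lon": err_lon[k],
                    "quality": qual[k],
                }
            )
    true = pd.DataFrame(true_rows)
    argos = pd.DataFrame(argos_rows).sort_values(["animal_id", "time"]).reset_index(drop=True)
    return true, argos


def _argos_error(lat, lon, quality, class_error_m, rng) -> tuple[np.ndarray, np.ndarray]:
    """Displace true positions by class-dependent error.

    Classes 3/2/1 draw isotropic Gaussian error scaled so the stated class
    accuracy is the 95% error radius; classes 0/A/B draw from a bivariate t
    with 3 df (heavy tails) at the configured scale.
    """
    n = len(lat)
    sigma_m = np.array([class_error_m[str(q)] / _R95 for q in quality])
    z = rng.normal(size=(n, 2))
    heavy = np.isin(np.asarray(quality, dtype=str), HEAVY_TAIL_CLASSES)
    if heavy.any():
        chi = rng.chisquare(3, size=n)
        z[heavy] *= np.sqrt(3.0 / chi[heavy])[:, None]
    off_m = z * sigma_m[:, None]
    dist_km = np.hypot(off_m[:, 0], off_m[:, 1]) / 1000.0
    bearing = np.degrees(np.arctan2(off_m[:, 0], off_m[:, 1])) % 360.0
    return destination_point(lat, lon, bearing, dist_km)


def gen_spike_track(
    n_fixes: int = 40,
    speed_kmh: float = 2.0,
    interval_min: float = 30.0,
    n_spikes: int = 2,
    spike_km: float = 40.0,
    seed: int | None = None,
    colony_lat: float = COLONY_LAT,
    colony_lon: float = COLONY_LON,
) -> tuple[pd.DataFrame, np.ndarray]:
    """A constant-speed track with large off-path spike fixes injected.

    The underlying path moves well below the 8 km/h filter threshold; spikes
    are displaced ``spike_km`` off-path and never placed at the endpoints or
    on class 3 fixes, so the speed filter should remove exactly the spikes.
    Returns (fix table, spike indices).
    """
    rng = np.random.default_rng(seed)
    step_km = speed_kmh * interval_min / 60.0
    heading = rng.uniform(0.0, 360.0)
    lats, lons = [colony_lat], [colony_lon]
    for _ in range(n_fixes - 1):
        heading += rng.normal(0.0, 15.0)
        la, lo = destination_point(lats[-1], lons[-1], heading, step_km)
        lats.append(float(la))
        lons.append(float(lo))
    times = pd.Timestamp("2011-01-10", tz="UTC") + pd.to_timedelta(
        np.arange(n_fixes) * interval_min, unit="m"
    )
    qual = rng.choice(["2", "1", "0", "A", "B"], size=n_fixes)
    lats, lons = np.array(lats), np.array(lons)
    spikes = rng.choice(np.arange(1, n_fixes - 1), size=n_spikes, replace=False)
    for s in spikes:
        la, lo = destination_point(
            lats[s], lons[s], rng.uniform(0, 360), spike_km
        )
        lats[s], lons[s] = la, lo
    df = pd.DataFrame(
        {
            "animal_id": "spiketest",
            "time": times,
            "lat": lats,
            "lon": lons,
            "quality": qual,
        }
    )
    return df, np.sort(spikes)


def gen_dive_record(
    trip_times: tuple,
    dive_depths,
    drift_rate_m_per_min: float = 0.0,
    seed: int | None = None,
    dive_duration_s: float = 90.0,
    noise_sd_m: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A 1 Hz depth record with square-wave dives on a linear surface drift.

    ``trip_times`` is (start, end); dives of the given depths are spread
    evenly over the span. Returns (TDR series, ground-truth dive table).
    """
    start, end = (pd.Timestamp(t) for t in trip_times)
    n = int((end - start).total_seconds()) + 1
    if n < 2:
        raise ValueError("record must span at least two samples")
    if drift_rate_m_per_min < 0 and n * abs(drift_rate_m_per_min) / 60 > 0:
        pass  # negative drift is allowed; negative *duration* is not possible here
    t_s = np.arange(n, dtype=float)
    depth = drift_rate_m_per_min * t_s / 60.0
    rng = np.random.default_rng(seed)
    if noise_sd_m > 0:
        depth = depth + rng.normal(0.0, noise_sd_m, size=n)
    dive_depths = list(dive_depths)
    truth_rows = []
    if dive_depths:
        if min(dive_depths) <= 0:
            raise ValueError("dive depths must be positive")
        gaps = n / (len(dive_depths) + 1)
        for i, d in enumerate(dive_depths, start=1):
            s = int(i * gaps - dive_duration_s / 2)
            e = int(s + dive_duration_s)
            s, e = max(s, 1), min(e, n - 2)
            depth[s:e] += d
            truth_rows.append(
                {
                    "start": start + pd.Timedelta(seconds=s),
                    "end": start + pd.Timedelta(seconds=e - 1),
                    "max_depth_m": d,
                }
            )
    times = start + pd.to_timedelta(t_s, unit="s")
    tdr = pd.DataFrame({"time": times, "depth_m": depth})
    return tdr, pd.DataFrame(truth_rows)


def gen_tdr_for_trips(
    true_track: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trip TDR records with dives placed at a fraction of foraging fixes.

    Dives (15–80 m, 90 s) start 30 s before the chosen fix times so those
    fixes fall inside the 150 s merge window. Returns the concatenated TDR
    series and the ground-truth table of which fixes are diving fixes.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    tdr_parts, truth_parts = [], []
    for trip, grp in true_track.groupby("trip"):
        at_sea = grp[~grp["at_colony"]]
        start = grp["time"].min() - pd.Timedelta(minutes=5)
        end = grp["time"].max() + pd.Timedelta(minutes=5)
        is_dive = rng.random(len(at_sea)) < config.dive_fraction
        dive_times = at_sea["time"].to_numpy()[is_dive]
        n = int((end - start).total_seconds()) + 1
        t_s = np.arange(n, dtype=float)
        depth = config.tdr_drift_m_per_min * t_s / 60.0 + rng.normal(0.0, 0.05, size=n)
        for dt in dive_times:
            s = int((pd.Timestamp(dt) - start).total_seconds()) - 30
            depth[s : s + 90] += rng.uniform(15.0, 80.0)
        times = start + pd.to_timedelta(t_s, unit="s")
        part = pd.DataFrame(
            {
                "animal_id": grp["animal_id"].iloc[0],
                "trip": trip,
                "time": times,
                "depth_m": depth,
            }
        )
        tdr_parts.append(part)
        tr = at_sea[["animal_id", "time"]].copy()
        tr["diving_truth"] = is_dive
        tr["trip"] = trip
        truth_parts.append(tr)
    return (
        pd.concat(tdr_parts, ignore_index=True),
        pd.concat(truth_parts, ignore_index=True),
    )


def constant_current(u: float, v: float):
    """Current field callable t → (u, v), constant in time."""

    def f(t_s):
        t_s = np.asarray(t_s, dtype=float)
        return np.full_like(t_s, u), np.full_like(t_s, v)

    return f


def sinusoidal_current(u0: float, v0: float, u1: float, v1: float, period_h: float, phase: float = 0.0):
    """Mean flow (u0, v0) plus a rotating/oscillating tidal component."""

    def f(t_s):
        w = 2 * np.pi * np.asarray(t_s, dtype=float) / (period_h * 3600.0) - phase
        return u0 + u1 * np.cos(w), v0 + v1 * np.sin(w)

    return f


def gen_glider_mission(
    current_field,
    duration_h: float = 48.0,
    waypoints_km=((0.0, 0.0), (6.0, 6.0)),
    speed_through_water: float = 0.35,
    surfacing_interval_h: float = 2.0,
    gps_noise_m: float = 0.0,
    seed: int | None = None,
    start: str = "2011-01-10",
    origin_lat: float = COLONY_LAT,
    origin_lon: float = COLONY_LON,
    dt_s: float = 60.0,
) -> pd.DataFrame:
    """Simulate dead reckoning through a current field between GPS surfacings.

    The glider steers toward the active waypoint (cycling through
    ``waypoints_km``, local km east/north of the origin) at
    ``speed_through_water`` m/s; the true position is additionally advected by
    ``current_field(t_seconds) -> (u, v)``. At each surfacing the table gets
    the dead-reckoned end (GPS of previous surfacing + through-water
    displacement) and the noisy GPS of the true position, plus the true
    segment-mean current for validation.
    """
    if surfacing_interval_h <= 0:
        raise ValueError("surfacing interval must be positive")
    rng = np.random.default_rng(seed)
    n_seg = int(round(duration_h / surfacing_interval_h))
    seg_steps = int(round(surfacing_interval_h * 3600.0 / dt_s))
    wps = [np.array(w, dtype=float) * 1000.0 for w in waypoints_km]
    true = np.zeros(2)
    gps_meas = true.copy()
    wp_i = 0
    t = 0.0
    t0 = pd.Timestamp(start)
    t0 = t0.tz_localize("UTC") if t0.tz is None else t0.tz_convert("UTC")
    rows = []

    def to_latlon(xy):
        # spherical conversion from local azimuthal coordinates about the origin
        dist_km = float(np.hypot(xy[0], xy[1])) / 1000.0
        bearing = float(np.degrees(np.arctan2(xy[0], xy[1]))) % 360.0
        lat, lon = destination_point(origin_lat, origin_lon, bearing, dist_km)
        return float(lat), float(lon)

    for _ in range(n_seg):
        dr = gps_meas.copy()
        cur_int = np.zeros(2)
        for _ in range(seg_steps):
            target = wps[wp_i]
            err = target - true
            dist = np.linalg.norm(err)
            if dist < 50.0:
                wp_i = (wp_i + 1) % len(wps)
                target = wps[wp_i]
                err = target - true
                dist = np.linalg.norm(err)
            heading = err / dist if dist > 0 else np.zeros(2)
            if dist == 0 and speed_through_water > 0:
                heading = np.zeros(2)
            thru = heading * speed_through_water * dt_s
            u, v = current_field(t + dt_s / 2.0)
            adv = np.array([float(u), float(v)]) * dt_s
            dr = dr + thru
            true = true + thru + adv
            cur_int += adv
            t += dt_s
        noise = rng.normal(0.0, gps_noise_m, size=2) if gps_noise_m > 0 else np.zeros(2)
        gps_meas = true + noise
        lat_dr, lon_dr = to_latlon(dr)
        # the GPS fix sits at the dead-reckoned point displaced, in that
        # point's own east/north frame, by the current integral plus noise
        off = gps_meas - dr
        lat_gps, lon_gps = (
            float(v)
            for v in destination_point(
                lat_dr,
                lon_dr,
                np.degrees(np.arctan2(off[0], off[1])) % 360.0,
                float(np.hypot(off[0], off[1])) / 1000.0,
            )
        )
        dur = seg_steps * dt_s
        rows.append(
            {
                "t0": t0 + pd.Timedelta(seconds=t - dur),
                "t1": t0 + pd.Timedelta(seconds=t),
                "lat_dr": lat_dr,
                "lon_dr": lon_dr,
                "lat_gps": lat_gps,
                "lon_gps": lon_gps,
                "u_true": cur_int[0] / dur,
                "v_true": cur_int[1] / dur,
            }
        )
    return pd.DataFrame(rows)


def gen_wind(
    times, mean_mps: float = 4.5, sd_mps: float = 2.0, seed: int | None = None
) -> pd.DataFrame:
    """AR(1) wind-speed series (m/s, floored at 0) at the given timestamps."""
    times = pd.DatetimeIndex(times)
    rng = np.random.default_rng(seed)
    n = len(times)
    phi = 0.9
    x = np.empty(n)
    x[0] = rng.normal()
    innov = rng.normal(size=n) * np.sqrt(1 - phi**2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i]
    speed = np.maximum(mean_mps + sd_mps * x, 0.0)
    return pd.DataFrame({"time": times, "speed_mps": speed})


def toy_island(colony_lat: float = COLONY_LAT, colony_lon: float = COLONY_LON) -> Polygon:
    """A small hexagonal island ~2 km east of the colony (synthetic land mask)."""
    clat = colony_lat
    clon = colony_lon + 2.0 / (111.19493 * np.cos(np.radians(colony_lat)))
    ang = np.linspace(0, 2 * np.pi, 7)
    r_deg = 0.5 / 111.19493
    ring = [
        (clon + r_deg * np.sin(a) / np.cos(np.radians(clat)), clat + r_deg * np.cos(a))
        for a in ang
    ]
    return Polygon(ring)


def write_landmask_geojson(path, polygon: Polygon) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [{"type": "Feature", "properties": {}, "geometry": mapping(polygon)}],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def write_manifest(path, config: SimConfig, extra: dict | None = None) -> None:
    """Record the generator seed and config next to the synthetic CSVs."""
    doc = {"config": asdict(config)}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
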