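"""End-to-end orchestration: generate/load → classify → filter → dives →
currents → models → report.

`run_pipeline` composes every stage of the analysis into a single seeded,
logged run and returns a JSON-serializable report. With a ``synthetic`` block
in the config, all inputs are generated on the fly; otherwise CSV/GeoJSON
paths must be supplied. Stage outputs are pure functions of config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, argos, circular, currents, dives, foraging, io, tides
from . import synthetic as synth

logger = logging.getLogger("tideforage")

__all__ = ["RunConfig", "load_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Either ``synthetic`` (a SimConfig) or the input ``paths`` (keys: tide,
    argos, tdr, glider, wind, landmask) must be present. Every analysis
    threshold is surfaced with its standard value as default.
    """

    synthetic: synth.SimConfig | None = None
    paths: dict = field(default_factory=dict)
    seed: int = 0
    vmax_kmh: float = 8.0
    dive_threshold_m: float = 5.0
    merge_window_s: float = 150.0
    trip_radius_km: float = 0.5
    cell_m: float = 725.0
    kernel_size_m: float = 3000.0
    min_separation_h: float = 8.0
    min_prominence_m: float = 0.1
    day_offset_hours: float = -3.0
    colony_lat: float = synth.COLONY_LAT
    colony_lon: float = synth.COLONY_LON
    mww_permutations: int = 0  # 0 -> asymptotic p only
    outdir: str | None = None

    def validate(self) -> None:
        for name in (
            "vmax_kmh",
            "dive_threshold_m",
            "trip_radius_km",
            "cell_m",
            "kernel_size_m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.merge_window_s < 0:
            raise ValueError("merge_window_s must be non-negative")
        if self.synthetic is None:
            required = {"tide", "argos", "landmask"}
            missing = required - set(self.paths)
            if missing:
                raise ValueError(
                    "config needs a synthetic block or input paths; missing: "
                    + ", ".join(sorted(missing))
                )


def load_config(path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    syn = doc.pop("synthetic", None)
    cfg = RunConfig(**doc)
    if syn is not None:
        cfg.synthetic = synth.SimConfig(**syn)
    cfg.validate()
    return cfg


def _config_hash(config: RunConfig) -> str:
    doc = asdict(config)
    return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]


def default_current_field(env_phase_offset_s: float = 0.0):
    """Along-canyon (northeastward) flow modulated by the K1–O1 beat envelope.

    The mean up-canyon flow strengthens during diurnal episodes (the envelope
    maximum, when flow never reverses) and weakens during semidiurnal
    episodes, where the ever-present M2 oscillation drives partial reversals
    down-canyon — the regime-dependent current structure the glider observes.
    A smaller cross-canyon wobble spreads bearings into the flanking
    quadrants.
    """
    w1 = 2 * np.pi / (synth.PERIOD_K1_H * 3600)
    w2 = 2 * np.pi / (synth.PERIOD_O1_H * 3600)
    wm = 2 * np.pi / (synth.PERIOD_M2_H * 3600)
    ax = np.sqrt(0.5)  # NE unit vector component; cross axis is (ax, -ax)

    def f(t_s):
        t = np.asarray(t_s, dtype=float) + env_phase_offset_s
        env = np.abs(np.cos((w1 - w2) / 2 * t))  # K1-O1 beat, max on diurnal days
        along = 0.01 + 0.14 * env + 0.09 * np.cos(wm * t + 0.9)
        perp = 0.05 * env * np.sin(w1 * t) + 0.075 * np.sin(wm * t)
        return along * ax + perp * ax, along * ax - perp * ax

    return f


def _generate_inputs(config: RunConfig) -> dict:
    sim = config.synthetic
    rng_seeds = np.random.SeedSequence(sim.seed).spawn(5)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng_seeds]
    tide = synth.gen_tide_series(
        synth.default_constituents(),
        pd.Timestamp(sim.start) - pd.Timedelta(days=1),
        sim.days + 2,
        dt_min=6.0,
        noise_sd=0.01,
        seed=seeds[0],
    )
    calendar = tides.build_regime_calendar(
        tide,
        config.min_separation_h,
        config.min_prominence_m,
        config.day_offset_hours,
    )
    true_track, argos_track = synth.gen_trips(sim, calendar, seed=seeds[1])
    tdr, dive_truth = synth.gen_tdr_for_trips(true_track, sim, seed=seeds[2])
    mission_days = min(sim.days - 2, 21)
    # the mission starts two days after the tide series, whose K1/O1 phases
    # put the diurnal envelope maximum at series start: align the field
    glider = synth.gen_glider_mission(
        default_current_field(env_phase_offset_s=2 * 86400.0),
        duration_h=24.0 * mission_days,
        waypoints_km=((2.0, 2.0), (8.0, 8.0), (8.0, 2.0)),
        gps_noise_m=15.0,
        seed=seeds[3],
        start=pd.Timestamp(sim.start, tz="UTC") + pd.Timedelta(days=1),
        origin_lat=sim.colony_lat,
        origin_lon=sim.colony_lon,
    )
    seg_mid = glider["t0"] + (glider["t1"] - glider["t0"]) / 2
    wind = synth.gen_wind(seg_mid, seed=seeds[4])
    mask = synth.toy_island(sim.colony_lat, sim.colony_lon)
    return {
        "tide": tide,
        "calendar": calendar,
        "argos": argos_track,
        "true_track": true_track,
        "tdr": tdr,
        "dive_truth": dive_truth,
        "glider": glider,
        "wind": wind,
        "mask": mask,
    }


def _load_inputs(config: RunConfig) -> dict:
    p = config.paths
    data = {
        "tide": io.read_csv(p["tide"], "tide"),
        "argos": io.read_csv(p["argos"], "argos"),
        "mask": argos.load_landmask(p["landmask"]),
    }
    data["calendar"] = tides.build_regime_calendar(
        data["tide"],
        config.min_separation_h,
        config.min_prominence_m,
        config.day_offset_hours,
    )
    for key, kind in (("tdr", "tdr"), ("glider", "glider"), ("wind", "wind")):
        if key in p:
            data[key] = io.read_csv(p[key], kind)
    return data


def _dive_stage(data: dict, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Zero-offset + dive detection per contiguous TDR record; merge per animal."""
    tdr = data["tdr"]
    group_cols = ["animal_id", "trip"] if "trip" in tdr.columns else ["animal_id"]
    events = []
    for key, grp in tdr.groupby(group_cols, sort=False):
        grp = grp.sort_values("time").reset_index(drop=True)
        corrected = dives.zero_offset_correct(grp)
        ev = dives.detect_dives(corrected, config.dive_threshold_m)
        if len(ev):
            ev["animal_id"] = key[0] if isinstance(key, tuple) else key
            events.append(ev)
    events = (
        pd.concat(events, ignore_index=True)
        if events
        else pd.DataFrame(columns=["start", "end", "max_depth_m", "duration_s", "animal_id"])
    )
    fixes = data["filtered"]
    labeled = []
    for animal, grp in fixes.groupby("animal_id", sort=False):
        ev = events[events["animal_id"] == animal]
        labeled.append(dives.merge_dive_locations(grp, ev, config.merge_window_s))
    return pd.concat(labeled, ignore_index=True), events


def _current_stage(data: dict, config: RunConfig, calendar: pd.DataFrame) -> dict:
    est = currents.estimate_currents(data["glider"])
    lab = tides.assign_regime(est["t_mid"], calendar)
    est["regime"] = lab["regime"].to_numpy()
    report: dict = {"n_estimates": int(len(est))}
    report["mean_speed_mps"] = float(est["speed"].mean())
    report["quadrant_fractions"] = dict(
        zip(("NE", "SE", "SW", "NW"), currents.quadrant_fractions(est["bearing"]))
    )
    by = {r: est[est["regime"] == r] for r in ("diurnal", "semidiurnal")}
    if all(len(v) >= 2 for v in by.values()):
        t, df, p = currents.compare_speed_regimes(
            by["diurnal"]["speed"], by["semidiurnal"]["speed"]
        )
        report["welch_speed"] = {"t": t, "df": df, "p": p}
        for r, sub in by.items():
            report[f"mean_speed_{r}_mps"] = float(sub["speed"].mean())
            report[f"quadrant_fractions_{r}"] = dict(
                zip(("NE", "SE", "SW", "NW"), currents.quadrant_fractions(sub["bearing"]))
            )
        method = "permutation" if config.mww_permutations else "asymptotic"
        mww = circular.mww_test(
            by["diurnal"]["bearing"].to_numpy(),
            by["semidiurnal"]["bearing"].to_numpy(),
            method=method,
            n_perm=config.mww_permutations or 9999,
            seed=config.seed,
        )
        report["mww_bearings"] = {
            "W": mww.W,
            "p_asymptotic": mww.p_asymptotic,
            "p_permutation": mww.p_permutation,
            "n_diurnal": mww.n1,
            "n_semidiurnal": mww.n2,
        }
        u2, p_gof = circular.vonmises_gof(
            est["bearing"].to_numpy(), n_boot=200, seed=config.seed + 1
        )
        report["vonmises_gof"] = {"U2": u2, "p": p_gof}
        if "wind" in data:
            wind = data["wind"].reset_index(drop=True)
            est_r = est.reset_index(drop=True)
            for r, n_keep in (("diurnal", 13), ("semidiurnal", 17)):
                # station-keeping style subset: first contiguous run in each regime
                idx = est_r.index[est_r["regime"] == r][:n_keep]
                if len(idx) >= 3:
                    rr, t_w, df_w, p_w = currents.correlate_wind_current(
                        wind.loc[idx, "speed_mps"], est_r.loc[idx, "speed"]
                    )
                    report[f"wind_correlation_{r}"] = {
                        "r": rr, "t": t_w, "df": df_w, "p": p_w, "n": int(len(idx)),
                    }
    data["current_estimates"] = est
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report dictionary.

    With ``config.outdir`` set, stage tables (calendar, filtered/labeled
    fixes, dive events, trip table, current estimates, density grids and
    contour areas), a plain-text log of per-stage record counts, and the
    report + provenance manifest are also written there.
    """
    config.validate()
    log_handler = None
    if config.outdir:
        Path(config.outdir).mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(Path(config.outdir) / "run.log", mode="w")
        log_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(log_handler)
        logger.setLevel(logging.INFO)
    try:
        return _run_pipeline(config)
    finally:
        if log_handler is not None:
            logger.removeHandler(log_handler)
            log_handler.close()


def _run_pipeline(config: RunConfig) -> dict:
    report: dict = {
        "manifest": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "tideforage_version": __version__,
            "synthetic": config.synthetic is not None,
        }
    }
    data = _generate_inputs(config) if config.synthetic else _load_inputs(config)
    calendar = data["calendar"]
    n_reg = calendar["regime"].value_counts()
    report["tide"] = {
        "n_days": int(len(calendar)),
        "n_diurnal_days": int(n_reg.get("diurnal", 0)),
        "n_semidiurnal_days": int(n_reg.get("semidiurnal", 0)),
        "n_unclassified_days": int(n_reg.get("unclassified", 0)),
        "mean_amplitude_diurnal_m": float(
            calendar.loc[calendar["regime"] == "diurnal", "amplitude_m"].mean()
        ),
        "mean_amplitude_semidiurnal_m": float(
            calendar.loc[calendar["regime"] == "semidiurnal", "amplitude_m"].mean()
        ),
    }

    # --- track filtering ---
    fixes = argos.filter_track(data["argos"], mask=data["mask"], vmax=config.vmax_kmh)
    data["filtered"] = fixes[fixes["retained"]].reset_index(drop=True)
    n_in, n_kept = len(fixes), int(fixes["retained"].sum())
    reasons = fixes.loc[~fixes["retained"], "rejection_reason"].value_counts()
    report["filtering"] = {
        "n_input": n_in,
        "n_retained": n_kept,
        "pct_removed": 100.0 * (n_in - n_kept) / n_in if n_in else 0.0,
        "n_removed_land": int(reasons.get("land", 0)),
        "n_removed_speed": int(reasons.get("speed", 0)),
    }
    logger.info("filtering: %d -> %d fixes", n_in, n_kept)

    # --- dives ---
    if "tdr" in data:
        labeled, events = _dive_stage(data, config)
        data["labeled_fixes"] = labeled
        data["dive_events"] = events
        report["dives"] = {
            "n_events": int(len(events)),
            "n_diving_fixes": int(labeled["diving"].sum()),
            "n_nondiving_fixes": int((~labeled["diving"]).sum()),
        }
        logger.info(
            "dives: %d events; %d diving / %d non-diving fixes",
            len(events),
            int(labeled["diving"].sum()),
            int((~labeled["diving"]).sum()),
        )
    else:
        labeled = data["filtered"].copy()
        labeled["diving"] = False
        report["dives"] = None

    # --- trips & mixed models ---
    trips = foraging.segment_trips(
        labeled, config.colony_lat, config.colony_lon, config.trip_radius_km
    )
    trips = foraging.attach_covariates(trips, calendar)
    data["trips"] = trips
    report["trips"] = {"n_trips": int(trips["trip_id"].nunique()), "n_fixes": int(len(trips))}
    logger.info("trips: %d trips over %d at-sea fixes", trips["trip_id"].nunique(), len(trips))

    def _model_block(subset: pd.DataFrame, transform: str) -> dict | None:
        if len(subset) < 8 or subset["trip_id"].nunique() < 2:
            return None
        if set(subset["regime"].unique()) != {"diurnal", "semidiurnal"}:
            return None
        f1 = foraging.fit_lmm(subset, "regime", transform)
        f2 = foraging.fit_lmm(subset, "full", transform)
        cmp_ = foraging.compare_models(f1, f2)
        means = subset.groupby("regime")["dhi_km"].mean()
        block = {
            "transform": transform,
            "n_obs": f1.n_obs,
            "n_trips": f1.n_groups,
            "mean_dhi_diurnal_km": float(means.get("diurnal", np.nan)),
            "mean_dhi_semidiurnal_km": float(means.get("semidiurnal", np.nan)),
        }
        for name, f in (("regime", f1), ("full", f2)):
            block[name] = {
                "beta": {k: float(v) for k, v in f.beta.items()},
                "se": {k: float(v) for k, v in f.se.items()},
                "t": {k: float(v) for k, v in f.t_stats.items()},
                "p": {k: float(v) for k, v in f.p_values.items()},
                "sigma_b": f.sigma_b,
                "sigma_e": f.sigma_e,
                "loglik": f.loglik,
                "aic": f.aic,
            }
        block["comparison"] = {
            "chi2": cmp_.chi2, "df": cmp_.df, "p": cmp_.p, "delta_aic": cmp_.delta_aic,
        }
        return block

    report["model_diving"] = _model_block(trips[trips["diving"]], "identity")
    report["model_all"] = _model_block(trips, "log10")

    # --- KDE areas per regime ---
    kde_block = {}
    for r in ("diurnal", "semidiurnal"):
        sub = trips[trips["regime"] == r]
        if len(sub) >= 20:
            surf = foraging.kde_surface(
                sub["lat"].to_numpy(),
                sub["lon"].to_numpy(),
                config.colony_lat,
                config.colony_lon,
                config.cell_m,
                config.kernel_size_m,
            )
            kde_block[f"area95_{r}_km2"] = foraging.contour_area_95(surf)
            data[f"kde_{r}"] = surf
    report["kde"] = kde_block or None

    # --- currents ---
    report["currents"] = (
        _current_stage(data, config, calendar) if "glider" in data else None
    )
    if report["currents"]:
        logger.info("currents: %d segment estimates", report["currents"]["n_estimates"])

    if config.outdir:
        _write_outputs(config, data, report)
    return report


def _write_ascii_grid(surface, path) -> None:
    """ESRI ASCII grid of a kernel density surface (km coordinates)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {len(surface.x)}\n")
        fh.write(f"nrows {len(surface.y)}\n")
        fh.write(f"xllcorner {surface.x[0] - surface.cell_km / 2:.6f}\n")
        fh.write(f"yllcorner {surface.y[0] - surface.cell_km / 2:.6f}\n")
        fh.write(f"cellsize {surface.cell_km:.6f}\n")
        fh.write("NODATA_value -9999\n")
        for row in surface.density[::-1]:
            fh.write(" ".join(f"{v:.6e}" for v in row) + "\n")


def _write_outputs(config: RunConfig, data: dict, report: dict) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_csv(data["calendar"], out / "regime_calendar.csv")
    if "filtered" in data:
        io.write_csv(data["filtered"], out / "filtered_fixes.csv")
    for key, name in (
        ("labeled_fixes", "labeled_fixes.csv"),
        ("dive_events", "dive_events.csv"),
        ("trips", "trip_table.csv"),
        ("current_estimates", "current_estimates.csv"),
    ):
        if key in data and isinstance(data[key], pd.DataFrame):
            io.write_csv(data[key], out / name)
    areas = report.get("kde") or {}
    if areas:
        pd.DataFrame(
            [{"regime": k.split("_")[1], "area95_km2": v} for k, v in areas.items()]
        ).to_csv(out / "contour_areas.csv", index=False)
    for r in ("diurnal", "semidiurnal"):
        if f"kde_{r}" in data:
            _write_ascii_grid(data[f"kde_{r}"], out / f"density_{r}.asc")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    logger.info("outputs written to %s", out)
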