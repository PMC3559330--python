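"""Central-place foraging analysis: trip segmentation, mixed models and
utilization-distribution contours.

The response variable throughout is DHI, the great-circle distance (km) of a
penguin location from the Humble Island colony. Because successive fixes
within a foraging trip are spatially autocorrelated, trips — maximal runs of
fixes beyond a 0.5 km colony radius, delimited by returns to the colony — are
treated as a random effect. The baseline model is

    DHI_ijk = β·regime_i + b_j + ε_ijk,                 (random-intercept LMM)

with tidal regime (diurnal/semidiurnal) a fixed effect, b_j ~ N(0, σ_b²) a
per-trip intercept and ε ~ N(0, σ_e²). The extended model adds daily tidal
amplitude (m) and Julian day as fixed effects; both models are fit by maximum
likelihood (not REML) so AICs and likelihood-ratio tests across fixed-effect
sets are valid. Where residuals are non-normal the response is log10
transformed.

Spatial use per regime is summarized by a Gaussian kernel density on an
azimuthal-equidistant plane about the colony (725 m grid, ~3 km kernel) and
the area of its 95% utilization contour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .argos import great_circle_distance, initial_bearing

DEFAULT_TRIP_RADIUS_KM = 0.5
DEFAULT_CELL_M = 725.0
DEFAULT_KERNEL_SIZE_M = 3000.0  # kernel extent (diameter); sigma is half this

FIXED_REGIME_ONLY = ["intercept", "semidiurnal"]
FIXED_FULL = ["intercept", "semidiurnal", "amplitude_m", "julian_day"]

__all__ = [
    "segment_trips",
    "attach_covariates",
    "LMMResult",
    "fit_lmm",
    "ModelComparison",
    "compare_models",
    "DensitySurface",
    "kde_surface",
    "contour_area_95",
    "check_residual_normality",
]


def segment_trips(
    fixes: pd.DataFrame,
    colony_lat: float,
    colony_lon: float,
    radius_km: float = DEFAULT_TRIP_RADIUS_KM,
) -> pd.DataFrame:
    """Split each animal's fixes into foraging trips bounded by colony returns.

    Fixes within ``radius_km`` of the colony are trip boundaries and are
    excluded from trips; maximal runs of beyond-radius fixes form trips.
    Leading/trailing runs that lack a bounding return still count as trips and
    are flagged ``open_trip``. Returns the trip table: one row per foraging
    fix with ``trip_id``, ``dhi_km`` and ``open_trip``.
    """
    if radius_km <= 0:
        raise ValueError("trip radius must be positive")
    out_rows = []
    trip_counter = 0
    for animal, grp in fixes.groupby("animal_id", sort=False):
        grp = grp.sort_values("time")
        dhi = great_circle_distance(
            grp["lat"].to_numpy(), grp["lon"].to_numpy(), colony_lat, colony_lon
        )
        away = dhi > radius_km
        if not away.any():
            continue
        edges = np.diff(away.astype(np.int8))
        starts = list(np.nonzero(edges == 1)[0] + 1)
        ends = list(np.nonzero(edges == -1)[0])
        if away[0]:
            starts = [0] + starts
        if away[-1]:
            ends = ends + [len(away) - 1]
        for s, e in zip(starts, ends):
            trip_counter += 1
            sub = grp.iloc[s : e + 1].copy()
            sub["trip_id"] = trip_counter
            sub["dhi_km"] = dhi[s : e + 1]
            sub["open_trip"] = (s == 0 and away[0]) or (e == len(away) - 1 and away[-1])
            out_rows.append(sub)
    if not out_rows:
        cols = list(fixes.columns) + ["trip_id", "dhi_km", "open_trip"]
        return pd.DataFrame(columns=cols)
    return pd.concat(out_rows, ignore_index=True)


def attach_covariates(
    trips: pd.DataFrame, calendar: pd.DataFrame, drop_unclassified: bool = True
) -> pd.DataFrame:
    """Join regime, daily amplitude and Julian day onto a trip table.

    Trip rows on days the calendar cannot classify (gauge gaps) are dropped by
    default, with a warning naming how many rows were lost.
    """
    from .tides import UNCLASSIFIED, assign_regime

    lab = assign_regime(trips["time"], calendar)
    trips = trips.copy()
    trips["regime"] = lab["regime"].to_numpy()
    trips["amplitude_m"] = lab["amplitude_m"].to_numpy()
    offset = calendar.attrs.get("day_offset_hours", -3.0)
    local = pd.DatetimeIndex(trips["time"]) + pd.Timedelta(hours=offset)
    trips["julian_day"] = local.dayofyear.to_numpy()
    if drop_unclassified:
        bad = trips["regime"] == UNCLASSIFIED
        if bad.any():
            warnings.warn(
                f"dropping {int(bad.sum())} fixes on unclassified days", stacklevel=2
            )
            trips = trips[~bad].copy()
    return trips


@dataclass
class LMMResult:
    """Summary of a random-intercept (trip) linear mixed model fit by ML."""

    beta: pd.Series
    se: pd.Series
    t_stats: pd.Series
    p_values: pd.Series
    sigma_b: float
    sigma_e: float
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    transform: str
    fixed_names: list = field(default_factory=list)

    @property
    def regime_effect(self) -> float:
        """Fixed-effect difference semidiurnal − diurnal on the model scale."""
        return float(self.beta["semidiurnal"])


def _design(data: pd.DataFrame, formula: str) -> tuple[np.ndarray, list]:
    semi = (data["regime"] == "semidiurnal").astype(float).to_numpy()
    cols = [np.ones(len(data)), semi]
    names = list(FIXED_REGIME_ONLY)
    if formula == "full":
        cols.append(data["amplitude_m"].to_numpy(dtype=float))
        cols.append(data["julian_day"].to_numpy(dtype=float))
        names = list(FIXED_FULL)
    elif formula != "regime":
        raise ValueError("formula must be 'regime' or 'full'")
    return np.column_stack(cols), names


def fit_lmm(
    data: pd.DataFrame, formula: str = "regime", transform: str = "identity"
) -> LMMResult:
    """Fit the regime-only model ("regime") or the regime + daily amplitude +
    Julian-day model ("full") with a random intercept per trip, by ML.

    ``transform="log10"`` models log10(DHI); non-positive distances are
    dropped with a warning. p-values use the normal approximation to the
    t-ratios, and AIC counts fixed effects plus the two variance parameters.
    """
    data = data.copy()
    if transform == "log10":
        bad = data["dhi_km"] <= 0
        if bad.any():
            warnings.warn(
                f"dropping {int(bad.sum())} non-positive distances for log10",
                stacklevel=2,
            )
            data = data[~bad]
        y = np.log10(data["dhi_km"].to_numpy(dtype=float))
    elif transform == "identity":
        y = data["dhi_km"].to_numpy(dtype=float)
    else:
        raise ValueError("transform must be 'identity' or 'log10'")
    regimes = set(data["regime"].unique())
    if not {"diurnal", "semidiurnal"} <= regimes:
        raise ValueError("both tidal regimes must be present to estimate the effect")
    groups = data["trip_id"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two trips")
    X, names = _design(data, formula)
    k = X.shape[1] + 2  # fixed effects + two variance components

    # degenerate (noise-free) data: OLS already fits exactly
    ols_beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ ols_beta
    if float(resid0 @ resid0) / len(y) < 1e-16:
        zero = pd.Series(0.0, index=names)
        nan = pd.Series(np.nan, index=names)
        return LMMResult(
            beta=pd.Series(ols_beta, index=names),
            se=zero,
            t_stats=nan,
            p_values=nan,
            sigma_b=0.0,
            sigma_e=0.0,
            loglik=np.inf,
            aic=-np.inf,
            n_obs=len(y),
            n_groups=len(np.unique(groups)),
            transform=transform,
            fixed_names=names,
        )

    def _ok(r) -> bool:
        return (
            r is not None
            and r.converged
            and np.isfinite(r.llf)
            and np.all(np.isfinite(np.asarray(r.bse_fe)))
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = None
        for method in (None, "powell", "cg"):
            try:
                res = model.fit(reml=False) if method is None else model.fit(
                    reml=False, method=method
                )
            except Exception:
                continue
            if _ok(res):
                break
        if res is None or not np.isfinite(res.llf):
            raise RuntimeError("mixed-model fit failed to converge")
    beta = pd.Series(res.fe_params, index=names)
    se = pd.Series(np.asarray(res.bse_fe), index=names)
    t = beta / se
    p = pd.Series(2.0 * stats.norm.sf(np.abs(t.to_numpy())), index=names)
    llf = float(res.llf)
    return LMMResult(
        beta=beta,
        se=se,
        t_stats=t,
        p_values=p,
        sigma_b=float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0))),
        sigma_e=float(np.sqrt(res.scale)),
        loglik=llf,
        aic=2.0 * k - 2.0 * llf,
        n_obs=len(y),
        n_groups=len(np.unique(groups)),
        transform=transform,
        fixed_names=names,
    )


@dataclass
class ModelComparison:
    """Likelihood-ratio and AIC comparison of two nested ML fits."""

    chi2: float
    df: int
    p: float
    delta_aic: float  # AIC(small) − AIC(big); positive favours the bigger model


def compare_models(fit_a: LMMResult, fit_b: LMMResult) -> ModelComparison:
    """Likelihood-ratio test between nested mixed models on the same data.

    The smaller fixed-effect set must be a subset of the larger; both fits
    must use the same transform and observations.
    """
    small, big = sorted([fit_a, fit_b], key=lambda f: len(f.fixed_names))
    if not set(small.fixed_names) <= set(big.fixed_names):
        raise ValueError("models are not nested")
    if small.transform != big.transform or small.n_obs != big.n_obs:
        raise ValueError("models must be fit to the same data and transform")
    df = len(big.fixed_names) - len(small.fixed_names)
    chi2 = max(2.0 * (big.loglik - small.loglik), 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return ModelComparison(
        chi2=float(chi2), df=df, p=p, delta_aic=float(small.aic - big.aic)
    )


@dataclass
class DensitySurface:
    """Kernel density on an azimuthal-equidistant grid about the colony.

    ``x``/``y`` are cell-centre coordinates in km (east/north of the colony),
    ``density`` is in km⁻² and integrates to ~1 over the padded grid.
    """

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray  # shape (len(y), len(x))
    cell_km: float
    bandwidth_km: float
    points_xy: np.ndarray  # projected observations, shape (n, 2)

    @property
    def integral(self) -> float:
        return float(self.density.sum() * self.cell_km**2)


def project_azimuthal(lat, lon, colony_lat: float, colony_lon: float) -> np.ndarray:
    """Azimuthal-equidistant projection about the colony; returns (n, 2) km."""
    d = great_circle_distance(lat, lon, colony_lat, colony_lon)
    theta = np.radians(initial_bearing(colony_lat, colony_lon, lat, lon))
    return np.column_stack([d * np.sin(theta), d * np.cos(theta)])


def _gaussian_density_on_grid(xy: np.ndarray, gx: np.ndarray, gy: np.ndarray, h: float) -> np.ndarray:
    # separable kernel: density = (Gy @ Gx^T-style product) / (n 2π h²)
    dx = (gx[None, :] - xy[:, 0][:, None]) / h
    dy = (gy[None, :] - xy[:, 1][:, None]) / h
    kx = np.exp(-0.5 * dx**2)
    ky = np.exp(-0.5 * dy**2)
    dens = ky.T @ kx  # (ny, nx)
    return dens / (len(xy) * 2.0 * np.pi * h * h)


def kde_surface(
    lat,
    lon,
    colony_lat: float,
    colony_lon: float,
    cell_m: float = DEFAULT_CELL_M,
    kernel_size_m: float = DEFAULT_KERNEL_SIZE_M,
) -> DensitySurface:
    """Isotropic Gaussian kernel density of locations on a colony-centred grid.

    ``kernel_size_m`` is the kernel extent (diameter), so the Gaussian σ is
    half of it (~3 km size → 1.5 km σ). The grid covers the points plus 4σ
    padding so the density integrates to 1 within 1%.
    """
    if cell_m <= 0 or kernel_size_m <= 0:
        raise ValueError("cell size and kernel size must be positive")
    xy = project_azimuthal(lat, lon, colony_lat, colony_lon)
    if len(xy) == 0:
        raise ValueError("need at least one location")
    h = kernel_size_m / 2.0 / 1000.0  # sigma, km
    cell = cell_m / 1000.0
    pad = 4.0 * h + cell
    x0, x1 = xy[:, 0].min() - pad, xy[:, 0].max() + pad
    y0, y1 = xy[:, 1].min() - pad, xy[:, 1].max() + pad
    gx = np.arange(x0, x1 + cell, cell)
    gy = np.arange(y0, y1 + cell, cell)
    dens = _gaussian_density_on_grid(xy, gx, gy, h)
    return DensitySurface(
        x=gx, y=gy, density=dens, cell_km=cell, bandwidth_km=h, points_xy=xy
    )


def density_at_points(surface: DensitySurface) -> np.ndarray:
    """Exact kernel density evaluated at the observation points themselves."""
    xy = surface.points_xy
    h = surface.bandwidth_km
    d2 = (
        (xy[:, 0][:, None] - xy[:, 0][None, :]) ** 2
        + (xy[:, 1][:, None] - xy[:, 1][None, :]) ** 2
    )
    k = np.exp(-0.5 * d2 / (h * h)).sum(axis=1)
    return k / (len(xy) * 2.0 * np.pi * h * h)


def contour_area_95(
    surface: DensitySurface, coverage: float = 0.95, method: str = "mass"
) -> float:
    """Area (km²) of the smallest density contour with the stated coverage.

    ``method="mass"`` (default, the standard utilization-distribution rule)
    thresholds the density so that the enclosed region holds ``coverage`` of
    the total kernel mass. ``method="points"`` instead sets the threshold at
    the (1−coverage) quantile of the density evaluated at the observations.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    n = len(surface.points_xy)
    if n < 20:
        warnings.warn("contour from fewer than 20 points is unstable", stacklevel=2)
    cell_area = surface.cell_km**2
    dens = surface.density.ravel()
    if method == "mass":
        order = np.argsort(dens)[::-1]
        cmass = np.cumsum(dens[order]) * cell_area
        target = coverage * dens.sum() * cell_area
        k = int(np.searchsorted(cmass, target) + 1)
        threshold = dens[order[min(k, len(dens)) - 1]]
    elif method == "points":
        pd_vals = density_at_points(surface)
        threshold = np.quantile(pd_vals, 1.0 - coverage)
    else:
        raise ValueError("method must be 'mass' or 'points'")
    return float((dens >= threshold).sum() * cell_area)


def check_residual_normality(residuals) -> tuple[float, float]:
    """Shapiro–Wilk test of within-group residuals (Anderson–Darling for n > 5000)."""
    r = np.asarray(residuals, dtype=float)
    if len(r) < 8:
        raise ValueError("need at least 8 residuals")
    if np.std(r) == 0:
        raise ValueError("constant residuals; normality test degenerate")
    if len(r) <= 5000:
        res = stats.shapiro(r)
        return float(res.statistic), float(res.pvalue)
    from statsmodels.stats.diagnostic import normal_ad

    stat, p = normal_ad(r)
    return float(stat), float(p)
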