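"""Trip segmentation, mixed models, model comparison and KDE contours."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import lmm_ml_loglik_oracle
from tideforage.argos import destination_point
from tideforage.foraging import (
    check_residual_normality,
    compare_models,
    contour_area_95,
    fit_lmm,
    kde_surface,
    segment_trips,
)

COLONY = (-64.766667, -64.066667)


def _fixes_from_dhi(dhi_seq, bearing=45.0):
    lat, lon = destination_point(COLONY[0], COLONY[1], bearing, np.asarray(dhi_seq))
    return pd.DataFrame(
        {
            "animal_id": "a",
            "time": pd.Timestamp("2011-01-10", tz="UTC")
            + pd.to_timedelta(np.arange(len(dhi_seq)) * 30, unit="m"),
            "lat": lat,
            "lon": lon,
        }
    )


class TestSegmentTrips:
    def test_hand_example_two_trips(self):
        fixes = _fixes_from_dhi([0.1, 2, 6, 3, 0.2, 4, 7, 0.3])
        trips = segment_trips(fixes, *COLONY)
        assert trips["trip_id"].nunique() == 2
        by = trips.groupby("trip_id")["dhi_km"].apply(list)
        np.testing.assert_allclose(by.iloc[0], [2, 6, 3], rtol=1e-6)
        np.testing.assert_allclose(by.iloc[1], [4, 7], rtol=1e-6)
        assert not trips["open_trip"].any()

    def test_all_colony_no_trips(self):
        trips = segment_trips(_fixes_from_dhi([0.1, 0.2, 0.3]), *COLONY)
        assert len(trips) == 0

    def test_single_excursion_open_trip(self):
        trips = segment_trips(_fixes_from_dhi([0.1, 3, 5, 6]), *COLONY)
        assert trips["trip_id"].nunique() == 1
        assert trips["open_trip"].all()


def _trip_table(dhi, trip_id, regime, amplitude=None, julian=None):
    n = len(dhi)
    return pd.DataFrame(
        {
            "dhi_km": dhi,
            "trip_id": trip_id,
            "regime": regime,
            "amplitude_m": amplitude if amplitude is not None else np.ones(n),
            "julian_day": julian if julian is not None else np.full(n, 10),
        }
    )


# printed 3-trip fixture: two diurnal trips, one semidiurnal, 4 fixes each
FIXTURE_12 = _trip_table(
    dhi=[4.2, 5.0, 6.1, 5.6, 8.3, 9.7, 10.2, 8.9, 5.9, 4.8, 5.1, 6.3],
    trip_id=[1] * 4 + [2] * 4 + [3] * 4,
    regime=["diurnal"] * 4 + ["semidiurnal"] * 4 + ["diurnal"] * 4,
)


class TestFitLMM:
    def test_noiseless_degenerate_fit_exact(self):
        data = _trip_table(
            dhi=[5.4] * 6 + [9.1] * 6,
            trip_id=[1] * 3 + [2] * 3 + [3] * 3 + [4] * 3,
            regime=["diurnal"] * 6 + ["semidiurnal"] * 6,
        )
        fit = fit_lmm(data, "regime")
        assert fit.beta["intercept"] == pytest.approx(5.4, abs=1e-10)
        assert fit.beta["semidiurnal"] == pytest.approx(3.7, abs=1e-10)
        assert fit.sigma_b == 0.0 and fit.sigma_e == 0.0

    def test_loglik_matches_profile_oracle_on_fixture(self):
        fit = fit_lmm(FIXTURE_12, "regime")
        X = np.column_stack(
            [np.ones(12), (FIXTURE_12["regime"] == "semidiurnal").astype(float)]
        )
        ll_oracle = lmm_ml_loglik_oracle(
            FIXTURE_12["dhi_km"].to_numpy(), X, FIXTURE_12["trip_id"].to_numpy()
        )
        assert fit.loglik == pytest.approx(ll_oracle, abs=1e-6)
        assert fit.aic == pytest.approx(2 * 4 - 2 * ll_oracle, abs=1e-5)

    def test_single_regime_rejected(self):
        data = _trip_table([5, 6, 7, 8], [1, 1, 2, 2], ["diurnal"] * 4)
        with pytest.raises(ValueError):
            fit_lmm(data, "regime")

    def test_log10_drops_nonpositive(self):
        data = _trip_table(
            dhi=[5.4, 0.0, 6.0, 9.1, 8.0, 10.0],
            trip_id=[1, 1, 1, 2, 2, 2],
            regime=["diurnal"] * 3 + ["semidiurnal"] * 3,
        )
        with pytest.warns(UserWarning):
            fit = fit_lmm(data, "regime", transform="log10")
        assert fit.n_obs == 5
        assert fit.transform == "log10"


class TestCompareModels:
    def test_identical_models(self):
        f = fit_lmm(FIXTURE_12, "regime")
        cmp_ = compare_models(f, f)
        assert cmp_.chi2 == 0.0 and cmp_.p == 1.0

    def test_nested_regime_full(self):
        rng = np.random.default_rng(0)
        data = _trip_table(
            dhi=np.r_[rng.normal(5.4, 1.0, 20), rng.normal(9.1, 1.0, 20)],
            trip_id=np.repeat(np.arange(8), 5),
            regime=["diurnal"] * 20 + ["semidiurnal"] * 20,
            amplitude=rng.normal(1.0, 0.2, 40),
            julian=rng.integers(5, 40, 40),
        )
        f1, f2 = fit_lmm(data, "regime"), fit_lmm(data, "full")
        cmp_ = compare_models(f1, f2)
        assert cmp_.df == 2
        assert cmp_.chi2 >= 0.0
        assert 0.0 <= cmp_.p <= 1.0

    def test_different_transform_rejected(self):
        f1 = fit_lmm(FIXTURE_12, "regime")
        f2 = fit_lmm(FIXTURE_12, "regime", transform="log10")
        with pytest.raises(ValueError):
            compare_models(f1, f2)


def _cloud(n, sigma_km, seed, center_km=(0.0, 0.0)):
    rng = np.random.default_rng(seed)
    xy = rng.normal(0.0, sigma_km, size=(n, 2)) + np.asarray(center_km)
    dist = np.hypot(xy[:, 0], xy[:, 1])
    bearing = np.degrees(np.arctan2(xy[:, 0], xy[:, 1])) % 360
    lat, lon = destination_point(COLONY[0], COLONY[1], bearing, dist)
    return np.asarray(lat), np.asarray(lon)


class TestKDE:
    def test_single_point_peak_and_unit_mass(self):
        lat, lon = destination_point(COLONY[0], COLONY[1], 45.0, 5.0)
        surf = kde_surface([float(lat)], [float(lon)], *COLONY, cell_m=200, kernel_size_m=3000)
        assert surf.integral == pytest.approx(1.0, abs=0.01)
        iy, ix = np.unravel_index(np.argmax(surf.density), surf.density.shape)
        px, py = surf.points_xy[0]
        assert abs(surf.x[ix] - px) <= surf.cell_km
        assert abs(surf.y[iy] - py) <= surf.cell_km

    def test_two_distant_points_two_equal_modes(self):
        la1, lo1 = destination_point(COLONY[0], COLONY[1], 0.0, 10.0)
        la2, lo2 = destination_point(COLONY[0], COLONY[1], 180.0, 10.0)
        surf = kde_surface(
            [float(la1), float(la2)], [float(lo1), float(lo2)], *COLONY,
            cell_m=500, kernel_size_m=3000,
        )
        top = np.sort(surf.density.ravel())[::-1]
        assert top[0] == pytest.approx(top[1], rel=0.01)

    def test_moments_match_sample_plus_bandwidth(self):
        lat, lon = _cloud(5000, 2.0, seed=1)
        surf = kde_surface(lat, lon, *COLONY, cell_m=250, kernel_size_m=3000)
        w = surf.density / surf.density.sum()
        gx, gy = np.meshgrid(surf.x, surf.y)
        mx, my = (w * gx).sum(), (w * gy).sum()
        vx = (w * (gx - mx) ** 2).sum()
        xy = surf.points_xy
        target_vx = xy[:, 0].var() + surf.bandwidth_km**2
        assert mx == pytest.approx(xy[:, 0].mean(), abs=0.1)
        assert my == pytest.approx(xy[:, 1].mean(), abs=0.1)
        assert vx == pytest.approx(target_vx, rel=0.05)


class TestContourArea:
    def test_gaussian_cloud_matches_closed_form(self):
        lat, lon = _cloud(5000, 2.0, seed=2)
        surf = kde_surface(lat, lon, *COLONY, cell_m=250, kernel_size_m=3000)
        area = contour_area_95(surf)
        s2 = 4.0 + 1.5**2
        expected = np.pi * s2 * stats.chi2.ppf(0.95, 2)
        assert area == pytest.approx(expected, rel=0.15)

    def test_scale_equivariance(self):
        lat1, lon1 = _cloud(2000, 1.5, seed=3)
        surf1 = kde_surface(lat1, lon1, *COLONY, cell_m=150, kernel_size_m=1500)
        lat2, lon2 = _cloud(2000, 3.0, seed=3)
        surf2 = kde_surface(lat2, lon2, *COLONY, cell_m=300, kernel_size_m=3000)
        a1 = contour_area_95(surf1)
        a2 = contour_area_95(surf2)
        assert a2 / a1 == pytest.approx(4.0, rel=0.05)

    def test_tight_cluster_single_kernel_disk(self):
        lat, lon = _cloud(500, 0.01, seed=4, center_km=(3.0, 3.0))
        surf = kde_surface(lat, lon, *COLONY, cell_m=100, kernel_size_m=3000)
        area = contour_area_95(surf)
        expected = np.pi * 1.5**2 * stats.chi2.ppf(0.95, 2)
        assert area == pytest.approx(expected, rel=0.15)

    def test_points_rule_available(self):
        lat, lon = _cloud(2000, 2.0, seed=5)
        surf = kde_surface(lat, lon, *COLONY, cell_m=250, kernel_size_m=3000)
        a_points = contour_area_95(surf, method="points")
        assert a_points > 0
        # observation-quantile rule tracks the unsmoothed spread instead
        assert a_points < contour_area_95(surf, method="mass")


class TestResidualNormality:
    def test_gaussian_residuals_usually_accepted(self):
        rng = np.random.default_rng(6)
        accepted = sum(
            check_residual_normality(rng.normal(size=200))[1] > 0.05 for _ in range(10)
        )
        assert accepted >= 9

    def test_skewed_residuals_rejected(self):
        rng = np.random.default_rng(7)
        rejected = sum(
            check_residual_normality(rng.lognormal(0, 1, 600))[1] < 0.05
            for _ in range(20)
        )
        assert rejected >= 19

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError):
            check_residual_normality(np.ones(50))
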