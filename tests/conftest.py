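"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately use plain loops and textbook
formulas, independent of the library code paths they validate.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from tideforage.argos import EARTH_RADIUS_KM


# ---------------------------------------------------------------- geodesy


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return EARTH_RADIUS_KM * 2 * math.asin(min(1.0, math.sqrt(a)))


# ------------------------------------------------- greedy speed-filter oracle


def greedy_speed_filter_oracle(times_h, lats, lons, quality, vmax) -> list[int]:
    """Plain-loop restatement of the sequential filter; returns kept indices."""
    n = len(times_h)
    kept = list(range(n))
    protected = {i for i in range(n) if str(quality[i]) == "3"} | {0, n - 1}
    while True:
        speeds = []
        for a, b in zip(kept[:-1], kept[1:]):
            dt = times_h[b] - times_h[a]
            d = haversine_km(lats[a], lons[a], lats[b], lons[b])
            if dt <= 0:
                speeds.append(0.0 if d == 0 else float("inf"))
            else:
                speeds.append(d / dt)
        candidates = {}
        for j, sp in enumerate(speeds):
            if sp > vmax:
                for pos in (j, j + 1):
                    idx = kept[pos]
                    if idx in protected:
                        continue
                    adj = []
                    if pos > 0:
                        adj.append(speeds[pos - 1])
                    if pos < len(speeds):
                        adj.append(speeds[pos])
                    candidates[idx] = max(adj)
        if not candidates:
            return kept
        worst = max(candidates.values())
        drop = max(i for i, s in candidates.items() if s == worst)
        kept.remove(drop)


# ------------------------------------------------------ peak-count oracle


def peak_indices_oracle(heights, min_sep_samples, min_prominence) -> list[int]:
    """Strict local maxima -> greedy-by-height distance pruning -> prominence."""
    h = np.asarray(heights, dtype=float)
    n = len(h)
    cand = [i for i in range(1, n - 1) if h[i - 1] < h[i] > h[i + 1]]
    keep: list[int] = []
    for i in sorted(cand, key=lambda i: -h[i]):
        if all(abs(i - j) >= min_sep_samples for j in keep):
            keep.append(i)
    out = []
    for i in keep:
        left = i
        lmin = h[i]
        while left > 0 and h[left] <= h[i]:
            left -= 1
            lmin = min(lmin, h[left])
        right = i
        rmin = h[i]
        while right < n - 1 and h[right] <= h[i]:
            right += 1
            rmin = min(rmin, h[right])
        prominence = h[i] - max(lmin, rmin)
        if prominence >= min_prominence:
            out.append(i)
    return sorted(out)


# --------------------------------------------------- point-in-polygon oracle


def point_in_ring_oracle(x, y, ring) -> bool:
    """Even-odd ray casting against a closed lon/lat ring."""
    inside = False
    pts = list(ring)
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if xint > x:
                inside = not inside
    return inside


# ---------------------------------------------------------- MWW oracle


def mww_w_oracle(scores_group1, scores_group2) -> float:
    c1 = sum(math.cos(g) for g in scores_group1)
    s1 = sum(math.sin(g) for g in scores_group1)
    c2 = sum(math.cos(g) for g in scores_group2)
    s2 = sum(math.sin(g) for g in scores_group2)
    return 2 * (
        (c1 * c1 + s1 * s1) / len(scores_group1)
        + (c2 * c2 + s2 * s2) / len(scores_group2)
    )


# ------------------------------------------ random-intercept ML loglik oracle


def lmm_ml_loglik_oracle(y, X, groups) -> float:
    """Maximum marginal Gaussian log-likelihood over (beta, sigma_b, sigma_e).

    Profiles beta by GLS at each variance pair and maximizes numerically over
    the two log-variances from several starting points.
    """
    from scipy.optimize import minimize

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)

    def loglik(log_vb, log_ve) -> float:
        vb, ve = np.exp(log_vb), np.exp(log_ve)
        XtVX = np.zeros((X.shape[1], X.shape[1]))
        XtVy = np.zeros(X.shape[1])
        pieces = []
        for g in uniq:
            m = groups == g
            ni = int(m.sum())
            Xi, yi = X[m], y[m]
            # (ve I + vb J)^-1 = (1/ve)(I - c J), c = vb / (ve + ni vb)
            c = vb / (ve + ni * vb)
            Xs = Xi.sum(axis=0)
            ys = yi.sum()
            XtVX += (Xi.T @ Xi - c * np.outer(Xs, Xs)) / ve
            XtVy += (Xi.T @ yi - c * Xs * ys) / ve
            pieces.append((Xi, yi, ni, c))
        beta = np.linalg.solve(XtVX, XtVy)
        ll = 0.0
        for Xi, yi, ni, c in pieces:
            r = yi - Xi @ beta
            quad = (r @ r - c * r.sum() ** 2) / ve
            logdet = (ni - 1) * np.log(ve) + np.log(ve + ni * vb)
            ll += -0.5 * (ni * np.log(2 * np.pi) + logdet + quad)
        return ll

    best = -np.inf
    var_y = np.var(y)
    for fb in (0.05, 0.3, 0.7):
        x0 = [np.log(max(var_y * fb, 1e-6)), np.log(max(var_y * (1 - fb), 1e-6))]
        res = minimize(
            lambda p: -loglik(p[0], p[1]),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        best = max(best, -res.fun)
    return float(best)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def mixed_tide():
    """Noise-free K1+O1+M2+K2 series spanning 30 days at 6-min sampling."""
    from tideforage.synthetic import default_constituents, gen_tide_series

    return gen_tide_series(default_constituents(), "2011-01-01", 30, dt_min=6.0)


@pytest.fixture(scope="session")
def block_calendar():
    """Deterministic calendar: alternating 4-day diurnal/semidiurnal blocks.

    Amplitudes vary day to day around regime means so the amplitude covariate
    is not collinear with regime.
    """
    rng = np.random.default_rng(20110105)
    dates = pd.date_range("2011-01-01", periods=32, freq="D")
    regime = [("diurnal" if (i // 4) % 2 == 0 else "semidiurnal") for i in range(32)]
    amp = [
        (1.23 if r == "diurnal" else 0.93) + rng.normal(0, 0.15) for r in regime
    ]
    cal = pd.DataFrame(
        {
            "date": dates,
            "regime": regime,
            "n_high_tides": [1 if r == "diurnal" else 2 for r in regime],
            "amplitude_m": amp,
        }
    )
    cal.attrs["day_offset_hours"] = -3.0
    return cal
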