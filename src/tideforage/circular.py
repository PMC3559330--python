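"""Circular statistics for comparing current-bearing distributions.

The Mardia–Watson–Wheeler (uniform-scores) test compares two samples of
angles nonparametrically: the pooled angles are ranked around the circle,
ranks are mapped to uniform scores γ_k = 2π·rank_k/N, and the statistic

    W = 2 · Σ_i (C_i² + S_i²) / n_i,   C_i = Σ cos γ, S_i = Σ sin γ over sample i,

is asymptotically χ² with 2 df under the null of a common distribution. It is
the appropriate two-sample test when bearings are not von Mises distributed —
which the Watson U² goodness-of-fit test (with maximum-likelihood von Mises
fit and parametric bootstrap p-value) checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import special, stats

__all__ = ["MWWResult", "mww_test", "fit_vonmises", "watson_u2", "vonmises_gof"]


@dataclass
class MWWResult:
    """Outcome of the Mardia–Watson–Wheeler two-sample test."""

    W: float
    p_asymptotic: float
    p_permutation: float | None
    n1: int
    n2: int

    @property
    def p(self) -> float:
        return self.p_permutation if self.p_permutation is not None else self.p_asymptotic


def _uniform_scores(angles_deg: np.ndarray) -> np.ndarray:
    """Circular ranks of the pooled sample mapped to angles; ties share averaged ranks."""
    a = np.mod(angles_deg, 360.0)
    ranks = stats.rankdata(a, method="average")
    return 2.0 * np.pi * ranks / len(a)


def _w_statistic(gamma: np.ndarray, idx1: np.ndarray, n1: int, n2: int) -> float:
    mask = np.zeros(len(gamma), dtype=bool)
    mask[idx1] = True
    c, s = np.cos(gamma), np.sin(gamma)
    c1, s1 = c[mask].sum(), s[mask].sum()
    c2, s2 = c[~mask].sum(), s[~mask].sum()
    return 2.0 * ((c1 * c1 + s1 * s1) / n1 + (c2 * c2 + s2 * s2) / n2)


def mww_test(
    angles_a,
    angles_b,
    method: str = "asymptotic",
    n_perm: int = 9999,
    seed: int | None = None,
) -> MWWResult:
    """Mardia–Watson–Wheeler uniform-scores test on two angle samples (degrees).

    ``method="asymptotic"`` uses the χ²(2 df) approximation;
    ``method="permutation"`` additionally resamples group labels. When the
    number of distinct label assignments C(N, n1) does not exceed ``n_perm``
    the permutation p-value is computed by exhaustive enumeration, otherwise
    by ``n_perm`` seeded random permutations with the +1 correction.
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least two angles")
    pooled = np.concatenate([a, b])
    if np.allclose(np.mod(pooled, 360.0), np.mod(pooled[0], 360.0)):
        warnings.warn("all angles identical; MWW test degenerate", stacklevel=2)
        return MWWResult(0.0, 1.0, 1.0 if method == "permutation" else None, n1, n2)
    gamma = _uniform_scores(pooled)
    idx1 = np.arange(n1)
    W = _w_statistic(gamma, idx1, n1, n2)
    p_asym = float(stats.chi2.sf(W, 2))
    p_perm = None
    if method == "permutation":
        N = n1 + n2
        total = math.comb(N, n1)
        tol = 1e-12
        if total <= n_perm:
            count = sum(
                _w_statistic(gamma, np.array(c), n1, n2) >= W - tol
                for c in combinations(range(N), n1)
            )
            p_perm = count / total
        else:
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(N)[:n1]
                if _w_statistic(gamma, perm, n1, n2) >= W - tol:
                    count += 1
            p_perm = (count + 1) / (n_perm + 1)
    elif method != "asymptotic":
        raise ValueError("method must be 'asymptotic' or 'permutation'")
    return MWWResult(float(W), p_asym, p_perm, n1, n2)


def _a1(kappa: float) -> float:
    """Mean resultant length of a von Mises distribution, I1(κ)/I0(κ)."""
    return special.i1e(kappa) / special.i0e(kappa)


def fit_vonmises(angles_deg) -> tuple[float, float]:
    """Maximum-likelihood von Mises fit: returns (mu_deg in [0,360), kappa).

    κ solves A1(κ) = R̄ by Newton iteration (tolerance 1e-10) from the
    Best–Fisher series starting values; R̄ ≈ 0 gives κ = 0 (uniform limit).
    """
    theta = np.radians(np.asarray(angles_deg, dtype=float))
    c, s = np.cos(theta).mean(), np.sin(theta).mean()
    rbar = float(np.hypot(c, s))
    mu = math.degrees(math.atan2(s, c)) % 360.0
    if rbar < 1e-8:
        return mu, 0.0
    if rbar < 0.53:
        k = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        k = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k = 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
    k = max(k, 1e-8)
    for _ in range(100):
        f = _a1(k) - rbar
        if abs(f) < 1e-10:
            break
        a1 = _a1(k)
        deriv = 1.0 - a1 * a1 - a1 / k
        if deriv <= 0:
            break
        step = f / deriv
        k = max(k - step, 1e-10)
        if k > 1e8:
            k = 1e8
            break
    return mu, float(k)


def watson_u2(angles_deg, mu_deg: float, kappa: float) -> float:
    """Watson U² statistic of a sample against a given von Mises distribution."""
    theta = np.radians(np.mod(np.asarray(angles_deg, dtype=float) - mu_deg, 360.0))
    theta = np.where(theta > np.pi, theta - 2 * np.pi, theta)  # to [-pi, pi]
    if kappa < 1e-8:  # uniform limit
        u = np.sort((theta + np.pi) / (2 * np.pi))
    else:
        u = np.sort(stats.vonmises.cdf(theta, kappa))
    n = len(u)
    i = np.arange(1, n + 1)
    ubar = u.mean()
    return float(np.sum((u - (2 * i - 1) / (2 * n) - ubar + 0.5) ** 2) + 1.0 / (12 * n))


def vonmises_gof(
    angles_deg, n_boot: int = 500, seed: int | None = None
) -> tuple[float, float]:
    """Von Mises goodness of fit: Watson U² with parametric-bootstrap p.

    Fits (μ, κ) by ML, computes U² against the fitted distribution, then
    bootstraps the null distribution of U² by drawing samples of the same size
    from the fit and refitting each. Returns (U², p).
    """
    angles = np.asarray(angles_deg, dtype=float)
    n = len(angles)
    if n < 10:
        raise ValueError("need at least 10 angles for a goodness-of-fit test")
    mu, kappa = fit_vonmises(angles)
    u2_obs = watson_u2(angles, mu, kappa)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        if kappa < 1e-8:
            sample = rng.uniform(0.0, 360.0, size=n)
        else:
            sample = np.degrees(stats.vonmises.rvs(kappa, size=n, random_state=rng)) + mu
        mu_b, kappa_b = fit_vonmises(sample)
        if watson_u2(sample, mu_b, kappa_b) >= u2_obs:
            count += 1
    p = (count + 1) / (n_boot + 1)
    return u2_obs, float(p)
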