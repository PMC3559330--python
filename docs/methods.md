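# Methods

This note documents the models and procedures implemented in `tideforage`,
the defaults and why they were chosen, what the synthetic-data generator
emulates, and the package's known limitations.

## Tidal regime classification

A mixed coastal tide is synthesized/observed as sea level h(t); high tides
are local maxima with minimum separation 8 h and minimum topographic
prominence 0.1 m (`scipy.signal.find_peaks`). The separation default keeps
the two highs of a ~12.4 h semidiurnal day distinct (≈ 12.4 h apart) while
rejecting ripple; the prominence floor suppresses noise-scale bumps. Each
calendar day is labelled by its high-tide count: exactly one → diurnal, two
or more → semidiurnal, zero → unclassified (a gauge gap; fixes on such days
are dropped from the models, with a warning). Daily amplitude is
(max − min)/2 of that day's heights.

Day boundaries are taken in station-local time: timestamps are shifted by a
configurable offset (default −3 h, the local solar offset of the study
region; the choice only moves day boundaries and is documented rather than
physically derived). Regime "periods" are contiguous runs of same-labelled
days.

## ARGOS track cleaning

Quality classes 3/2/1 carry nominal 95% error radii of 100/250/1500 m;
classes 0/A/B carry no error estimate. Cleaning:

1. **Land mask** — fixes strictly inside any mask polygon are rejected
   (boundary points are kept: a bird at the waterline is a valid position).
2. **Sequential speed filter** — among fixes adjacent to a consecutive
   retained pair whose implied great-circle speed exceeds 8 km h⁻¹ (the
   species' maximum sustained swimming speed), the fix with the largest
   implied speed is removed (ties → the later fix), and the scan repeats to
   a fixed point. Class 3 fixes and the first/last fix of a track are never
   removed. The rule is deliberately simple enough to verify against an
   independent brute-force implementation; a turning-angle spike test, as in
   more elaborate published filters, is not included.
3. **Manual rejections** — a per-fix rejection list can stand in for visual
   track inspection; no automated coastal-geometry reasoning is attempted.

Great-circle distances use the haversine formula on a sphere of radius
6371.0088 km.

## Dive processing

TDR pressure sensors drift, so the surface reading wanders from 0 m. The
zero-offset correction subtracts a baseline built in two passes: a centred
running 5% quantile over 120 s (the surface level between dives), then a
morphological opening (running minimum followed by running maximum, both
centred, 1800 s). The opening removes dive excursions from the baseline —
any dive shorter than the window borrows its baseline from the flanking
surface intervals — while tracking monotone drift with no lag. The window
defaults span surface intervals but not whole foraging bouts; dives longer
than ~28 min would leak into the baseline.

Foraging dives are maximal runs strictly deeper than 5 m (an excursion to
exactly 5 m is not a dive). A location fix is a foraging location iff its
minimum temporal gap to any dive *interval* is ≤ 150 s, boundary inclusive
(gap 0 inside the interval). Measuring to the interval rather than the dive
start is a deliberate reading of "within 150 seconds of a dive"; it is
monotone in the window size.

## Glider-derived currents

Between GPS surfacings a glider dead-reckons by compass and speed through
water; the displacement from its dead-reckoned surfacing position to the GPS
fix, divided by the submerged duration, estimates the 0–100 m
depth-integrated current for that ~2 h segment. The displacement is
decomposed into east/north metres via geodesic range and initial bearing —
numerically a local-tangent-plane quantity, but free of the
meridian-convergence error (~0.2% per km of easting at 65°S) that plain
equirectangular differencing would introduce. Bearings are
"direction toward", clockwise from true north; quadrant fractions partition
[0°, 360°) into NE/SE/SW/NW quarters. Segments spanning a regime switch are
labelled by their midpoint time.

Speed comparisons between regimes use Welch's t (unequal variances,
Welch–Satterthwaite df); wind–current coupling uses Pearson r with
t = r√(df/(1−r²)), df = n − 2.

## Circular statistics

The Mardia–Watson–Wheeler test ranks the pooled bearings around the circle,
maps ranks to uniform scores γ_k = 2π·rank_k/N (ties get averaged ranks —
only relevant for rounded synthetic data), and computes
W = 2·Σ_i (C_i² + S_i²)/n_i from the per-sample score resultants. p-values
come from the asymptotic χ²(2) distribution or from label permutations —
exhaustive enumeration whenever C(N, n1) ≤ n_perm, otherwise seeded random
permutations with the (count+1)/(n_perm+1) estimator. A pooled sample with
zero circular spread returns W = 0, p = 1 with a warning.

Von Mises goodness of fit: μ̂ is the mean direction; κ̂ solves
I₁(κ)/I₀(κ) = R̄ by Newton iteration (tolerance 1e-10) from the Best–Fisher
series starts, with κ̂ = 0 in the uniform limit. Watson's U² is computed
against the fitted CDF and its p-value by parametric bootstrap (refitting
each bootstrap sample).

## Mixed models of foraging distance

The response DHI is the great-circle distance (km) of a fix from the colony.
Trips — maximal runs of fixes farther than 0.5 km from the colony, delimited
by returns — absorb within-trip spatial autocorrelation as a Gaussian random
intercept. Two fixed-effect structures are fit by **maximum likelihood**
(never REML, so AICs and likelihood-ratio tests are comparable across
fixed-effect sets): regime only, and regime + daily tidal amplitude +
Julian day. The amplitude covariate is the *daily* amplitude of the fix's
day (not instantaneous height); Julian day is the day-of-year in station
local time. Fits use `statsmodels.MixedLM`; the default optimizer is
validated (convergence, finite log-likelihood and standard errors) with
Powell/CG fallbacks. AIC = 2k − 2ℓ with k counting fixed effects plus the
two variance parameters. t-ratios use the normal approximation for p-values
(no Satterthwaite df correction); with the ≥ 150 observations per model this
is a second-order issue. Exactly noise-free inputs short-circuit to the OLS
solution with σ_b = σ_e = 0 and an undefined (infinite) log-likelihood.
Where residuals of the identity-scale model are non-normal
(Shapiro–Wilk; Anderson–Darling above n = 5000), the response is log10
transformed; non-positive distances cannot enter the log model and are
dropped with a warning.

Model comparison: χ² = 2(ℓ_big − ℓ_small), df = difference in fixed-effect
count, plus ΔAIC (reported as AIC_small − AIC_big).

## Kernel utilization contours

Locations are projected to an azimuthal-equidistant plane about the colony.
An isotropic Gaussian kernel density is evaluated on a square grid (cell
725 m) padded by 4σ so the density integrates to 1 ± 0.01. The "~3 km
kernel" is read as the kernel *extent* (diameter), hence σ = 1.5 km; both
are configurable. The 95% contour is the density-mass (volume) contour — the
smallest-density threshold whose superlevel set holds 95% of the kernel
mass, the standard utilization-distribution rule; its area is the count of
qualifying cells × cell area. An alternative rule that thresholds at the 5th
percentile of the density evaluated at the observations themselves is
available (`method="points"`); it tracks the unsmoothed point spread and was
not adopted as the default because it disagrees with the closed-form
smoothed-Gaussian area that the mass rule reproduces (for an N(0, σ²I)
cloud with kernel σ_h the 95% mass contour has area π(σ² + σ_h²)·χ²₀.₉₅(2),
against which the implementation is tested to 15%).

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions the analysis assumes:

* **Tide** — K1 (0.55 m), O1 (0.50 m), M2 (0.38 m), K2 (0.12 m) harmonics:
  the K1–O1 beat (period ≈ 13.7 d) alternates multi-day diurnal episodes
  with semidiurnal episodes; daily amplitudes average ≈ 1.1 m on diurnal and
  ≈ 0.65 m on semidiurnal days. Amplitudes are configuration, not constants;
  a harmonic quartet cannot simultaneously match every observed amplitude
  statistic of a real mixed-mainly-diurnal station, and the episode
  *structure* was prioritized.
* **Trips** — 23-day season, 30 trips across 11 birds, 22 fixes per trip at
  30-min intervals (~660 at-sea fixes). Per-fix true distance is
  β(regime) + b_trip + ε with β_diurnal = 5.4 km, β_semidiurnal = 9.1 km,
  σ_b = 1.4 km, σ_e = 2.0 km; draws are arranged into an out-and-back
  profile (statistically free: the mixed-model likelihood is
  permutation-invariant within trips) and the trip is bracketed by colony
  fixes a ≥ 90-min transit away, so the underlying track respects the 8 km/h
  bound. Trip headings fall in a seaward 10–130° sector. Trips are
  distance-draw constructs matching the statistical model — there is no
  correlated-random-walk movement model, no behavioural time budget, and
  within-trip residuals are exchangeable rather than serially correlated as
  real tracks would be.
* **ARGOS error** — classes drawn per fix (10/15/20/15/20/20% for
  3/2/1/0/A/B); classes 3/2/1 get isotropic Gaussian error scaled so the
  stated accuracy is the 95% radius, classes 0/A/B get bivariate t(3 df)
  error at 1.5/3/10 km scales (their accuracy is unspecified in the ARGOS
  system documentation; heavy tails produce the spikes the speed filter
  exists for). A 3% fraction of non-class-3 fixes is displaced onto a toy
  island to exercise the land mask.
* **TDR** — 1 Hz records per trip with 0.005 m/min linear drift, 5 cm
  noise, and 90 s square dives (15–80 m) at ~35% of fix times, 30 s before
  the fix so the 150 s merge window captures it.
* **Glider** — Cartesian simulation of waypoint-seeking at 0.35 m/s through
  water, advected by a configurable current field, surfacing every 2 h with
  15 m GPS noise. The default field is an along-canyon (NE) flow whose mean
  is modulated by the K1–O1 beat envelope (phase-aligned with the tide
  series): diurnal episodes have strong (~0.14 m/s) flow that never
  reverses; semidiurnal episodes weaker (~0.10 m/s) flow with partial M2
  reversals, plus a small cross-canyon wobble. This reproduces the
  qualitative regime contrast (stronger, steadier, more northeastward
  diurnal currents) without any claim of dynamical realism.
* **Wind** — an AR(1) speed series independent of the currents, so
  wind–current correlations are null by construction.

Passing tests on these data demonstrate the *algorithms* (filters, tests,
estimators) and the estimators' calibration under the assumed model; they do
not validate the model against real penguin movement, real ARGOS error
structure, or real shelf circulation.

## Numerical choices and degenerate inputs

* Problem sizes in the test suite (200-replicate recovery and type-I runs,
  500-replicate LRT calibration, 5000-replicate MWW calibration) were chosen
  to bound Monte-Carlo error at the few-percent level while keeping the
  default suite around a minute of compute.
* Speed-filter ties break toward the later fix; fixes with zero time gap and
  zero distance imply speed 0, with positive distance speed ∞.
* The KDE grid auto-pads by 4σ; a single location yields a unimodal surface
  integrating to 1. Contours from fewer than 20 points warn (the percentile
  and mass thresholds are then unstable).
* Seeds: every generator takes an explicit seed; the pipeline derives
  per-stage seeds from one master seed via `numpy.random.SeedSequence`, so
  reports are byte-identical across reruns.

## Limitations

* The speed filter omits the turning-angle test of more elaborate published
  trackers; on heavy-tailed class A/B errors this removes slightly fewer
  borderline spikes.
* Mixed-model inference uses normal-approximation p-values; for designs with
  few trips a Satterthwaite or bootstrap correction would be preferable.
* Regime classification is binary by high-tide count; no harmonic analysis
  of the observed gauge record (constituent fitting) is performed.
* No map rendering, bathymetry handling, or ecological interpretation of the
  fitted effects is included.
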