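# tideforage

Analysis pipeline linking coastal tidal dynamics to the foraging locations of
a central-place marine predator — Adélie penguins (*Pygoscelis adeliae*)
breeding on a small Antarctic island near a submarine canyon. Mixed coastal
tides switch on roughly weekly timescales between a **diurnal** regime (one
high tide per day, when the K1+O1 constituents beat in phase) and a
**semidiurnal** regime (two highs per day, when M2+K2 dominate). The question
the pipeline answers: does that regime switching — rather than day-to-day
tidal amplitude or seasonal date — predict how far from the colony the birds
forage?

It is written for movement ecologists and biologging analysts who need the
full chain from raw instrument records to the statistical comparison:

1. **Tide gauge → regime calendar** (`tideforage.tides`): high tides are
   local maxima of the sea-level record (≥ 8 h apart, ≥ 0.1 m prominence);
   each day is diurnal (exactly one high), semidiurnal (two or more) or
   unclassified (gauge gap), with daily amplitude (max − min)/2.
2. **ARGOS track cleaning** (`tideforage.argos`): land-mask rejection plus a
   sequential filter that greedily removes fixes implying swimming speeds
   above 8 km h⁻¹ between consecutive retained locations (quality class 3
   fixes and track endpoints are immune).
3. **Dive records** (`tideforage.dives`): zero-offset correction of 1 Hz
   time–depth-recorder series (running-quantile baseline + morphological
   opening), detection of foraging dives (> 5 m), and labelling of any
   location fix within 150 s of a dive as a foraging location.
4. **Glider currents** (`tideforage.currents`): 0–100 m depth-integrated
   currents from the displacement between where an underwater glider
   dead-reckoned itself and where GPS found it at each surfacing, with Welch
   *t*, quadrant fractions and wind–current correlation by regime.
5. **Circular statistics** (`tideforage.circular`): the Mardia–Watson–Wheeler
   uniform-scores test for comparing bearing distributions between regimes
   (χ², 2 df asymptotics, exact/permutation option) and a Watson U² von Mises
   goodness-of-fit test with parametric bootstrap.
6. **Foraging statistics** (`tideforage.foraging`): trips are maximal runs of
   fixes beyond 0.5 km of the colony; the distance of each fix from the
   colony (DHI, km) is modelled by maximum likelihood with a random intercept
   per trip,

   DHI_ijk = β·regime_i + b_j + ε_ijk        (regime-only model)

   DHI_ijk = X_ijl·β_l + b_j + ε_ijk         (regime + amplitude + Julian day)

   with b_j ~ N(0, σ_b²), ε ~ N(0, σ_e²); the two fixed-effect structures are
   compared by a 2-df likelihood-ratio test and AIC. Spatial use per regime
   is summarized by a Gaussian kernel density (725 m grid, ~3 km kernel) and
   its 95% utilization-contour area.
7. **Synthetic data** (`tideforage.synthetic`): seeded generators for every
   input — harmonic tides, regime-dependent foraging trips wrapped in
   class-dependent ARGOS error, drifting TDR records, glider missions through
   a known current field, wind — so the whole pipeline is testable without
   any field data.

## Worked example

A full synthetic season (23 days, 30 trips, 11 birds) from one YAML config:

```yaml
# run.yaml
seed: 1
outdir: demo_out
synthetic:
  seed: 1
```

```text
$ tideforage all --config run.yaml
{
  "n_input": 720,
  "n_retained": 521,
  "pct_removed": 27.63888888888889,
  "n_removed_land": 21,
  "n_removed_speed": 178
}
diving-location regime effect 3.14 km (p=0.0000)
report written to demo_out/report.json
```

Reading the output: of 720 raw ARGOS fixes, 27.6% are discarded (21 on land,
178 above the 8 km h⁻¹ speed bound). On the retained diving locations the
mixed model estimates that birds forage 3.14 km farther from the colony
during semidiurnal tides than during diurnal tides (normal-approximation
p ≈ 10⁻⁹ for this seed; the generator's true effect is 9.1 − 5.4 = 3.7 km).
`demo_out/report.json` additionally holds the regime calendar summary, the
regime + amplitude + Julian-day model and its likelihood-ratio comparison
(which correctly finds no amplitude or day-of-season effect), per-regime
95% kernel contour areas, and the glider-current statistics (Welch *t* on
speeds, Mardia–Watson–Wheeler W on bearings, quadrant fractions,
wind–current correlations).

The same stages are importable directly, e.g.

```python
from tideforage import tides, foraging
cal = tides.build_regime_calendar(tide_df)          # date, regime, amplitude
fit = foraging.fit_lmm(trip_table, "regime")           # random-intercept ML fit
print(fit.regime_effect, fit.p_values["semidiurnal"], fit.aic)
```

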