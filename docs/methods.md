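# Methods

## The analysis model

`aqoi` produces hourly surface concentration maps by optimal interpolation
(OI): a gridded short-term model forecast `x^f` (the first guess, or trial
field) is corrected by station observations `y^o`,

    x^a = x^f + K (y^o − H x^f),

where `H` is bilinear interpolation from the grid to the stations and the
gain `K = (HB)^T (H(HB)^T + R)^{-1}` minimizes the analysis error variance
for prescribed, stationary error statistics.  The background error
covariance is homogeneous and isotropic with an exponential (first-order
autoregressive, FOAR) correlation,

    H(HB)^T(k1, k2) = σf(k1) σf(k2) exp(−d(k1,k2)/Lc),
    (HB)^T(i,j, k)  = σf_grid σf(k) exp(−d((i,j),k)/Lc),

with great-circle distances on a 6371-km sphere.  The observation error
covariance `R` is diagonal.  The station-space innovation matrix
`A = H(HB)^T + R` is symmetric positive definite, factorized once per
analysis by Cholesky; if factorization fails, a single diagonal jitter of
`1e−8·tr(A)/n` is tried before failing with the closest station pair named.
Stations closer than 1 km are averaged into a pseudo-station first, which
removes the main practical cause of ill-conditioning.

The grid-side `σf_grid` is the domain mean background error standard
deviation (homogeneous assumption); station-side `σf(k)` may be local when
a per-station estimate exists.  Statistics are allowed to differ by hour
and season (stratum), which lets the analysis follow the diurnal cycle; the
small synthetic experiments in this repository use a single "all" stratum.

## Error statistics

Two independent estimators feed the background error variance `σ_B²`:

1. **Innovation variogram.**  Per-station observation-minus-forecast (OmP)
   series are paired across stations; the covariance of each pair is binned
   by separation (bins of 20 km out to 500 km, bins kept with ≥ 10 pairs,
   stations kept with ≥ 30 paired hours) and fitted, origin excluded, with
   `c(d) = σf² exp(−d/Lc)` by pair-count-weighted nonlinear least squares.
   The intercept `σf²` is the spatially correlated (background) part; the
   nugget `varOmP(0) − σf²` is the uncorrelated part, identified with the
   observation error `σ_o²` including representativeness.  By construction
   `σ_B² + σ_o² = varOmP`.
2. **Representativeness scaling.**  `σ_o² = σ_instr² (1 + nΔx/(4 L_repr))`
   with the effective-resolution factor `n = 4` (structures finer than 4Δx
   are unresolved), grid spacing `Δx` in km, and representativeness lengths
   `L_repr` = 10, 4, 2 km for rural, suburban, urban sites.  No tuning
   factor is applied.  `σ_B²` then follows as `varOmP − σ_o²`; stations
   where that residual is non-positive are flagged unusable.

When both routes succeed, their `σ_B²` estimates are blended by arithmetic
mean — the announced blending has no published formula, and the mean is the
neutral choice.  Fitted correlation lengths are *estimated but not used* by
default: variogram-derived lengths for surface pollutants are known to come
out too long, so the analysis uses prescribed defaults (O3 60 km,
PM2.5 60 km, PM10 40 km, NO2 20 km), all configurable within 5–500 km.

The analytic relations `1/σ_a² = 1/σ_B² + 1/σ_o²` and
`σ_a²/σ_B² = 1/(1+λ)` with `λ = σ_B²/σ_o²` are exposed directly; λ = 2
(typical of the longer-lived pollutants) implies a threefold error-variance
reduction, λ = 1 a twofold one.

## Quality control

Three flag-only stages: a range check against per-pollutant physical
bounds, an hourly-jump check (never applied to the first record or across a
gap in the hourly sequence), and a background check
`|O − P| > k √(σ_B² + σ_o²)` with `k = 4`.  Equality never flags; any flag
rejects; values are never altered.  All thresholds here are configurable
defaults standing in for unpublished operational values, and stage-by-stage
rejection counts are reported with every analysis.

## Bias correction

Within a user-supplied polygon the spatial mean innovation `b = mean(O−P)`
over in-region stations (minimum 5) is added to the forecast; outside, the
correction decays as `b·exp(−d/decay_km)` (default 100 km) with `d` the
great-circle distance to the boundary, sampled at ≤ 5 km.  The correction
is therefore continuous, bounded by `|b|`, and with several regions the
nearest region alone applies (no double counting).  Correction precedes
innovation computation, so the OI sees debiased innovations.

## AQHI

Exact index: `(10/10.4)·100·Σ (e^{c_i x_i} − 1)` with c = 0.000871 (NO2,
ppbv), 0.000537 (O3, ppbv), 0.000487 (PM2.5, µg/m³); linearized:
`(0.871·NO2 + 0.537·O3 + 0.487·PM2.5)/10.4`.  Over mixtures where the
three pollutants contribute equally and the exact index stays ≤ 10, the
linearization undershoots by at most ~1.7 % (< 2 %); the bound does *not*
hold for single-pollutant extremes (≈ 5 % when one term alone reaches 10),
so the equal-contribution domain is the one tested.  Categories use
round-half-up with a floor of 1: 1–3 Low, 4–6 Moderate, 7–10 High, > 10
Extreme.  The rolling 3-h mean is trailing (current + two previous hours)
and undefined whenever an hour is missing.  Gridded AQHI is a *pseudo*
objective analysis — the exact formula applied cellwise to the three
pollutant analyses (clipped at zero, since strong negative increments can
push an analysis slightly negative), with a residual panel exact − linear.
The seasonal climatology reports the percent of valid hours with index
strictly above 3 per cell and DJF/MAM/JJA/SON season, with cells under 1 %
marked as effectively unpolluted.

## Validation

Metrics: mean bias, residual standard deviation, and FC2 (fraction of
predictions within a factor two of the observation, inclusive bounds,
computed only for observed values ≥ 1 concentration unit).  Cross-
validation splits by *station* (so holdout series are wholly unseen), runs
three independent replicates, pools their holdout pairs, and per UTC hour
applies a two-sided unpaired Welch t-test to mean(OmP) vs mean(OmA) and a
two-sided F-ratio test to their variances, flagging p < 0.05.  The paired
vs unpaired choice is not specified anywhere authoritative; unpaired is
used and recorded in the report metadata.

## Synthetic scenes

The generator draws truth fields as Gaussian random fields with exponential
covariance (dense Cholesky of the cell-to-cell covariance — exact, cached,
limited to ≤ 5000 cells), forecasts as truth + a correlated error field of
variance `σ_B²` (+ optional constant regional offsets), and observations as
bilinear truth at the station + white noise with the land-use
representativeness variance.  Defaults describe a ~400-km mid-latitude
domain at 10-km nominal spacing, 200 stations, PM2.5-like magnitudes
(`σ_B² = 25`, `Lc = 60 km`, `σ_instr² = 4`, so rural `σ_o² = 8`), 24 hours.
Hours are independent draws: the generator models spatial, not temporal,
error correlation, consistent with the diagonal-R, time-white assumption of
the analysis.  Real data differ in ways the generator deliberately omits —
non-Gaussian concentration distributions, diurnally varying and
inhomogeneous error statistics, temporally correlated representativeness
error, irregular station density — so passing tests demonstrate internal
consistency of the method under its own assumptions, not skill on real
networks.

## Problem sizes and numerical choices

Tests run the variogram recovery at 200 stations × 500 hours and the
cross-validation at a 30 × 30 grid, 200 stations, 24 hours, 3 replicates —
sizes at which dense linear algebra is exact and fast while sampling error
stays well inside the 20 % recovery tolerances.  The cross-validation check
uses the 75–25 split: at the expected holdout variance ratio (~1.7 for
λ = 2) the pooled 150 pairs/hour give the F-test high power, whereas 90–10
(60 pairs/hour) leaves it near coin-flip power — the same power argument
that motivates 75–25 for sparsely observed pollutants operationally.  In
the regional-bias check, the offset is estimated over a region inset by
~1.5 grid cells, because the cellwise offset step is smeared across
boundary cells by bilinear interpolation; the inset isolates the
discretization effect from the estimator.

## Known limitations

Homogeneous isotropic correlations only (inhomogeneous/anisotropic OI is
out of scope by design); no χ² consistency diagnostic; no temporal error
correlation; bias estimation shares the error-statistics stratum rather
than having its own windowing; NetCDF output is NetCDF3 (scipy backend).
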