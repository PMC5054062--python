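# aqoi — surface air-quality objective analysis

Hourly maps of surface pollutant concentrations (O3, NO2, PM2.5, PM10) and
of the Air Quality Health Index (AQHI), produced by statistically fusing
station observations with a gridded model first guess.  Point measurements
are accurate but sparse; model forecasts cover everywhere but carry biases
and larger errors.  Optimal interpolation (OI) blends the two into an
analysis whose error variance is smaller than either input's, giving air
quality forecasters, epidemiologists and policy analysts a defensible
exposure surface where no monitor exists.

The analysis update is

```
x^a = x^f + K (y^o − H x^f),      K = (HB)^T (H(HB)^T + R)^{-1}
```

with `x^f` the first-guess grid, `H` bilinear interpolation to stations,
and an exponential (FOAR) background error correlation
`σf(k1) σf(k2) exp(−d/Lc)`.  Error statistics come from the innovations
themselves: station-pair OmP covariances binned by distance and fitted with
`σf² exp(−d/Lc)` give the background variance `σ_B²` (intercept) and the
observation error `σ_o²` (nugget), blended with a representativeness model
`σ_o² = σ_instr² (1 + nΔx/(4 L_repr))` keyed to land use (rural/suburban/
urban).  On top of the pollutant analyses the package computes the AQHI

```
AQHI = (10/10.4) · 100 · [(e^(0.000871·NO2) − 1) + (e^(0.000537·O3) − 1)
                          + (e^(0.000487·PM2.5) − 1)]
```

as a gridded *pseudo* objective analysis, with risk categories Low 1–3,
Moderate 4–6, High 7–10, Extreme > 10, plus a seasonal exceedance
climatology (percent of hours above index 3).

Because no public observation/forecast archive ships with the package, a
first-class synthetic-scene generator provides truth fields, forecasts and
observations with exactly the statistical structure the method assumes, so
every stage — QC, error-statistics estimation, bias correction, analysis,
cross-validation — is testable against a known truth.

## Worked example

```python
import numpy as np
from aqoi import (SyntheticConfig, simulate_scene, ErrorStatistics,
                  analyze, cross_validate)

cfg = SyntheticConfig(n_lat=30, n_lon=30, n_stations=200, n_hours=24, seed=1)
scene = simulate_scene(cfg)                      # truth, forecast, obs
stats = ErrorStatistics(pollutant="PM2.5", sigma_b2=25.0, lc_km=60.0,
                        sigma_o2_by_land_use={"rural": 8.0})

t = cfg.times()[12]
product = analyze(scene.forecast[t], scene.observations, stats)
truth = scene.truth[t].values
print(np.sqrt(np.mean((scene.forecast[t].values - truth) ** 2)))  # 5.147
print(np.sqrt(np.mean((product.analysis.values - truth) ** 2)))   # 3.075

report = cross_validate(scene.forecast, scene.observations, stats,
                        "PM2.5", fraction=0.75, n_replicates=3, seed=1)
print(report["std_omp"].mean(), report["std_oma"].mean())  # 5.107  3.808
print(int(report["significant_var"].sum()))                # 20 (of 24 hours)
```

The forecast's RMSE against the known truth (5.15 µg/m³) drops to 3.08
after analysis — close to the analytic expectation
`σ_a² = (1/σ_B² + 1/σ_o²)^{-1}`.  At *withheld* stations (never seen by the
analysis), the residual standard deviation falls from 5.11 to 3.81, and the
F-test flags the variance reduction as significant (p < 0.05) for 20 of the
24 hours.  For the index itself:

```python
from aqoi import aqhi_exact, aqhi_linear, categorize
aqhi_exact(20, 40, 20)   # 4.7185  (NO2 ppbv, O3 ppbv, PM2.5 µg/m³)
aqhi_linear(20, 40, 20)  # 4.6769  (linearized, always a slight undershoot)
categorize(4.7185)       # 'Moderate'
```

The same chain is scriptable from the shell:

```
aqoi simulate --out-dir scene/ --seed 1
aqoi fit-stats --obs scene/obs.csv --forecast-dir scene/ --pollutant PM2.5 --out stats.yaml
aqoi analyze --pollutant PM2.5 --forecast scene/forecast_20130701T12.nc \
     --obs scene/obs.csv --stats stats.yaml --out-dir product/
aqoi validate --pollutant PM2.5 --obs scene/obs.csv --forecast-dir scene/ \
     --stats stats.yaml --fraction 0.75 --out report.csv
```

See `docs/methods.md` for the model, assumptions, defaults and known
limitations.

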