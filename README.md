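# aeroplume

Monthly, airport-level PM2.5 from civil-aviation landing–take-off (LTO)
activity: a tested pipeline from national turnover statistics to a
24-hour-average concentration per airport per month, with station-based
validation. It is aimed at exposure and health-impact analysts who need a
reproducible aviation PM2.5 time series for a whole airport network but
only have aggregate transport statistics to start from.

## What it computes

1. **Emissions** — national monthly turnover (ton-km) is apportioned to
   airports by turnover share; fuel burn follows from the unit ton-km
   consumption (kg/ton-km), PM2.5 mass from a pluggable emission intensity
   (default 0.2772 g per kg fuel), and the monthly mass is averaged over
   the month's seconds to the emission flow *E* (g/s).
2. **Dispersion** — a fixed-coefficient Gaussian plume with ground and
   mixing-layer image-source reflections:

       C = E / (2π μ δy δz) · exp(−y²/2δy²) · P
       P = 2 exp(−h²/2δz²) + Σₙ exp(−(nl−h)²/2δz²) + Σₙ exp(−(nl+h)²/2δz²)

   with μ = 3.7 m/s, δy = 1.33, δz = 1, h = 2 m, lid l = 900 m (coastal) or
   1100 m (inland), averaged over receptor offsets y ∈ {1, 2, 3} m.
3. **Validation** — monitoring stations within 50 km are combined by
   inverse-distance weighting and the modeled value is scored by relative
   error; the 16 published station distances around Guangzhou Baiyun (CAN)
   ship as a fixture.
4. **Synthetic scenarios** — a generator with multiplicative seasonality
   (August peak, February trough), compound growth, a pandemic-style shock
   year with partial recovery, Dirichlet hub-dominated airport shares and
   log-normal noise, so every stage is testable without any downloads.

Results are written both as long CSV and in the wide distribution layout
(one row per year × airport, columns Year, Airport, Jan…Dec) in CSV or
XLSX. See `docs/methods.md` for assumptions, parameter rationale and
limitations.

## Worked example

```python
import aeroplume as ap

# plume constants at the default parameters
params = ap.PlumeParams()
ap.vertical_term(params)             # 0.2706705664732254  (P = 2 e^-2; reflections underflow)
ap.average_concentration(1.0, params)  # 0.003370751006248581  (C per unit flow, mean over y=1,2,3)

# the published CAN June-2020 validation pair: stations 2.767, model 2.603 ug/m3
100 * ap.relative_error(2.767, 2.603)  # 5.926996747379823  -> the 5.9% error rate

# a full synthetic run: 20 airports x 2019-2021 with a 2020 shock
result = ap.run_pipeline(config=ap.ScenarioConfig(seed=42))
result.emissions.head(3)
#    year  month airport       fuel_kg         pm25_g  flow_g_per_s
# 0  2019      1     QUL  1.020659e+06  282926.554174      0.105633
# 1  2019      1     GXK  1.196558e+05   33168.587996      0.012384
# 2  2019      1     VQX  1.577821e+06  437372.049419      0.163296
result.validation
# ValidationReport(idw_average=0.00745467..., modeled=0.00703270...,
#                  relative_error=0.0566037..., n_stations=16, power=1.0, radius_km=50.0)
```

The flow column is each airport's month-averaged PM2.5 source strength in
g/s; concentrations are that flow times the plume constant for the
airport's mixing regime. The validation report compares the top airport's
modeled June value against synthetic stations that include a 6 %
non-aviation background — hence the ≈5.7 % relative error.

The same stages are available from the shell:

```sh
aeroplume simulate --out-dir scenario --seed 1
aeroplume emissions --activity scenario/activity.csv \
    --fuel-params scenario/fuel_params.csv --out emissions.csv
aeroplume concentration --emissions emissions.csv \
    --airports scenario/airports.csv --out conc.csv --wide-out conc_wide.csv
aeroplume validate --stations stations.csv --modeled 2.603
aeroplume pipeline --out-dir run --seed 1
```

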