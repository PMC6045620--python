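# pyrocast

Empirical seasonal forecasting of burned area from standardized drought
indicators, on regular latitude–longitude grids.

Many fire-prone regions show a strong, lagged coupling between
precipitation anomalies and the area burned in the following fire season:
antecedent wet spells build fuel, antecedent drought dries it out. This
package models that coupling cell by cell with a deliberately simple,
fully cross-validated linear model, and then turns it into a seasonal
forecast by feeding it bias-corrected precipitation forecasts in place of
the not-yet-observed months.

## The model

For every grid cell with a regular fire season, the standardized seasonal
burned-area anomaly `BA*` is regressed on one standardized precipitation
index (SPI):

```
BA* = β · SPI_t(M − m) + ε
```

where `t ∈ {3, 6, 12}` is the accumulation window in months and the lag
`M − m ∈ {0, …, 5}` offsets the window's final month `m` from the last
month `M` of the fire season — 18 candidate predictors in total. Both
sides are robustly detrended (iteratively reweighted least squares with a
Tukey bisquare weight) and standardized before the slope-only fit, also by
IRLS, so single extreme fire years do not dominate.

Everything is selected and scored by leave-one-out cross-validation over
the available years: for each held-out year, detrending, standardization
and the regression use the remaining years only. A candidate is eligible
when the one-tailed Pearson test of its cross-validated predictions
against the held-out observations gives p < 0.05; among eligible
candidates the one with the highest correlation r wins. Cells whose best
candidate fails the test carry no model.

Variants: SPEI (precipitation minus Thornthwaite potential
evapotranspiration) instead of SPI, a standardized temperature index, or a
two-predictor SPI + temperature model.

To forecast, monthly predictions from a seasonal forecasting system are
bias-corrected by leave-one-out linear scaling (per lead and calendar
month) and merged with observations: months before the issue date are
observed, months after it come from the forecast. Long accumulation
windows at long lags need no forecast at all, which is where much of the
practical skill lives.

## Worked example

Fit the model on a small synthetic grid whose burned area was generated
from a known SPI dependence (β = −0.8 on the 6-month window at lag 1):

```python
from pyrocast import (SyntheticScenario, generate_ba, generate_climate,
                      seasonal_to_monthly)
from pyrocast.firemodel import BurnedAreaModel
from pyrocast.preprocess import SeasonSpec

sc = SyntheticScenario(n_lat=4, n_lon=5, seed=7)
precip, temp = generate_climate(sc)
ba = generate_ba(sc, precip, "JJA")
monthly = seasonal_to_monthly(ba, SeasonSpec("JJA"), precip["time"].dt)

model = BurnedAreaModel(
    ba=monthly, precip=precip.values, season="JJA",
    months=precip["time"].dt.month.values,
    years=precip["time"].dt.year.values,
)
res = model.fit()
print(res.summary())
```

which prints

```
Seasonal burned-area model fit
==============================
season:               JJA
indicator:            spi
season-years:         22 (1996-2017)
grid cells:           20
burnable cells:       20
significant cells:    20 (100.0% of burnable, p < 0.05)
mean r (significant): 0.917
beta < 0:             100.0% of modelled cells
chosen windows t:     {3: 0, 6: 20, 12: 0}
```

`res` also carries per-cell maps (`beta`, `t`, `lag`, `r`, `p_value`,
`significant`) and the cross-validated `predictions`/`observed` series;
`res.to_dataset(lat, lon)` converts them to an xarray Dataset.

The same pipeline is available from the shell:

```
pyrocast simulate --out sim --seed 7
pyrocast fit --ba sim/ba.nc --precip sim/precip.nc --season JJA --out fits.nc
pyrocast verify --fits fits.nc
```

## Forecast-driven prediction

```python
from pyrocast import PseudoForecastSpec, generate_forecast_system
from pyrocast.forecast import bias_correct, fit_with_forecast

spec = PseudoForecastSpec(name="sys", alphas=(0.9, 0.8, 0.7, 0.6, 0.5), seed=1)
arc = generate_forecast_system(spec, precip, temp, "JJA", ba["year"].values)
fc = fit_with_forecast(model, arc)
```

With perfect pseudo-forecasts (`alphas=(1.0,)*5`, no bias) the
forecast-driven skill map is bit-identical to the observation-driven one;
degrading the forecasts degrades skill monotonically. See
`tests/test_acceptance.py` for the end-to-end checks of these properties.

## Layout

- `src/pyrocast/indicators.py` — SPI / SPEI / T index, Thornthwaite PET
- `src/pyrocast/preprocess.py` — remapping, seasonal totals, burnable
  mask, robust detrending
- `src/pyrocast/firemodel.py` — candidate search, LOOCV,
  `BurnedAreaModel` / `BurnedAreaResults`
- `src/pyrocast/forecast.py` — archives, bias correction, obs/forecast
  merging, ensembles
- `src/pyrocast/synthetic.py` — scenario generators with known ground
  truth
- `src/pyrocast/verification.py` — skill summaries, null model,
  bootstrap comparison
- `docs/methods.md` — full description of the method and its numerical
  choices
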