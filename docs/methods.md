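# Methods

This document describes the statistical method implemented by pyrocast,
the conventions it fixes, and the numerical choices behind them.

## 1. Drought indicators

**Accumulation.** For a window of `t` months, the accumulated series is
the rolling sum of the previous `t` monthly values (the first `t − 1`
entries are undefined). SPI uses accumulated precipitation; SPEI uses the
accumulated climatic water balance, precipitation minus potential
evapotranspiration; the T index uses the `t`-month *mean* temperature.

**Empirical standardization (SPI/SPEI).** Within each calendar month, the
accumulated values are ranked (average ranks for ties) and mapped to
probabilities with the Gringorten plotting position
`p_i = (rank_i − 0.44) / (n + 0.12)`, then through the inverse standard
normal CDF. This nonparametric route avoids distributional assumptions
and by construction gives each calendar month's index mean ≈ 0 and
standard deviation ≈ 1 (sd → 1 from below as the sample grows; at
n = 833 the sd is 0.9990). Months with fewer than 8 valid values are
returned as NaN with a warning.

When a value must be standardized *against* a reference sample (the
held-out year of a cross-validation fold, or a forecast-driven
accumulation), its rank is its insertion rank in the sample
(`#less + 0.5·#ties + 0.5`), with `n + 1` in the plotting position — the
value never participates in its own reference distribution.

**T index.** Standardized with the per-calendar-month moment estimates
(mean and ddof-1 standard deviation) instead of ranks, since temperature
is close to Gaussian and a moment z-score keeps the index linear in the
anomaly.

**Potential evapotranspiration.** Thornthwaite (1948): the annual heat
index is `I = Σ (T̄_k / 5)^1.514` over the 12 climatological monthly mean
temperatures (warm months only); monthly PET for `T ≤ 0 °C` is zero, for
moderate temperatures `PET = 16 K (10 T / I)^a` with the standard cubic
polynomial `a(I)`, and above 26.5 °C the Willmott quadratic is used. The
day-length factor `K = (N/12)(days/30)` comes from the sunset hour angle
with solar declination `δ = 0.4093 sin(2πJ/365 − 1.405)` at mid-month day
`J`.

## 2. Preprocessing

**Burned-area remapping** to a coarser grid is conservative summation over
integer-factor blocks (burned area is an extensive quantity). Missing
fine cells count as zero; the fraction of missing contributors is
returned as a diagnostic. Climate fields are remapped with separable
bilinear interpolation (exact for planar fields) or first-order
conservative averaging with cell areas measured in `sin(lat) × lon`.

**Seasonal totals.** A season's burned area is the sum of its member
months; a season-year is labelled by the calendar year of its last month
(DJF belongs to the January/February year). Seasons with missing member
months are NaN.

**Burnable mask.** A cell enters the analysis when its seasonal burned
area is nonzero in a strict majority of seasons (≥ `floor(n/2) + 1`, i.e.
11 of 21): the rank-based machinery and the regression are meaningless on
mostly-zero series.

**Robust detrending.** A straight line `a + b·year` is fit by IRLS with
the Tukey bisquare weight (tuning constant c = 4.685, scale = median
absolute residual / 0.6745, tolerance 1e-8, max 50 iterations) and
removed. Standardization afterwards uses the ddof-1 standard deviation.

## 3. The climate–fire model

Per cell, the candidate predictor set is the cross product of
accumulation windows `t ∈ {3, 6, 12}` and lags `0…5` of the window's end
month relative to the season's last month — 18 candidates, ordered by
(t, lag).

For every candidate and every leave-one-out fold (one season-year held
out):

1. Both the seasonal burned-area series and the accumulated predictor are
   robustly detrended and standardized using the *training years only*;
   the held-out year is transformed with the training-year line, mean and
   sd (the predictor via the insertion-rank standardization above when
   the empirical standardizer is in use).
2. The standardized burned area is regressed on the standardized
   predictor with a slope-only IRLS fit (the model has no intercept: both
   series are centred by construction).
3. The held-out prediction is `β̂ · z_x,held`; the "observation" it is
   scored against is the held-out year's standardized burned area from
   the same fold. With this convention a noiseless linear relationship
   yields r = 1 exactly.

**Selection and significance.** Each candidate's cross-validated
predictions are correlated with the held-out observations; significance
is the one-tailed Pearson test (H₁: r > 0, t-transform with n − 2
degrees of freedom). By default (`p_mode="per_candidate"`) only
individually significant candidates compete and the largest r wins, ties
breaking toward the smallest window then the smallest lag; the
alternative `selected_max` mode takes the overall maximum first and tests
only it. A cell with no qualifying candidate carries no model. Note that
maximizing over 18 correlated candidates inflates the fraction of
pure-noise cells that pass the per-candidate 5% test to roughly 34%
(`verification.NULL_SELECTION_RATE`, measured once at a reference
protocol and frozen as a regression constant); domain-level skill claims
must therefore always be read against this null rate, which is what
`compare_to_null` is for.

**Reported β** is the mean of the per-fold slopes. The two-predictor
variant adds the standardized temperature index of the matching
(t, lag) window as a second column in the same IRLS fit, yielding a
coefficient pair (β, γ).

`BurnedAreaModel.fit()` applies this per-cell procedure over the grid and
returns a `BurnedAreaResults` with per-cell parameter and skill maps plus
the cross-validated prediction series.

## 4. Forecast-driven prediction

A `ForecastArchive` holds one system's monthly re-forecasts at leads
0…L (L ≥ 4), one issue date per season-year placed one month before the
season starts.

**Bias correction** is linear scaling per lead (hence per calendar
month): precipitation is multiplied by the ratio of observed to forecast
mean climatology, temperature is shifted by the mean difference. Both
statistics are computed leaving the target year out, so no year's
correction uses its own observation. Precipitation ratios are capped to
[0.2, 5] (with a warning) against near-zero climatologies.

**Merging.** The accumulated predictor for a held-out season-year is
assembled month by month: calendar months strictly before the issue month
come from observations, months from the issue month onward from the
bias-corrected forecast at the corresponding lead. Accumulation windows
that close before the issue month are purely observational. Training
folds always use observed accumulations; only the held-out year's value
is merged. Consequently, perfect unbiased pseudo-forecasts reproduce the
observation-driven skill maps *bit for bit* — a property the test suite
enforces.

**Ensembles.** `ensemble_mean` averages the (bias-corrected) fields of
several systems; `select_best_systems` ranks systems by the percentage of
burnable area with a significant model and keeps the best k (k = 3 for
the "best ensemble").

## 5. Synthetic ground truth

`SyntheticScenario` generates monthly precipitation as independent
per-cell, per-calendar-month gamma draws (default shape 2, scale 50) and
temperature as a seasonal cycle plus an AR(1) anomaly. Burned area is
`baseline + trend·year + scale · (β_true · SPI_true + σ·noise)`, floored
at zero, optionally zero-inflated, where `SPI_true` is the index of the
planted window (t_true, lag_true). All truth parameters may vary per
cell. Pseudo-forecasts blend the observed standardized anomaly with
independent noise (`α·obs + √(1−α²)·noise`, one α per lead), then apply a
multiplicative precipitation bias and/or additive temperature offset.
Streams are separated with `numpy.random.SeedSequence` spawning so
climate, burned-area noise and each forecast system are independently
reproducible.

Scope: the generator supports *verification of the machinery* (known β,
window, skill ceilings), not realism — cells are spatially independent,
precipitation is serially uncorrelated, and fire behaviour beyond the
linear SPI coupling (ignitions, suppression, land cover) is absent.
Headline numbers from real-data studies are not reproducible from it.

## 6. Verification

`skill_summary` reports cell counts, the percentage of burnable area with
a significant model, and the mean r over significant cells. Errors (MAE,
ME) are in standardized burned-area units. The climatology null model
predicts each year's standardized burned area by the leave-one-out mean
of the others; note the algebraic degeneracy that for a full-period
standardized series this equals `−z_y/(n−1)` — a small but perfectly
anti-correlated signal — so a `mode="full"` fixed-climatology variant
(identically zero) is provided as well. `compare_to_null` bootstraps
season-years (the same resample applied to both forecasts) and flags
cells whose 95% percentile interval of the correlation difference
excludes zero.

## 7. Numerical choices

- **IRLS kernel** (`_irls.py`): hand-vectorized over batches because the
  candidate search needs ~10⁵–10⁶ tiny robust fits; statsmodels' RLM is
  used as an independent cross-check in the tests, not in the hot path.
  Converged rows are frozen so results are independent of batch
  composition (batched ≡ one-at-a-time); exact fits (scale ≈ 0) keep
  their current coefficients; rows that never converge fall back to OLS
  with a warning.
- **Rank standardization** handles ties by average ranks and never lets a
  held-out value rank itself.
- **NetCDF** I/O uses xarray's scipy engine (classic NETCDF3_64BIT), so
  the package runs without compiled NetCDF/HDF5 libraries.
- All stochastic APIs take explicit seeds; no global random state is
  touched.

## 8. Limitations

- The one-tailed 5% gate is per candidate; the 18-candidate maximization
  means per-cell "significance" is a *selection*, not a family-wise
  statement (see the null selection rate above).
- With ~21 years, LOOCV correlations are noisy; β̂ from 20-point slope
  fits carries wide sampling error even when the window is correctly
  identified.
- The leave-one-out climatology null is slightly anti-correlated with the
  verifying observation by construction; comparisons use it as a
  conservative baseline.
- Bias correction is mean scaling only; variance and drift errors of a
  forecast system are not corrected.
- Remapping assumes regular latitude–longitude grids and integer-factor
  nesting for the conservative burned-area sum.
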