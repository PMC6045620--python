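"""Synthetic gridded climate, burned area and pseudo-forecast systems.

The generator produces data with exactly the statistical structure the
empirical climate-fire model assumes, with known per-cell ground truth so
parameter recovery can be tested:

* monthly precipitation is gamma-distributed per cell and calendar month
  (a seasonal cycle enters through the monthly shape/scale parameters);
* monthly temperature is a seasonal cycle plus an AR(1) anomaly;
* the standardized seasonal burned-area anomaly of each cell is
  ``beta_true * SPI_{t_true}(lag_true) + noise``, mapped affinely onto raw
  burned area with an optional linear trend, floored at zero, and
  optionally zero-inflated so the burnable-cell filter has work to do;
* pseudo-forecast systems regress toward the observed anomaly with a
  tunable per-lead correlation ``alpha`` and carry multiplicative
  (precipitation) or additive (temperature) biases for the correction
  step to remove.

The default record length is 21 season-years (plus two spin-up years of
climate so every 12-month/5-lag candidate window is covered), matching the
length of the global burned-area record the method was developed on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

try:
    import xarray as xr
except ImportError:  # pragma: no cover
    xr = None

from .forecast import ForecastArchive
from .indicators import SCALES, compute_spi
from .preprocess import SeasonSpec

__all__ = [
    "SyntheticScenario",
    "PseudoForecastSpec",
    "generate_climate",
    "generate_ba",
    "generate_forecast_system",
    "seasonal_to_monthly",
]

from dataclasses import dataclass, field


def _cellwise(value, shape, name, months=False):
    """Broadcast a scalar / per-month / per-cell parameter to full shape."""
    arr = np.asarray(value, dtype=float)
    target = (12,) + shape if months else shape
    if months and arr.ndim == 1 and arr.shape == (12,):
        arr = arr[:, None, None]
    try:
        return np.broadcast_to(arr, target).copy()
    except ValueError as err:
        raise ValueError(f"{name} cannot broadcast to {target}") from err


@dataclass
class SyntheticScenario:
    """Ground-truth description of one synthetic experiment.

    Per-cell truth parameters (``beta_true`` etc.) may be scalars,
    per-cell maps (n_lat, n_lon), and the climate parameters additionally
    per calendar month (12,) or (12, n_lat, n_lon).
    """

    n_lat: int = 4
    n_lon: int = 5
    n_years: int = 21
    seed: int = 0
    spinup_years: int = 2
    start_year: int = 1995
    # climate
    precip_shape: object = 2.0        # gamma shape k (per calendar month)
    precip_scale: object = 50.0       # gamma scale theta, mm/month
    temp_monthly_mean: object = None  # (12,) deg C; default sinusoidal cycle
    temp_ar1: float = 0.6
    temp_innov_sd: float = 1.5        # deg C
    # burned-area truth
    beta_true: object = -0.8
    t_true: object = 6
    lag_true: object = 1
    noise_sd: object = 0.3
    trend_slope: object = 0.0         # raw BA units per year
    ba_baseline: object = 1000.0      # raw BA units (e.g. ha)
    ba_scale: object = 200.0          # raw BA units per standardized unit
    zero_inflation_prob: object = 0.0

    def __post_init__(self):
        if self.n_years < 8:
            raise ValueError("n_years must be >= 8 for a meaningful cross-validation")
        shape = (self.n_lat, self.n_lon)
        self.precip_shape = _cellwise(self.precip_shape, shape, "precip_shape", months=True)
        self.precip_scale = _cellwise(self.precip_scale, shape, "precip_scale", months=True)
        if np.any(self.precip_shape <= 0) or np.any(self.precip_scale <= 0):
            raise ValueError("gamma shape and scale must be positive")
        if self.temp_monthly_mean is None:
            m = np.arange(12)
            self.temp_monthly_mean = 15.0 + 8.0 * np.sin(2 * np.pi * (m - 3) / 12.0)
        self.temp_monthly_mean = _cellwise(self.temp_monthly_mean, shape, "temp_monthly_mean", months=True)
        for name in ("beta_true", "noise_sd", "trend_slope", "ba_baseline", "ba_scale", "zero_inflation_prob"):
            setattr(self, name, _cellwise(getattr(self, name), shape, name))
        for name in ("t_true", "lag_true"):
            setattr(self, name, _cellwise(getattr(self, name), shape, name).astype(int))
        if not np.all(np.isin(self.t_true, SCALES)):
            raise ValueError(f"t_true must be one of {SCALES}")
        if np.any(self.lag_true < 0) or np.any(self.lag_true > 5):
            raise ValueError("lag_true must lie in 0..5")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be non-negative")
        if np.any((self.zero_inflation_prob < 0) | (self.zero_inflation_prob >= 1)):
            raise ValueError("zero_inflation_prob must lie in [0, 1)")

    @property
    def grid_shape(self):
        return (self.n_lat, self.n_lon)

    @property
    def n_months(self):
        return 12 * (self.n_years + self.spinup_years)

    def time_index(self):
        return pd.date_range(f"{self.start_year}-01-01", periods=self.n_months, freq="MS")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream (0 climate, 1 BA, 2+ forecasts)."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])

    def latitudes(self):
        return np.linspace(-40.0, 40.0, self.n_lat)

    def longitudes(self):
        return np.linspace(0.0, 10.0 * (self.n_lon - 1), self.n_lon)


@dataclass
class PseudoForecastSpec:
    """One pseudo seasonal forecast system.

    ``alphas`` is the correlation of the forecast anomaly with the observed
    anomaly per lead 0..L (non-increasing by convention); biases are applied
    after the skill mixing so the bias-correction step has something real
    to remove.
    """

    name: str = "pseudo-1"
    alphas: tuple = (0.9, 0.8, 0.7, 0.6, 0.5)
    precip_bias: object = 1.0   # multiplicative, scalar or per calendar month (12,)
    temp_offset: object = 0.0   # additive deg C, scalar or per calendar month
    seed: int = 0

    def __post_init__(self):
        a = np.asarray(self.alphas, dtype=float)
        if a.ndim != 1 or a.size < 5:
            raise ValueError("alphas must cover at least leads 0..4")
        if np.any((a < 0) | (a > 1)):
            raise ValueError("alphas must lie in [0, 1]")
        self.alphas = tuple(a)

    @property
    def max_lead(self) -> int:
        return len(self.alphas) - 1


def generate_climate(scenario: SyntheticScenario):
    """Monthly precipitation and temperature fields for the scenario.

    Returns two xarray DataArrays (time, lat, lon): gamma precipitation and
    AR(1) temperature, bit-reproducible for a fixed scenario seed.
    """
    rng = scenario.rng(0)
    times = scenario.time_index()
    mo = times.month.values - 1
    shape_t = scenario.precip_shape[mo]          # (T, nlat, nlon)
    scale_t = scenario.precip_scale[mo]
    precip = rng.gamma(shape_t, scale_t)

    T = scenario.n_months
    anom = np.empty((T,) + scenario.grid_shape)
    innov = rng.normal(0.0, scenario.temp_innov_sd, size=anom.shape)
    rho = scenario.temp_ar1
    # stationary start
    anom[0] = innov[0] / np.sqrt(max(1.0 - rho**2, 1e-12))
    for k in range(1, T):
        anom[k] = rho * anom[k - 1] + innov[k]
    temp = scenario.temp_monthly_mean[mo] + anom

    coords = {
        "time": times,
        "lat": scenario.latitudes(),
        "lon": scenario.longitudes(),
    }
    precip_da = xr.DataArray(precip, dims=("time", "lat", "lon"), coords=coords,
                             name="precip", attrs={"units": "mm/month"})
    temp_da = xr.DataArray(temp, dims=("time", "lat", "lon"), coords=coords,
                           name="temp", attrs={"units": "degC"})
    return precip_da, temp_da


def ba_season_years(scenario: SyntheticScenario, season: SeasonSpec) -> np.ndarray:
    """The season-years the scenario models (spin-up years excluded)."""
    first = scenario.start_year + scenario.spinup_years
    return np.arange(first, first + scenario.n_years)


def generate_ba(scenario: SyntheticScenario, precip, season: SeasonSpec):
    """Seasonal burned-area series generated from the true SPI predictor.

    Per cell, the standardized BA anomaly is ``beta_true * SPI_{t_true}
    (lag_true) + N(0, noise_sd)``; raw BA is ``ba_baseline + trend_slope *
    year_index + ba_scale * anomaly`` floored at zero, and each season-year
    is independently zeroed with probability ``zero_inflation_prob``.

    Returns an xarray DataArray (year, lat, lon) of raw seasonal BA.
    """
    if isinstance(season, str):
        season = SeasonSpec(season)
    rng = scenario.rng(1)
    months = precip["time"].dt.month.values
    years = precip["time"].dt.year.values
    pvals = np.asarray(precip.values, dtype=float)
    season_years = ba_season_years(scenario, season)
    # SPI per scale from the full record, then pick each cell's true window
    spi = {t: compute_spi(pvals, t, months=months) for t in SCALES}
    nY = len(season_years)
    predictor = np.empty((nY,) + scenario.grid_shape)
    for t in SCALES:
        for lag in range(6):
            cells = (scenario.t_true == t) & (scenario.lag_true == lag)
            if not np.any(cells):
                continue
            for k, sy in enumerate(season_years):
                end = int(sy) * 12 + (season.last_month - 1) - lag
                yy, mm = divmod(end, 12)
                hit = np.where((years == yy) & (months == mm + 1))[0]
                if hit.size != 1:
                    raise ValueError(f"precipitation record does not cover {yy}-{mm + 1:02d}")
                predictor[k][cells] = spi[t][hit[0]][cells]
    noise = rng.normal(size=(nY,) + scenario.grid_shape) * scenario.noise_sd
    anom = scenario.beta_true * predictor + noise
    year_idx = np.arange(nY, dtype=float)[:, None, None]
    raw = scenario.ba_baseline + scenario.trend_slope * year_idx + scenario.ba_scale * anom
    raw = np.maximum(raw, 0.0)
    zero = rng.random(size=raw.shape) < scenario.zero_inflation_prob
    raw = np.where(zero, 0.0, raw)
    return xr.DataArray(
        raw,
        dims=("year", "lat", "lon"),
        coords={"year": season_years, "lat": scenario.latitudes(), "lon": scenario.longitudes()},
        name="ba",
        attrs={"units": "ha", "season": season.name},
    )


def seasonal_to_monthly(ba_seasonal, season: SeasonSpec, times) -> np.ndarray:
    """Spread seasonal BA totals evenly over their member months.

    Returns a monthly (T, nlat, nlon) field whose seasonal re-aggregation
    reproduces the input exactly; months outside the season are zero.
    """
    if isinstance(season, str):
        season = SeasonSpec(season)
    months = times.month.values if hasattr(times, "month") else np.asarray([t.month for t in times])
    years = times.year.values if hasattr(times, "year") else np.asarray([t.year for t in times])
    vals = np.asarray(ba_seasonal.values if hasattr(ba_seasonal, "values") else ba_seasonal, float)
    season_years = np.asarray(
        ba_seasonal["year"].values if hasattr(ba_seasonal, "coords") else np.arange(len(vals))
    )
    out = np.zeros((len(months),) + vals.shape[1:])
    label = np.where(
        season.crosses_year() & (months >= season.members[0]), years + 1, years
    )
    member = np.isin(months, season.members)
    # season-years outside the generated record are missing, not zero
    out[member & ~np.isin(label, season_years)] = np.nan
    for k, sy in enumerate(season_years):
        out[member & (label == sy)] = vals[k] / 3.0
    return out


def generate_forecast_system(
    spec: PseudoForecastSpec,
    precip,
    temp,
    season: SeasonSpec,
    season_years: np.ndarray,
) -> ForecastArchive:
    """A pseudo-forecast archive correlated with the observed climate.

    Per lead, the forecast anomaly is ``alpha * observed anomaly +
    sqrt(1 - alpha^2) * climatological-sd * noise`` around the observed
    monthly climatology, after which the system's biases are applied
    (multiplicative for precipitation, additive for temperature) and
    precipitation is floored at zero. With ``alpha = 1`` and neutral biases
    the forecasts reproduce the observations exactly.
    """
    if isinstance(season, str):
        season = SeasonSpec(season)
    rng = np.random.default_rng(spec.seed)
    months = precip["time"].dt.month.values
    years = precip["time"].dt.year.values
    pvals = np.asarray(precip.values, float)
    tvals = np.asarray(temp.values, float)
    issue_month = season.issue_month
    season_years = np.asarray(season_years)
    L = spec.max_lead
    nY = len(season_years)
    grid = pvals.shape[1:]
    fprec = np.empty((nY, L + 1) + grid)
    ftemp = np.empty((nY, L + 1) + grid)
    pbias = np.broadcast_to(np.asarray(spec.precip_bias, float), (12,))
    toff = np.broadcast_to(np.asarray(spec.temp_offset, float), (12,))
    for lead in range(L + 1):
        obs_p, obs_t, cal = [], [], None
        for sy in season_years:
            iy = int(sy) - 1 if issue_month > season.last_month else int(sy)
            total = iy * 12 + (issue_month - 1) + lead
            yy, mm = divmod(total, 12)
            cal = mm  # calendar month index of this lead (same for all years)
            hit = np.where((years == yy) & (months == mm + 1))[0]
            if hit.size != 1:
                raise ValueError(f"observations do not cover {yy}-{mm + 1:02d}")
            obs_p.append(pvals[hit[0]])
            obs_t.append(tvals[hit[0]])
        obs_p = np.stack(obs_p)
        obs_t = np.stack(obs_t)
        a = spec.alphas[lead]
        mix = np.sqrt(max(0.0, 1.0 - a * a))
        for obs, out, bias_mul, bias_add in (
            (obs_p, fprec, pbias[cal], 0.0),
            (obs_t, ftemp, 1.0, toff[cal]),
        ):
            clim = obs.mean(axis=0)
            sd = obs.std(axis=0, ddof=1)
            anom = obs - clim
            noise = rng.normal(size=obs.shape) * sd
            out[:, lead] = (clim + a * anom + mix * noise) * bias_mul + bias_add
    np.maximum(fprec, 0.0, out=fprec)
    return ForecastArchive(
        system=spec.name,
        issue_month=issue_month,
        season_years=season_years,
        precip=fprec,
        temp=ftemp,
    )
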