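"""Seasonal forecast archives: bias correction, merging and ensembles.

A :class:`ForecastArchive` holds one system's monthly re-forecasts, one
issue date per year placed one month before the target season starts, with
monthly fields at leads 0..L (lead 0 is the issue month itself).

Bias correction is simple linear scaling of the ensemble-mean field, lead-
and issue-date dependent: precipitation is multiplied by the ratio of the
observed to the forecast long-term monthly mean and temperature shifted by
the difference of means, each computed leaving the forecast year out so the
corrected value for a year never uses that year's own observation.

Predictor accumulations for a season-year are then built by merging:
months strictly before the issue month come from observations, months from
the issue month onward from the bias-corrected forecast. When the whole
accumulation window closes before the issue month, the predictor is purely
observational and the dynamical forecast is not needed at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .firemodel import BurnedAreaModel, BurnedAreaResults
from .indicators import LAGS, SCALES, accumulate, standardize_against
from .preprocess import SeasonSpec, seasonal_total

__all__ = [
    "ForecastArchive",
    "bias_correct",
    "merge_obs_forecast",
    "merged_accumulations",
    "forecast_indicator",
    "ensemble_mean",
    "select_best_systems",
    "fit_with_forecast",
]

MIN_TRAINING_YEARS = 8
#: bounds on the precipitation scaling ratio against near-zero climatologies
RATIO_CAP = (0.2, 5.0)


@dataclass
class ForecastArchive:
    """Monthly re-forecasts of one system (or an ensemble of systems).

    ``precip``/``temp`` have shape (n_issue_dates, L+1, nlat, nlon); row y
    is the forecast issued in ``issue_month`` of the issue year belonging
    to season-year ``season_years[y]``. After :func:`bias_correct` the
    leave-one-out scaling state is kept in ``precip_factors`` and
    ``temp_offsets`` (same shape).
    """

    system: str
    issue_month: int
    season_years: np.ndarray
    precip: np.ndarray
    temp: np.ndarray
    corrected: bool = False
    precip_factors: np.ndarray | None = None
    temp_offsets: np.ndarray | None = None

    def __post_init__(self):
        self.precip = np.asarray(self.precip, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        if self.precip.shape != self.temp.shape:
            raise ValueError("precip and temp archives must share one shape")
        if self.max_lead < 4:
            raise ValueError("archives must cover at least leads 0..4")
        if np.any(self.precip < 0):
            raise ValueError("precipitation forecasts must be non-negative")

    @property
    def max_lead(self) -> int:
        return self.precip.shape[1] - 1

    def issue_year(self, season_year: int, season: SeasonSpec) -> int:
        """Calendar year the forecast for ``season_year`` was issued in."""
        return season_year - 1 if self.issue_month > season.last_month else season_year


def _lead_obs(obs: np.ndarray, months: np.ndarray, years: np.ndarray,
              archive: ForecastArchive, season: SeasonSpec, lead: int) -> np.ndarray:
    """Observed field for each issue date at the given lead, (nY, ...)."""
    vals = []
    for sy in archive.season_years:
        iy = archive.issue_year(int(sy), season)
        total = iy * 12 + (archive.issue_month - 1) + lead
        yy, mm = divmod(total, 12)
        hit = np.where((years == yy) & (months == mm + 1))[0]
        if hit.size != 1:
            raise ValueError(f"observations do not cover {yy}-{mm + 1:02d}")
        vals.append(obs[hit[0]])
    return np.stack(vals)


def bias_correct(
    archive: ForecastArchive,
    obs_precip: np.ndarray,
    obs_temp: np.ndarray,
    months: np.ndarray,
    years: np.ndarray,
    season: SeasonSpec,
    ratio_cap: tuple[float, float] = RATIO_CAP,
) -> ForecastArchive:
    """Leave-one-out linear-scaling bias correction of an archive.

    For each lead (hence each forecast calendar month) and each year, the
    precipitation scaling factor is the ratio of observed to forecast
    long-term means over the *other* years, capped to ``ratio_cap``; the
    temperature offset is the difference of those means.
    """
    nY = len(archive.season_years)
    if nY - 1 < MIN_TRAINING_YEARS:
        raise ValueError(f"bias correction needs at least {MIN_TRAINING_YEARS + 1} years")
    cp = np.empty_like(archive.precip)
    ct = np.empty_like(archive.temp)
    factors = np.empty_like(archive.precip)
    offsets = np.empty_like(archive.temp)
    capped = 0
    for lead in range(archive.max_lead + 1):
        o_p = _lead_obs(obs_precip, months, years, archive, season, lead)
        o_t = _lead_obs(obs_temp, months, years, archive, season, lead)
        f_p = archive.precip[:, lead]
        f_t = archive.temp[:, lead]
        # leave-one-out means: (sum - row) / (n - 1)
        mop = (o_p.sum(axis=0)[None] - o_p) / (nY - 1)
        mfp = (f_p.sum(axis=0)[None] - f_p) / (nY - 1)
        mot = (o_t.sum(axis=0)[None] - o_t) / (nY - 1)
        mft = (f_t.sum(axis=0)[None] - f_t) / (nY - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = mop / mfp
        bad = ~np.isfinite(ratio)
        ratio = np.where(bad, 1.0, ratio)
        clipped = np.clip(ratio, *ratio_cap)
        capped += int(np.sum((clipped != ratio) | bad))
        cp[:, lead] = f_p * clipped
        ct[:, lead] = f_t + (mot - mft)
        factors[:, lead] = clipped
        offsets[:, lead] = mot - mft
    if capped:
        warnings.warn(
            f"precipitation scaling ratio capped/defaulted in {capped} cells",
            RuntimeWarning,
            stacklevel=2,
        )
    return replace(
        archive, precip=cp, temp=ct, corrected=True,
        precip_factors=factors, temp_offsets=offsets,
    )


def _window_indices(season: SeasonSpec, season_year: int, lag: int, t: int):
    """Absolute (year*12 + month-1) indices of the t-month window ending
    ``lag`` months before the season's last month."""
    end = season_year * 12 + (season.last_month - 1) - lag
    return np.arange(end - t + 1, end + 1)


def merge_obs_forecast(
    obs: np.ndarray,
    months: np.ndarray,
    years: np.ndarray,
    archive: ForecastArchive,
    season: SeasonSpec,
    season_year: int,
    lag: int,
    t: int,
    variable: str = "precip",
) -> np.ndarray:
    """Accumulated predictor value for one season-year, merging sources.

    Months strictly before the issue month are taken from observations;
    the issue month onward comes from the (bias-corrected) forecast at the
    appropriate lead. Raises if the window would need a lead beyond the
    archive's maximum, or observations outside the record.
    """
    iy = archive.issue_year(int(season_year), season)
    issue_abs = iy * 12 + (archive.issue_month - 1)
    row = np.where(archive.season_years == season_year)[0]
    if row.size != 1:
        raise ValueError(f"archive has no issue date for season-year {season_year}")
    fc = archive.precip if variable == "precip" else archive.temp
    total = None
    for a in _window_indices(season, int(season_year), lag, t):
        if a < issue_abs:
            yy, mm = divmod(a, 12)
            hit = np.where((years == yy) & (months == mm + 1))[0]
            if hit.size != 1:
                raise ValueError(f"observations do not cover {yy}-{mm + 1:02d}")
            v = obs[hit[0]]
        else:
            lead = a - issue_abs
            if lead > archive.max_lead:
                raise ValueError(
                    f"window needs lead {lead} but archive stops at {archive.max_lead}"
                )
            v = fc[row[0], lead]
        total = v if total is None else total + v
    return np.asarray(total, dtype=float)


def merged_accumulations(
    obs: np.ndarray,
    months: np.ndarray,
    years: np.ndarray,
    archive: ForecastArchive,
    season: SeasonSpec,
    season_years: np.ndarray,
    variable: str = "precip",
) -> dict[tuple[int, int], np.ndarray]:
    """Merged accumulated predictor values for all 18 candidate windows.

    Maps (t, lag) -> (n_season_years, ...); feed the result to
    :meth:`BurnedAreaModel.fit` as ``heldout_accumulations``. Season-years
    without an issue date in the archive (record spin-up) come out as NaN
    and are excluded from the fit by the finite-pair masking downstream.
    """
    blank = np.full(obs.shape[1:], np.nan)
    out = {}
    for t in SCALES:
        for lag in LAGS:
            vals = [
                merge_obs_forecast(obs, months, years, archive, season, sy, lag, t, variable)
                if sy in archive.season_years else blank
                for sy in season_years
            ]
            out[(t, lag)] = np.stack(vals)
    return out


def forecast_indicator(
    obs: np.ndarray,
    months: np.ndarray,
    years: np.ndarray,
    archive: ForecastArchive,
    spec,
    season: SeasonSpec,
    season_years: np.ndarray,
) -> np.ndarray:
    """Standardized forecast indicator series, one value per season-year.

    Each merged accumulation is ranked within the observed accumulation
    sample for the same calendar window, so residual forecast biases show
    up as index bias rather than being silently absorbed.
    """
    acc = accumulate(np.asarray(obs, float), spec.t)
    obs_sample = []
    for sy in season_years:
        end = int(sy) * 12 + (season.last_month - 1) - spec.lag
        yy, mm = divmod(end, 12)
        hit = np.where((years == yy) & (months == mm + 1))[0]
        if hit.size != 1:
            raise ValueError(f"observations do not cover {yy}-{mm + 1:02d}")
        obs_sample.append(acc[hit[0]])
    obs_sample = np.stack(obs_sample)  # (nY, ...)
    merged = np.stack([
        merge_obs_forecast(obs, months, years, archive, season, sy, spec.lag, spec.t)
        for sy in season_years
    ])
    out = np.empty_like(merged)
    for i in range(len(season_years)):
        out[i] = standardize_against(np.moveaxis(obs_sample, 0, -1), merged[i], axis=-1)
    return out


def ensemble_mean(archives: list[ForecastArchive], name: str = "ENS") -> ForecastArchive:
    """Grand ensemble: the mean of several systems' (corrected) fields."""
    if not archives:
        raise ValueError("need at least one archive")
    first = archives[0]
    for a in archives[1:]:
        if (a.issue_month != first.issue_month or a.precip.shape != first.precip.shape
                or not np.array_equal(a.season_years, first.season_years)):
            raise ValueError("archives are not aligned")
    return ForecastArchive(
        system=name,
        issue_month=first.issue_month,
        season_years=first.season_years,
        precip=np.mean([a.precip for a in archives], axis=0),
        temp=np.mean([a.temp for a in archives], axis=0),
        corrected=all(a.corrected for a in archives),
    )


def select_best_systems(skill: dict[str, float], k: int = 3) -> list[str]:
    """Names of the k systems with the largest skill summary (percentage of
    eligible area with a significant model); ties break alphabetically."""
    ranked = sorted(skill, key=lambda name: (-skill[name], name))
    return ranked[: min(k, len(ranked))]


def fit_with_forecast(
    model: BurnedAreaModel,
    archive: ForecastArchive,
    alpha: float = 0.05,
    **fit_kwargs,
) -> BurnedAreaResults:
    """Fit the climate-fire model with forecast-driven held-out predictors.

    The candidate search and training still use observed accumulations; the
    held-out year of every fold is predicted from the merged observation/
    forecast accumulation, which is how the system would run operationally.
    Only the 'spi' indicator is supported (the model the forecasts feed).
    """
    if model.indicator != "spi":
        raise ValueError("forecast-driven fits are defined for the 'spi' indicator")
    _, season_years = seasonal_total(model.ba, model.months, model.years, model.season)
    merged = merged_accumulations(
        model.precip, model.months, model.years, archive, model.season, season_years
    )
    return model.fit(alpha=alpha, heldout_accumulations=merged, **fit_kwargs)
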