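"""Standardized climate indicators: SPI, SPEI and the temperature index.

The standardized precipitation index (SPI) maps accumulated precipitation
onto a standard Gaussian scale, per calendar month, so that negative values
mean drier-than-usual and positive values wetter-than-usual conditions
relative to the local climatology. The standardization is nonparametric:
ranks are converted to Gringorten plotting positions and passed through the
inverse normal CDF. The SPEI applies the same transform to the monthly water
balance (precipitation minus Thornthwaite potential evapotranspiration), and
the temperature index standardizes multi-month temperature means with
ordinary (moment-based) z-scores.

All functions operate on numpy arrays whose leading axis is time, with a
parallel ``months`` vector of calendar months (1-12); xarray DataArrays with
a ``time`` coordinate are accepted and returned where noted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

try:  # xarray is used only for coordinate plumbing
    import xarray as xr
except ImportError:  # pragma: no cover
    xr = None

__all__ = [
    "IndicatorSpec",
    "accumulate",
    "gringorten_positions",
    "empirical_standardize",
    "standardize_against",
    "compute_spi",
    "compute_pet_thornthwaite",
    "compute_spei",
    "compute_t_index",
]

#: Accumulation windows considered for every indicator, in months.
SCALES = (3, 6, 12)
#: Lags (months back from the last month of the season) searched by the model.
LAGS = (0, 1, 2, 3, 4, 5)

_MONTH_DAYS = np.array([31.0, 28.0, 31.0, 30.0, 31.0, 30.0, 31.0, 31.0, 30.0, 31.0, 30.0, 31.0])
_MID_MONTH_DOY = np.array([15.5, 45.0, 74.5, 105.0, 135.5, 166.0, 196.5, 227.5, 258.0, 288.5, 319.0, 349.5])


@dataclass(frozen=True)
class IndicatorSpec:
    """A candidate predictor: which index, its accumulation window and lag.

    ``lag`` counts months back from the last month of the target season
    (lag 0 is the season's final month, lag 5 five months earlier).
    """

    variable: str  # 'spi' | 'spei' | 't'
    t: int
    lag: int

    def __post_init__(self):
        if self.variable not in ("spi", "spei", "t"):
            raise ValueError(f"unknown indicator variable {self.variable!r}")
        if self.t not in SCALES:
            raise ValueError(f"accumulation window must be one of {SCALES}, got {self.t}")
        if self.lag not in LAGS:
            raise ValueError(f"lag must be in {LAGS}, got {self.lag}")


def _as_array(field):
    """Return (values, months, is_xarray, template) for ndarray or DataArray input."""
    if xr is not None and isinstance(field, xr.DataArray):
        months = field["time"].dt.month.values
        return np.asarray(field.values, dtype=float), months, True, field
    return np.asarray(field, dtype=float), None, False, None


def _wrap(values, is_xr, template, **attrs):
    if is_xr:
        out = template.copy(data=values)
        out.attrs = dict(attrs)
        return out
    return values


def accumulate(series: np.ndarray, t: int) -> np.ndarray:
    """Backward-looking rolling sum over ``t`` months along the time axis.

    Entry ``m`` is the sum over months ``m-t+1 .. m``; the first ``t-1``
    entries (incomplete windows) are NaN, as is any window containing NaN.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if t < 1:
        raise ValueError("accumulation window must be >= 1 month")
    if t > n:
        warnings.warn(
            f"accumulation window {t} exceeds series length {n}; all missing",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full_like(series, np.nan)
    out = np.full_like(series, np.nan)
    c = np.cumsum(series, axis=0)
    out[t - 1] = c[t - 1]
    out[t:] = c[t:] - c[:-t]
    return out


def gringorten_positions(n: int) -> np.ndarray:
    """Plotting positions (i - 0.44) / (n + 0.12) for ranks i = 1..n."""
    i = np.arange(1, n + 1, dtype=float)
    return (i - 0.44) / (n + 0.12)


def empirical_standardize(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Rank-based standardization of one climatological sample.

    Ranks (average ranks for ties) are mapped to Gringorten plotting
    positions p_i = (rank_i - 0.44)/(n + 0.12) and through the standard
    normal quantile function. NaNs are ignored in the ranking and returned
    as NaN. Samples with fewer than 8 valid values come back all-NaN, and an
    all-tied sample comes back all-zero; both emit a warning.
    """
    values = np.asarray(values, dtype=float)
    n_valid = np.sum(np.isfinite(values), axis=axis)
    ranks = stats.rankdata(values, method="average", axis=axis, nan_policy="omit")
    n = np.expand_dims(n_valid, axis)
    with np.errstate(invalid="ignore"):
        out = stats.norm.ppf((ranks - 0.44) / (n + 0.12))
    small = n_valid < 8
    if np.any(small):
        warnings.warn(
            "standardization sample smaller than 8 values; returning missing",
            RuntimeWarning,
            stacklevel=2,
        )
        out = np.where(np.broadcast_to(np.expand_dims(small, axis), out.shape), np.nan, out)
    # an all-tied sample (e.g. a run of zero-precipitation months) gets average
    # ranks, p = 0.5 exactly, hence index 0; just flag it
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        spread = np.nanmax(values, axis=axis) - np.nanmin(values, axis=axis)
    if np.any((spread == 0) & (n_valid >= 8)):
        warnings.warn("all-tied standardization sample; index set to 0", RuntimeWarning, stacklevel=2)
    out[~np.isfinite(values)] = np.nan
    return out


def standardize_against(sample: np.ndarray, value, axis: int = -1):
    """Standardize held-out value(s) by ranking them within ``sample``.

    The value receives the rank it would take if inserted into the sample
    (ties get the midpoint), and the Gringorten position uses the sample
    size, keeping it consistent with :func:`empirical_standardize` on the
    training sample. Used inside cross-validation so the predicted year
    never enters its own climatological ranking sample.
    """
    sample = np.asarray(sample, dtype=float)
    value = np.asarray(value, dtype=float)
    n = np.sum(np.isfinite(sample), axis=axis)
    v = np.expand_dims(value, axis) if np.ndim(value) == sample.ndim - 1 else value
    less = np.sum(sample < v, axis=axis)
    ties = np.sum(sample == v, axis=axis)
    rank = less + 0.5 * ties + 0.5
    p = (rank - 0.44) / (n + 0.12)
    return stats.norm.ppf(p)


def _standardize_by_month(acc: np.ndarray, months: np.ndarray) -> np.ndarray:
    out = np.full_like(acc, np.nan)
    for m in range(1, 13):
        sel = months == m
        if not np.any(sel):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[sel] = empirical_standardize(acc[sel], axis=0)
    return out


def compute_spi(precip, t: int, months: np.ndarray | None = None):
    """Standardized precipitation index at accumulation window ``t``.

    ``precip`` is a monthly field (time first axis, mm/month), either an
    xarray DataArray with a time coordinate or an ndarray plus a ``months``
    vector of calendar months.
    """
    values, m, is_xr, tpl = _as_array(precip)
    if m is None:
        if months is None:
            raise ValueError("months must be given for ndarray input")
        m = np.asarray(months)
    acc = accumulate(values, t)
    out = _standardize_by_month(acc, m)
    return _wrap(out, is_xr, tpl, variable="spi", scale=t)


def _day_length_hours(latitudes: np.ndarray) -> np.ndarray:
    """Mean day length (hours) per calendar month and latitude, shape (12, nlat)."""
    lat = np.deg2rad(np.asarray(latitudes, dtype=float))
    decl = 0.4093 * np.sin(2.0 * np.pi * _MID_MONTH_DOY / 365.0 - 1.405)  # (12,)
    x = -np.tan(lat)[None, :] * np.tan(decl)[:, None]
    omega = np.arccos(np.clip(x, -1.0, 1.0))
    return 24.0 * omega / np.pi


def compute_pet_thornthwaite(temp, latitudes=None, months: np.ndarray | None = None):
    """Monthly potential evapotranspiration (mm/month) after Thornthwaite (1948).

    The heat index I is built from the per-cell climatological monthly mean
    temperatures (months at or below 0 °C contribute nothing), the exponent
    a(I) is the usual cubic, and the unadjusted PET is corrected by day
    length and month length. PET is 0 for monthly temperatures at or below
    0 °C, and the hot branch (T > 26.5 °C) uses the Willmott quadratic.
    """
    values, m, is_xr, tpl = _as_array(temp)
    if m is None:
        if months is None:
            raise ValueError("months must be given for ndarray input")
        m = np.asarray(months)
    if is_xr and latitudes is None:
        latitudes = tpl["lat"].values
    if latitudes is None:
        raise ValueError("latitudes are required")
    latitudes = np.atleast_1d(np.asarray(latitudes, dtype=float))
    if np.any(np.abs(latitudes) > 90.0):
        raise ValueError("latitudes must lie in [-90, 90]")
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    # climatological monthly means -> heat index per cell
    clim = np.stack([values[m == mo].mean(axis=0) for mo in range(1, 13)])  # (12, ...)
    I = np.sum(np.where(clim > 0.0, (np.maximum(clim, 0.0) / 5.0) ** 1.514, 0.0), axis=0)
    a = 6.75e-7 * I**3 - 7.71e-5 * I**2 + 1.7912e-2 * I + 0.49239
    daylen = _day_length_hours(latitudes)  # (12, nlat)
    mo_idx = m - 1
    K = (daylen[mo_idx] / 12.0) * (_MONTH_DAYS[mo_idx][:, None] / 30.0)  # (T, nlat)
    while K.ndim < values.ndim:
        K = K[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        mild = 16.0 * np.power(np.maximum(10.0 * values / np.where(I > 0, I, np.nan), 0.0), a)
    hot = -415.85 + 32.24 * values - 0.43 * values**2
    pet = np.where(values > 26.5, hot, np.where(np.isfinite(mild), mild, 0.0))
    pet = np.where(values <= 0.0, 0.0, pet * K)
    if squeeze:
        pet = pet[:, 0]
    return _wrap(pet, is_xr, tpl, variable="pet", units="mm/month")


def compute_spei(precip, temp, latitudes=None, t: int = 3, months: np.ndarray | None = None):
    """Standardized precipitation-evapotranspiration index at window ``t``."""
    pvals, m, is_xr, tpl = _as_array(precip)
    tvals = temp.values if (xr is not None and isinstance(temp, xr.DataArray)) else np.asarray(temp, float)
    if m is None:
        if months is None:
            raise ValueError("months must be given for ndarray input")
        m = np.asarray(months)
    if is_xr and latitudes is None:
        latitudes = tpl["lat"].values
    pet = compute_pet_thornthwaite(tvals, latitudes, months=m)
    balance = pvals - np.asarray(pet)
    acc = accumulate(balance, t)
    out = _standardize_by_month(acc, m)
    return _wrap(out, is_xr, tpl, variable="spei", scale=t)


def compute_t_index(temp, t: int, months: np.ndarray | None = None):
    """Standardized multi-month temperature index.

    The ``t``-month running mean is standardized per calendar month with
    plain z-scores (anomaly from the long-term mean divided by the
    long-term standard deviation) — moment-based, unlike SPI/SPEI.
    """
    values, m, is_xr, tpl = _as_array(temp)
    if m is None:
        if months is None:
            raise ValueError("months must be given for ndarray input")
        m = np.asarray(months)
    acc = accumulate(values, t) / float(t)
    out = np.full_like(acc, np.nan)
    for mo in range(1, 13):
        sel = m == mo
        if not np.any(sel):
            continue
        grp = acc[sel]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(grp, axis=0)
            sd = np.nanstd(grp, axis=0, ddof=1)
        degenerate = ~(sd > 0)
        if np.any(degenerate & np.any(np.isfinite(grp), axis=0)):
            warnings.warn("zero-variance temperature sample; index undefined", RuntimeWarning, stacklevel=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[sel] = (grp - mean) / np.where(degenerate, np.nan, sd)
    return _wrap(out, is_xr, tpl, variable="t", scale=t)
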