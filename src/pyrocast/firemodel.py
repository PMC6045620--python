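"""The empirical climate-fire model and its cross-validated selection.

The model relates the standardized seasonal burned-area (BA) anomaly of one
grid cell to a single standardized climate indicator,

    BA* = beta * SPI_t(M - m) + eps,

where ``t`` is the accumulation window of the indicator (3, 6 or 12
months), ``m`` the lag of its target month back from the last month ``M``
of the season (0..5), ``beta`` the sensitivity of BA to wet/dry anomalies,
and ``eps`` noise. For every cell the 18 candidate (t, m) pairs are
evaluated with leave-one-out cross-validation: in each fold the trend, the
standardization moments, the indicator's climatological ranking sample and
the regression coefficient are estimated from the training years only, so
no information from the predicted year leaks into its own prediction. The
candidate with the largest positive out-of-sample Pearson correlation among
those significant at the one-tailed 5% level is selected; cells with no
significant candidate are left unmodelled.

A two-predictor variant (indicator plus standardized temperature sharing
the same (t, m)) is also provided.

:class:`BurnedAreaModel` / :class:`BurnedAreaResults` wrap the per-cell
machinery for whole grids in the statsmodels fit()/results idiom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._irls import irls, irls_line, irls_slope
from .indicators import (
    LAGS,
    SCALES,
    IndicatorSpec,
    accumulate,
    compute_pet_thornthwaite,
    empirical_standardize,
    standardize_against,
)
from .preprocess import SeasonSpec, burnable_mask, seasonal_total

try:
    import xarray as xr
except ImportError:  # pragma: no cover
    xr = None

__all__ = [
    "candidate_predictors",
    "candidate_accumulations",
    "loocv_predict",
    "select_best_model",
    "fit_two_predictor",
    "LoocvFit",
    "CellFit",
    "BurnedAreaModel",
    "BurnedAreaResults",
]

MIN_YEARS = 8


def candidate_predictors(variable: str = "spi") -> list[IndicatorSpec]:
    """The 18 candidate predictors: 3 accumulation windows x 6 lags,
    ordered by (t, lag) — the order used to break selection ties."""
    return [IndicatorSpec(variable, t, lag) for t in SCALES for lag in LAGS]


def target_month(season: SeasonSpec, lag: int) -> int:
    """Calendar month of the indicator target, ``lag`` months before M."""
    return (season.last_month - lag - 1) % 12 + 1


# ---------------------------------------------------------------------------
# per-cell LOOCV core

@dataclass
class LoocvFit:
    """Cross-validated single-candidate fit for one cell."""

    predictions: np.ndarray  # (n,) standardized units
    observed: np.ndarray     # (n,) held-out BA in per-fold standardized units
    betas: np.ndarray        # (n,) per-fold coefficients
    r: float
    p_value: float
    gammas: np.ndarray | None = None

    @property
    def beta(self) -> float:
        """Average coefficient across the out-of-sample fits."""
        return float(np.nanmean(self.betas))

    @property
    def gamma(self) -> float | None:
        return None if self.gammas is None else float(np.nanmean(self.gammas))


@dataclass
class CellFit:
    """Best significant model of one cell (or None if no candidate passed)."""

    spec: IndicatorSpec
    fit: LoocvFit

    @property
    def beta(self):
        return self.fit.beta

    @property
    def r(self):
        return self.fit.r

    @property
    def p_value(self):
        return self.fit.p_value


def _fold_indices(n: int) -> np.ndarray:
    """Training-year index matrix, row j = all years except j; (n, n-1)."""
    idx = np.arange(n)
    return np.stack([np.delete(idx, j) for j in range(n)])


def _fold_standardize(Ytr: np.ndarray, held: np.ndarray, Xtr: np.ndarray, xheld: np.ndarray):
    """Detrend (robust) and z-standardize per fold, training years only.

    Ytr (B, k) training values, held (B,) held-out raw values, Xtr (B, k)
    training abscissae (year indices), xheld (B,) held-out year index.
    Returns (z_train (B, k), z_held (B,), ok (B,)).
    """
    ok = np.isfinite(Ytr).all(axis=1) & np.isfinite(held)
    Ysafe = np.where(ok[:, None], Ytr, 0.0)
    a, b, _ = irls_line(Xtr, Ysafe, warn=False)
    resid = Ysafe - (a[:, None] + b[:, None] * Xtr)
    m = resid.mean(axis=1)
    s = resid.std(axis=1, ddof=1)
    ok &= s > 0
    s = np.where(s > 0, s, np.nan)
    z_tr = (resid - m[:, None]) / s[:, None]
    z_held = (held - (a + b * xheld) - m) / s
    return z_tr, z_held, ok


def _pearson_p(pred: np.ndarray, obs: np.ndarray):
    """Pearson r and one-tailed p (H1: r > 0) over finite pairs, row-wise."""
    pred = np.atleast_2d(pred)
    obs = np.broadcast_to(obs, pred.shape)
    ok = np.isfinite(pred) & np.isfinite(obs)
    n = ok.sum(axis=1)
    p_ = np.where(ok, pred, 0.0)
    o_ = np.where(ok, obs, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mp = p_.sum(1) / n
        mo = o_.sum(1) / n
        cov = (p_ * o_).sum(1) / n - mp * mo
        vp = (p_**2).sum(1) / n - mp**2
        vo = (o_**2).sum(1) / n - mo**2
        r = cov / np.sqrt(vp * vo)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    tstat = np.where(r >= 1.0, np.inf, np.where(r <= -1.0, -np.inf, tstat))
    pval = stats.t.sf(tstat, np.maximum(n - 2, 1))
    bad = n < MIN_YEARS
    r = np.where(bad, np.nan, r)
    pval = np.where(bad, np.nan, pval)
    return r, pval


def _loocv_batch(
    y: np.ndarray,
    X: np.ndarray,
    X_held: np.ndarray | None = None,
    standardizer: str = "empirical",
    X2: np.ndarray | None = None,
):
    """LOOCV predictions for one cell and a batch of candidate predictors.

    y : (n,) raw seasonal BA; X : (C, n) raw candidate series; X_held :
    optional (C, n) per-year held-out predictor values (e.g. merged
    observation/forecast accumulations) — training always uses ``X``.
    X2 : optional (C, n) second predictor (temperature), used linearly.

    Returns (pred (C, n), obs (n,), betas (C, n), gammas (C, n) | None).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = X.shape[0]
    if X_held is None:
        X_held = X
    else:
        X_held = np.atleast_2d(np.asarray(X_held, dtype=float))
    T = _fold_indices(n)
    yrs = np.arange(n, dtype=float)
    Xtr_years = yrs[T]                         # (n, k)
    held_years = yrs

    zy_tr, zy_held, y_ok = _fold_standardize(y[T], y, Xtr_years, held_years)

    Atr = X[:, T]                              # (C, n, k)
    Aheld = X_held[:, np.arange(n)]            # (C, n)
    if standardizer == "empirical":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            Str = stats.norm.ppf(
                (stats.rankdata(Atr, method="average", axis=-1, nan_policy="omit") - 0.44)
                / (np.sum(np.isfinite(Atr), axis=-1, keepdims=True) + 0.12)
            )
            Sheld = standardize_against(Atr, Aheld, axis=-1)
    elif standardizer == "linear":
        Str, Sheld = Atr, Aheld
    else:
        raise ValueError(f"unknown standardizer {standardizer!r}")

    k = n - 1
    flatS = Str.reshape(C * n, k)
    flat_held = Sheld.reshape(C * n)
    flat_years = np.broadcast_to(Xtr_years, (C, n, k)).reshape(C * n, k)
    zx_tr, zx_held, x_ok = _fold_standardize(flatS, flat_held, flat_years, np.tile(held_years, C))

    fold_ok = x_ok & np.tile(y_ok, C)
    zx_tr = np.where(fold_ok[:, None] & np.isfinite(zx_tr), zx_tr, 0.0)
    ZY = np.broadcast_to(zy_tr, (C, n, k)).reshape(C * n, k)
    ZY = np.where(fold_ok[:, None] & np.isfinite(ZY), ZY, 0.0)

    gammas = None
    if X2 is None:
        betas, _ = irls_slope(zx_tr, ZY, warn=False)
        pred = betas * zx_held
        betas = betas.reshape(C, n)
        pred = pred.reshape(C, n)
    else:
        X2 = np.atleast_2d(np.asarray(X2, dtype=float))
        Btr = X2[:, T].reshape(C * n, k)
        Bheld = X2[:, np.arange(n)].reshape(C * n)
        z2_tr, z2_held, ok2 = _fold_standardize(Btr, Bheld, flat_years, np.tile(held_years, C))
        fold_ok &= ok2
        z2_tr = np.where(fold_ok[:, None] & np.isfinite(z2_tr), z2_tr, 0.0)
        design = np.stack([zx_tr, z2_tr], axis=-1)   # (C*n, k, 2)
        coef, _ = irls(design, ZY, warn=False)
        betas, gam = coef[:, 0], coef[:, 1]
        pred = betas * zx_held + gam * z2_held
        betas = betas.reshape(C, n)
        gammas = np.where(fold_ok, gam, np.nan).reshape(C, n)
        pred = pred.reshape(C, n)

    fold_ok = fold_ok.reshape(C, n)
    pred = np.where(fold_ok, pred, np.nan)
    betas = np.where(fold_ok, betas, np.nan)
    obs = np.where(y_ok, zy_held, np.nan)
    return pred, obs, betas, gammas


def loocv_predict(
    ba: np.ndarray,
    predictor: np.ndarray,
    standardizer: str = "linear",
    predictor_heldout: np.ndarray | None = None,
) -> LoocvFit:
    """Leave-one-out cross-validated fit of one cell against one predictor.

    ``ba`` and ``predictor`` are per-season-year series (raw units; every
    fold detrends and standardizes them on its training years). With
    ``standardizer='empirical'`` the predictor is an accumulated raw value
    and is rank-standardized within each fold's training sample first.
    ``predictor_heldout`` optionally supplies the held-out-year predictor
    from another source (merged observation/forecast values).

    Requires at least 8 paired non-missing years.
    """
    ba = np.asarray(ba, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    ok = np.isfinite(ba) & np.isfinite(predictor)
    if predictor_heldout is not None:
        ok &= np.isfinite(predictor_heldout)
    if ok.sum() < MIN_YEARS:
        raise ValueError(f"need at least {MIN_YEARS} paired years, got {int(ok.sum())}")
    idx = np.where(ok)[0]
    held = None if predictor_heldout is None else np.asarray(predictor_heldout, float)[idx][None, :]
    pred, obs, betas, _ = _loocv_batch(ba[idx], predictor[idx][None, :], held, standardizer)
    r, p = _pearson_p(pred, obs)
    full = np.full(ba.shape, np.nan)
    out = LoocvFit(full.copy(), full.copy(), full.copy(), float(r[0]), float(p[0]))
    out.predictions[idx] = pred[0]
    out.observed[idx] = obs
    out.betas[idx] = betas[0]
    return out


def select_best_model(
    ba: np.ndarray,
    predictors: dict[IndicatorSpec, np.ndarray] | list,
    standardizer: str = "empirical",
    alpha: float = 0.05,
    heldout: dict[IndicatorSpec, np.ndarray] | None = None,
    p_mode: str = "per_candidate",
    temp_predictors: dict[IndicatorSpec, np.ndarray] | None = None,
) -> CellFit | None:
    """Pick the best significant candidate model for one cell.

    Every candidate is cross-validated; with ``p_mode='per_candidate'``
    (the default) only candidates individually significant at ``alpha``
    compete and the one with maximal r wins; ``p_mode='selected_max'``
    instead takes the overall maximum r and then applies the significance
    test to it. Ties in r break toward the smallest accumulation window,
    then the smallest lag (the candidate ordering). Returns None when no
    candidate qualifies.
    """
    if isinstance(predictors, dict):
        specs = sorted(predictors, key=lambda s: (s.t, s.lag))
        X = np.stack([predictors[s] for s in specs])
        Xh = None if heldout is None else np.stack([heldout[s] for s in specs])
        if temp_predictors is None:
            X2 = None
        else:
            by_window = {(s.t, s.lag): v for s, v in temp_predictors.items()}
            X2 = np.stack([by_window[(s.t, s.lag)] for s in specs])
    else:
        specs = [s for s, _ in predictors]
        X = np.stack([v for _, v in predictors])
        Xh, X2 = None, None
    ba = np.asarray(ba, dtype=float)
    ok = np.isfinite(ba) & np.isfinite(X).all(axis=0)
    if Xh is not None:
        ok &= np.isfinite(Xh).all(axis=0)
    if ok.sum() < MIN_YEARS:
        return None
    idx = np.where(ok)[0]
    pred, obs, betas, gammas = _loocv_batch(
        ba[idx], X[:, idx], None if Xh is None else Xh[:, idx], standardizer,
        None if X2 is None else X2[:, idx],
    )
    r, p = _pearson_p(pred, obs)
    if p_mode == "per_candidate":
        eligible = p < alpha
    elif p_mode == "selected_max":
        eligible = np.zeros_like(p, dtype=bool)
        if np.any(np.isfinite(r)):
            j = int(np.nanargmax(r))
            eligible[j] = p[j] < alpha
    else:
        raise ValueError(f"unknown p_mode {p_mode!r}")
    if not np.any(eligible):
        return None
    score = np.where(eligible, r, -np.inf)
    best = int(np.argmax(score))
    n_all = ba.size
    full = np.full(n_all, np.nan)
    fit = LoocvFit(full.copy(), full.copy(), full.copy(), float(r[best]), float(p[best]),
                   gammas=None if gammas is None else full.copy())
    fit.predictions[idx] = pred[best]
    fit.observed[idx] = obs
    fit.betas[idx] = betas[best]
    if gammas is not None:
        fit.gammas[idx] = gammas[best]
    return CellFit(specs[best], fit)


def fit_two_predictor(
    ba: np.ndarray,
    predictors: dict[IndicatorSpec, np.ndarray],
    temp_predictors: dict[IndicatorSpec, np.ndarray],
    **kwargs,
) -> CellFit | None:
    """Best two-predictor (indicator + temperature) model for one cell.

    Both predictors share one (t, lag); the search and significance rules
    match :func:`select_best_model`. A collinear pair degrades gracefully
    (pseudo-inverse solution) rather than erroring.
    """
    return select_best_model(ba, predictors, temp_predictors=temp_predictors, **kwargs)


# ---------------------------------------------------------------------------
# grid-level assembly

def candidate_accumulations(
    monthly: np.ndarray,
    months: np.ndarray,
    years: np.ndarray,
    season: SeasonSpec,
    season_years: np.ndarray,
    mean: bool = False,
) -> dict[tuple[int, int], np.ndarray]:
    """Raw accumulated values of every candidate window for each season-year.

    ``monthly`` is a (T, ...) field; the result maps (t, lag) to an array
    (n_season_years, ...) of window sums (or means) ending at the target
    month of each season-year. Season-years whose window reaches before the
    start of the record come back NaN.
    """
    monthly = np.asarray(monthly, dtype=float)
    months = np.asarray(months)
    years = np.asarray(years)
    out = {}
    # absolute index of M for each season-year
    m_abs = {}
    for sy in season_years:
        hit = np.where((months == season.last_month) & (years == sy))[0]
        if hit.size != 1:
            raise ValueError(f"season-year {sy} not uniquely covered by the record")
        m_abs[sy] = int(hit[0])
    for t in SCALES:
        acc = accumulate(monthly, t)
        if mean:
            acc = acc / float(t)
        for lag in LAGS:
            vals = []
            for sy in season_years:
                j = m_abs[sy] - lag
                vals.append(acc[j] if j >= 0 else np.full(monthly.shape[1:], np.nan))
            out[(t, lag)] = np.stack(vals)
    return out


@dataclass
class BurnedAreaModel:
    """Empirical seasonal climate-fire model for a gridded record.

    Parameters
    ----------
    ba : ndarray (T, nlat, nlon)
        Monthly burned area on the analysis grid (area units).
    precip : ndarray (T, nlat, nlon)
        Monthly precipitation (mm/month) on the same grid and calendar.
    season : SeasonSpec or str
        Target season ('DJF', 'MAM', 'JJA', 'SON').
    months, years : ndarray (T,)
        Calendar months (1-12) and years of the shared time axis.
    temp : ndarray (T, nlat, nlon), optional
        Monthly 2 m temperature (deg C), required for the 'spei', 't' and
        'spi+t' indicator choices.
    latitudes : ndarray (nlat,), optional
        Needed for the Thornthwaite PET inside 'spei'.
    indicator : str
        'spi' (default), 'spei', 't', or 'spi+t'.
    """

    ba: np.ndarray
    precip: np.ndarray
    season: SeasonSpec | str
    months: np.ndarray
    years: np.ndarray
    temp: np.ndarray | None = None
    latitudes: np.ndarray | None = None
    indicator: str = "spi"

    def __post_init__(self):
        if isinstance(self.season, str):
            self.season = SeasonSpec(self.season)
        if self.indicator not in ("spi", "spei", "t", "spi+t"):
            raise ValueError(f"unknown indicator {self.indicator!r}")
        if self.indicator != "spi" and self.temp is None:
            raise ValueError(f"indicator {self.indicator!r} requires temperature")
        self.ba = np.asarray(self.ba, dtype=float)
        self.precip = np.asarray(self.precip, dtype=float)

    @classmethod
    def from_datasets(cls, ba, precip, season, temp=None, **kwargs):
        """Build from xarray DataArrays sharing a monthly ``time`` coordinate."""
        months = ba["time"].dt.month.values
        years = ba["time"].dt.year.values
        lats = ba["lat"].values if "lat" in ba.coords else None
        return cls(
            ba=ba.values, precip=precip.values, season=season, months=months,
            years=years, temp=None if temp is None else temp.values,
            latitudes=lats, **kwargs,
        )

    def _predictor_fields(self):
        """Monthly field(s) the candidate windows accumulate over."""
        if self.indicator == "spi":
            return self.precip, None, "empirical", False
        if self.indicator == "spei":
            pet = compute_pet_thornthwaite(self.temp, self.latitudes, months=self.months)
            return self.precip - pet, None, "empirical", False
        if self.indicator == "t":
            return np.asarray(self.temp, float), None, "linear", True
        # 'spi+t'
        return self.precip, np.asarray(self.temp, float), "empirical", False

    def fit(
        self,
        alpha: float = 0.05,
        heldout_accumulations: dict | None = None,
        p_mode: str = "per_candidate",
        min_coverage_years: int = MIN_YEARS,
    ) -> "BurnedAreaResults":
        """Aggregate BA to seasons, apply the burnable filter and run the
        cross-validated candidate search in every eligible cell.

        ``heldout_accumulations`` optionally replaces each held-out year's
        predictor accumulation with values merged from a forecast archive
        (mapping (t, lag) -> (n_years, nlat, nlon)); training always uses
        the observed accumulations.
        """
        season = self.season
        ba_seasonal, season_years = seasonal_total(self.ba, self.months, self.years, season)
        field1, field2, standardizer, use_mean = self._predictor_fields()
        acc = candidate_accumulations(field1, self.months, self.years, season, season_years, mean=use_mean)
        acc2 = None
        if field2 is not None:
            acc2 = candidate_accumulations(field2, self.months, self.years, season, season_years, mean=True)
        # drop season-years without full candidate coverage (record spin-up)
        cov = np.ones(len(season_years), dtype=bool)
        for v in acc.values():
            cov &= np.isfinite(v).any(axis=tuple(range(1, v.ndim))) | ~np.isfinite(v).any(axis=tuple(range(1, v.ndim)))
        full_years = np.array([
            i for i in range(len(season_years))
            if all(np.isfinite(v[i]).all() for v in acc.values())
        ])
        if full_years.size < min_coverage_years:
            raise ValueError("too few season-years with full predictor coverage")
        season_years = season_years[full_years]
        ba_seasonal = ba_seasonal[full_years]
        variable = {"spi": "spi", "spei": "spei", "t": "t", "spi+t": "spi"}[self.indicator]
        specs = {
            IndicatorSpec(variable, t, lag): acc[(t, lag)][full_years]
            for (t, lag) in acc
        }
        specs2 = None
        if acc2 is not None:
            specs2 = {
                IndicatorSpec("t", t, lag): acc2[(t, lag)][full_years]
                for (t, lag) in acc2
            }
        heldout = None
        if heldout_accumulations is not None:
            heldout = {
                IndicatorSpec(variable, t, lag): np.asarray(heldout_accumulations[(t, lag)], float)[full_years]
                for (t, lag) in acc
            }

        eligible = burnable_mask(ba_seasonal)
        nlat, nlon = eligible.shape
        n = len(season_years)
        shape = (nlat, nlon)
        res = BurnedAreaResults(
            model=self,
            season_years=season_years,
            eligible=eligible,
            beta=np.full(shape, np.nan),
            gamma=np.full(shape, np.nan),
            t=np.full(shape, np.nan),
            lag=np.full(shape, np.nan),
            r=np.full(shape, np.nan),
            p_value=np.full(shape, np.nan),
            significant=np.zeros(shape, dtype=bool),
            predictions=np.full((n,) + shape, np.nan),
            observed=np.full((n,) + shape, np.nan),
            alpha=alpha,
        )
        for i, j in zip(*np.nonzero(eligible)):
            cell = select_best_model(
                ba_seasonal[:, i, j],
                {s: v[:, i, j] for s, v in specs.items()},
                standardizer=standardizer,
                alpha=alpha,
                heldout=None if heldout is None else {s: v[:, i, j] for s, v in heldout.items()},
                p_mode=p_mode,
                temp_predictors=None if specs2 is None else {s: v[:, i, j] for s, v in specs2.items()},
            )
            if cell is None:
                continue
            res.beta[i, j] = cell.beta
            if cell.fit.gamma is not None:
                res.gamma[i, j] = cell.fit.gamma
            res.t[i, j] = cell.spec.t
            res.lag[i, j] = cell.spec.lag
            res.r[i, j] = cell.r
            res.p_value[i, j] = cell.p_value
            res.significant[i, j] = True
            res.predictions[:, i, j] = cell.fit.predictions
            res.observed[:, i, j] = cell.fit.observed
        return res


@dataclass
class BurnedAreaResults:
    """Fitted parameter and skill maps of a :class:`BurnedAreaModel`.

    ``beta``/``gamma`` are the average out-of-sample coefficients, ``t`` and
    ``lag`` the selected candidate, ``r``/``p_value`` the cross-validated
    correlation and its one-tailed significance; ``predictions`` and
    ``observed`` are per-season-year standardized values. Cells failing the
    burnable filter are NaN and excluded from ``eligible``.
    """

    model: BurnedAreaModel
    season_years: np.ndarray
    eligible: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    t: np.ndarray
    lag: np.ndarray
    r: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    predictions: np.ndarray
    observed: np.ndarray
    alpha: float

    @property
    def pct_significant(self) -> float:
        """Percentage of eligible (burnable) cells with a significant model."""
        n_el = int(self.eligible.sum())
        if n_el == 0:
            return float("nan")
        return 100.0 * float(self.significant.sum()) / n_el

    @property
    def mean_r(self) -> float:
        """Mean cross-validated correlation over significant cells."""
        vals = self.r[self.significant]
        return float(np.mean(vals)) if vals.size else float("nan")

    def to_dataset(self, latitudes=None, longitudes=None):
        """Parameter/skill maps as an xarray Dataset (beta, t, lag, r, ...)."""
        if xr is None:  # pragma: no cover
            raise ImportError("xarray is required for to_dataset")
        nlat, nlon = self.eligible.shape
        coords = {
            "lat": ("lat", np.asarray(latitudes) if latitudes is not None else np.arange(nlat)),
            "lon": ("lon", np.asarray(longitudes) if longitudes is not None else np.arange(nlon)),
        }
        data = {
            name: (("lat", "lon"), getattr(self, name))
            for name in ("beta", "gamma", "t", "lag", "r", "p_value")
        }
        data["significant"] = (("lat", "lon"), self.significant.astype("i1"))
        data["eligible"] = (("lat", "lon"), self.eligible.astype("i1"))
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["season"] = self.model.season.name
        ds.attrs["indicator"] = self.model.indicator
        return ds

    def summary(self) -> str:
        """Human-readable fit summary."""
        season = self.model.season.name
        n_el = int(self.eligible.sum())
        lines = [
            "Seasonal burned-area model fit",
            "==============================",
            f"season:               {season}",
            f"indicator:            {self.model.indicator}",
            f"season-years:         {len(self.season_years)} "
            f"({self.season_years[0]}-{self.season_years[-1]})",
            f"grid cells:           {self.eligible.size}",
            f"burnable cells:       {n_el}",
            f"significant cells:    {int(self.significant.sum())} "
            f"({self.pct_significant:.1f}% of burnable, p < {self.alpha})",
            f"mean r (significant): {self.mean_r:.3f}",
        ]
        if np.any(self.significant):
            frac_neg = float(np.mean(self.beta[self.significant] < 0))
            lines.append(f"beta < 0:             {100 * frac_neg:.1f}% of modelled cells")
            counts = {
                int(t): int(np.sum(self.t[self.significant] == t)) for t in SCALES
            }
            lines.append(f"chosen windows t:     {counts}")
        return "\n".join(lines)
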