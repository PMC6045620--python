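"""Grid harmonisation and seasonal aggregation.

Burned area arrives on a fine grid and is aggregated by block summation
onto the coarse analysis grid (total area burned is conserved exactly);
temperature is bilinearly interpolated and precipitation conservatively
remapped. Seasonal totals, the burnable-cell filter (non-zero seasonal BA
in more than half of the record) and the robust detrending/standardisation
used throughout the pipeline also live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._irls import irls_line

__all__ = [
    "SeasonSpec",
    "remap_ba_sum",
    "remap_bilinear",
    "remap_conservative",
    "seasonal_total",
    "burnable_mask",
    "robust_detrend",
    "standardize",
]

_SEASON_MONTHS = {
    "DJF": (12, 1, 2),
    "MAM": (3, 4, 5),
    "JJA": (6, 7, 8),
    "SON": (9, 10, 11),
}


@dataclass(frozen=True)
class SeasonSpec:
    """A standard three-month climatological season.

    DJF is labelled by the calendar year of its January/February, i.e. the
    December is borrowed from the previous year.
    """

    name: str
    members: tuple[int, int, int] = field(init=False)

    def __post_init__(self):
        if self.name not in _SEASON_MONTHS:
            raise ValueError(f"season must be one of {sorted(_SEASON_MONTHS)}, got {self.name!r}")
        object.__setattr__(self, "members", _SEASON_MONTHS[self.name])

    @property
    def last_month(self) -> int:
        """M, the final calendar month of the season (Feb/May/Aug/Nov)."""
        return self.members[2]

    @property
    def issue_month(self) -> int:
        """Calendar month one month before the season starts (1-month lead)."""
        return (self.members[0] - 2) % 12 + 1

    def crosses_year(self) -> bool:
        return self.members[0] > self.members[2]


def remap_ba_sum(fine: np.ndarray, factor: int) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate a fine burned-area field onto a coarser grid by block sums.

    ``fine`` has shape (..., nlat, nlon) with both trailing dims divisible
    by ``factor`` (fine cells must nest exactly into coarse cells). Missing
    fine cells are treated as zero in the sum; the per-coarse-cell fraction
    of missing fine cells is returned as a diagnostic.
    """
    fine = np.asarray(fine, dtype=float)
    nlat, nlon = fine.shape[-2:]
    if factor < 1 or nlat % factor or nlon % factor:
        raise ValueError(
            f"fine grid {nlat}x{nlon} does not nest into blocks of {factor}"
        )
    blocks = fine.reshape(fine.shape[:-2] + (nlat // factor, factor, nlon // factor, factor))
    missing = ~np.isfinite(blocks)
    coarse = np.where(missing, 0.0, blocks).sum(axis=(-3, -1))
    missing_frac = missing.mean(axis=(-3, -1))
    return coarse, missing_frac


def _linear_weights(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """1-D linear interpolation indices/weights, clamped at the boundary."""
    idx = np.searchsorted(src, dst) - 1
    idx = np.clip(idx, 0, len(src) - 2)
    w = (dst - src[idx]) / (src[idx + 1] - src[idx])
    w = np.clip(w, 0.0, 1.0)
    return idx, idx + 1, w


def remap_bilinear(field: np.ndarray, src_lats, src_lons, dst_lats, dst_lons) -> np.ndarray:
    """Bilinear interpolation between regular lat-lon grids (exact on planes)."""
    field = np.asarray(field, dtype=float)
    src_lats = np.asarray(src_lats, float)
    src_lons = np.asarray(src_lons, float)
    i0, i1, wa = _linear_weights(src_lats, np.asarray(dst_lats, float))
    j0, j1, wb = _linear_weights(src_lons, np.asarray(dst_lons, float))
    a = field[..., i0, :] * (1 - wa)[:, None] + field[..., i1, :] * wa[:, None]
    return a[..., j0] * (1 - wb) + a[..., j1] * wb


def _cell_edges(centers: np.ndarray) -> np.ndarray:
    centers = np.asarray(centers, dtype=float)
    step = np.diff(centers)
    if len(step) and not np.allclose(step, step[0]):
        raise ValueError("grid is not regular")
    h = step[0] / 2 if len(step) else 0.5
    return np.concatenate([[centers[0] - h], centers + h])


def _overlap_matrix(src_edges: np.ndarray, dst_edges: np.ndarray) -> np.ndarray:
    """Pairwise 1-D interval overlaps, shape (ndst, nsrc)."""
    lo = np.maximum(dst_edges[:-1, None], src_edges[None, :-1])
    hi = np.minimum(dst_edges[1:, None], src_edges[None, 1:])
    return np.maximum(hi - lo, 0.0)


def remap_conservative(field: np.ndarray, src_lats, src_lons, dst_lats, dst_lons) -> np.ndarray:
    """First-order conservative remapping between regular lat-lon grids.

    Each destination cell is the overlap-area-weighted mean of the source
    cells it intersects; areas use the sin(latitude) measure, so the
    area-weighted global mean is conserved when the domains coincide.
    """
    field = np.asarray(field, dtype=float)
    wlat = _overlap_matrix(
        np.sin(np.deg2rad(np.clip(_cell_edges(np.asarray(src_lats, float)), -90, 90))),
        np.sin(np.deg2rad(np.clip(_cell_edges(np.asarray(dst_lats, float)), -90, 90))),
    )
    wlon = _overlap_matrix(_cell_edges(np.asarray(src_lons, float)), _cell_edges(np.asarray(dst_lons, float)))
    num = np.einsum("...ij,ai,bj->...ab", field, wlat, wlon)
    den = np.outer(wlat.sum(axis=1), wlon.sum(axis=1))
    if np.any(den <= 0):
        raise ValueError("destination cell does not overlap the source grid")
    return num / den


def seasonal_total(
    ba: np.ndarray, months: np.ndarray, years: np.ndarray, season: SeasonSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Sum the three member months of each season-year.

    Returns (totals, season_years) where totals has shape (n_season_years,
    ...). A season-year with any member month absent or missing is NaN (or
    dropped at the record edges).
    """
    ba = np.asarray(ba, dtype=float)
    months = np.asarray(months)
    years = np.asarray(years)
    # season-year label: DJF's December counts toward the following year
    label = np.where(
        season.crosses_year() & (months >= season.members[0]), years + 1, years
    )
    in_season = np.isin(months, season.members)
    labels = np.unique(label[in_season])
    out, keep = [], []
    for y in labels:
        sel = in_season & (label == y)
        if np.count_nonzero(sel) != 3:
            continue
        keep.append(y)
        out.append(ba[sel].sum(axis=0) + np.where(np.isfinite(ba[sel]).all(axis=0), 0.0, np.nan))
    if not out:
        return np.empty((0,) + ba.shape[1:]), np.empty(0, dtype=int)
    return np.stack(out), np.asarray(keep)


def burnable_mask(ba_seasonal: np.ndarray) -> np.ndarray:
    """Cells eligible for modelling: seasonal BA > 0 in more than half of
    the available seasons (>= floor(n/2) + 1, i.e. 11 of 21)."""
    ba = np.asarray(ba_seasonal, dtype=float)
    n = np.sum(np.isfinite(ba), axis=0)
    nonzero = np.sum(np.nan_to_num(ba) > 0, axis=0)
    return nonzero >= (n // 2 + 1)


def robust_detrend(series: np.ndarray, x: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Remove a robust (IRLS, bisquare) linear trend from yearly series.

    ``series`` is (n,) or (B, n) with the fit done per row against ``x``
    (defaults to 0..n-1). Returns (residuals, slopes). Rows with fewer than
    5 finite points come back all-NaN.
    """
    arr = np.atleast_2d(np.asarray(series, dtype=float))
    B, n = arr.shape
    if x is None:
        x = np.arange(n, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(arr)
    resid = np.full_like(arr, np.nan)
    slopes = np.full(B, np.nan)
    full = ok.all(axis=1)
    if np.any(full):
        a, b, _ = irls_line(x, arr[full])
        resid[full] = arr[full] - (a[:, None] + b[:, None] * x)
        slopes[full] = b
    for i in np.where(~full)[0]:
        m = ok[i]
        if m.sum() < 5:
            continue
        a, b, _ = irls_line(x[m], arr[i, m][None, :])
        resid[i, m] = arr[i, m] - (a[0] + b[0] * x[m])
        slopes[i] = b[0]
    if np.ndim(series) == 1:
        return resid[0], slopes[0]
    return resid, slopes


def standardize(series: np.ndarray, axis: int = -1) -> np.ndarray:
    """z-scores: subtract the mean and divide by the (ddof=1) standard
    deviation along ``axis``; constant series come back NaN with a warning."""
    arr = np.asarray(series, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=axis, keepdims=True)
        sd = np.nanstd(arr, axis=axis, ddof=1, keepdims=True)
    if np.any(~(sd > 0) & np.any(np.isfinite(arr), axis=axis, keepdims=True)):
        warnings.warn("constant series cannot be standardized", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (arr - mean) / np.where(sd > 0, sd, np.nan)
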