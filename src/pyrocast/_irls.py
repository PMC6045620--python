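"""Batched iteratively reweighted least squares with Tukey bisquare weights.

The candidate search runs a robust line fit inside every leave-one-out fold
of every cell and every candidate predictor, i.e. O(10^5-10^6) tiny fits per
grid. This module solves many small weighted least-squares problems at once:
each row of ``Y`` is an independent response vector sharing the row's design
matrix, and the IRLS iteration is carried out for all rows simultaneously.

The tuning constant defaults to 4.685 (95% Gaussian efficiency), the scale
estimate is the median absolute residual rescaled by 1/0.6745, and rows that
fail to converge fall back to their ordinary least-squares solution with a
warning.
"""

from __future__ import annotations

import warnings

import numpy as np

BISQUARE_C = 4.685
#: MAD-to-sigma consistency factor for the Gaussian distribution.
MAD_SCALE = 0.6745

__all__ = ["irls", "irls_line", "irls_slope", "bisquare_weights"]


def bisquare_weights(resid: np.ndarray, scale: np.ndarray, c: float = BISQUARE_C) -> np.ndarray:
    """Tukey bisquare weights w(u) = (1 - u^2)^2 for |u| < 1, else 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        u = resid / (c * scale[..., None])
    u = np.where(np.isfinite(u), u, 0.0)
    w = np.square(1.0 - np.square(u))
    w[np.abs(u) >= 1.0] = 0.0
    return w


def _wls(X: np.ndarray, Y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Solve the weighted normal equations for each row.

    X : (B, n, p), Y : (B, n), W : (B, n) -> coefficients (B, p).
    Singular systems are solved with the pseudo-inverse.
    """
    XtW = X.transpose(0, 2, 1) * W[:, None, :]          # (B, p, n)
    A = XtW @ X                                          # (B, p, p)
    b = (XtW @ Y[..., None])[..., 0]                     # (B, p)
    p = X.shape[2]
    if p == 1:
        a = A[:, 0, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(a > 0, b[:, 0] / np.where(a > 0, a, 1.0), 0.0)
        return beta[:, None]
    det = np.linalg.det(A)
    bad = ~(np.abs(det) > np.finfo(float).tiny)
    if np.any(bad):
        A = A.copy()
        A[bad] = np.eye(p)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    if np.any(bad):
        beta[bad] = (np.linalg.pinv(XtW[bad] @ X[bad]) @ b[bad][..., None])[..., 0]
    return beta


def irls(
    X: np.ndarray,
    Y: np.ndarray,
    c: float = BISQUARE_C,
    tol: float = 1e-8,
    maxiter: int = 50,
    warn: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Robust linear regression of each row of ``Y`` on the design ``X``.

    Parameters
    ----------
    X : ndarray, shape (B, n, p) or (n, p)
        Design matrices (broadcast over rows when 2-D).
    Y : ndarray, shape (B, n)
        Response vectors.

    Returns
    -------
    coef : ndarray, shape (B, p)
    converged : ndarray of bool, shape (B,)
        Rows that did not converge carry their OLS solution.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    B, n = Y.shape
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = np.broadcast_to(X, (B,) + X.shape)
    ones = np.ones((B, n))
    coef = _wls(X, Y, ones)
    ols_coef = coef.copy()
    converged = np.zeros(B, dtype=bool)
    for _ in range(maxiter):
        resid = Y - (X @ coef[..., None])[..., 0]
        scale = np.median(np.abs(resid), axis=1) / MAD_SCALE
        # a (near-)perfect fit on the retained points: keep it as-is
        exact = scale <= 1e-12 * np.maximum(np.max(np.abs(Y), axis=1), 1.0)
        W = bisquare_weights(resid, np.where(exact, 1.0, scale), c)
        # guard against all-zero weight rows (every point flagged an outlier)
        dead = W.sum(axis=1) <= 0
        W[dead] = 1.0
        new = _wls(X, Y, W)
        # freeze finished rows so every row's result is independent of the
        # rest of the batch (batched and one-at-a-time runs agree exactly)
        new = np.where((exact | converged)[:, None], coef, new)
        step = np.max(np.abs(new - coef), axis=1)
        coef = new
        converged |= exact | (step < tol)
        if converged.all():
            break
    if not converged.all():
        coef = coef.copy()
        coef[~converged] = ols_coef[~converged]
        if warn:
            warnings.warn(
                f"IRLS did not converge for {np.count_nonzero(~converged)} of {B} "
                "fits; ordinary least squares used for those.",
                RuntimeWarning,
                stacklevel=2,
            )
    return coef, converged


def irls_line(
    x: np.ndarray, Y: np.ndarray, **kwargs
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Robust straight-line fits y = a + b*x for each row of ``Y``.

    ``x`` may be one shared abscissa (n,) or one per row (B, n).
    Returns (intercepts, slopes, converged).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    B, n = Y.shape
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = np.broadcast_to(x, (B, n))
    X = np.stack([np.ones_like(x), x], axis=-1)
    coef, conv = irls(X, Y, **kwargs)
    return coef[:, 0], coef[:, 1], conv


def irls_slope(x: np.ndarray, Y: np.ndarray, **kwargs) -> tuple[np.ndarray, np.ndarray]:
    """Robust through-origin fits y = b*x for each row of ``Y``."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    B, n = Y.shape
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = np.broadcast_to(x, (B, n))
    coef, conv = irls(x[..., None], Y, **kwargs)
    return coef[:, 0], conv
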