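"""Polynomial least-squares machinery shared by the ordering and fishing steps.

For a candidate order of n cells the regression abscissa is the rank
position mapped to n equally spaced points in [0, 1]; the design matrix
therefore depends only on (n, degree), never on the order itself. We cache
an orthonormal basis Q of the polynomial column space per (n, degree): the
residual sum of squares of a response y is ||y||^2 - ||Q^T y||^2, so
evaluating the ordering objective for many candidate orders costs one thin
matrix product each.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["poly_basis", "mse_matrix", "polyfit_order", "linear_slope"]


@lru_cache(maxsize=256)
def poly_basis(n: int, degree: int) -> np.ndarray:
    """Orthonormal basis (n x (degree+1)) of polynomials of given degree
    evaluated at n equally spaced points in [0, 1]."""
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if n < degree + 2:
        raise ValueError(f"need at least degree+2={degree + 2} points, got {n}")
    x = np.linspace(0.0, 1.0, n)
    V = np.vander(x, degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    return Q


def mse_matrix(Y: np.ndarray, degree: int) -> np.ndarray:
    """Per-column polynomial-regression MSE of an (n x G) response matrix.

    Column g holds gene g's (rescaled) expression listed in candidate-order
    position; returns the G mean squared residuals of the degree-d fits.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    Q = poly_basis(n, degree)
    proj = Q.T @ Y
    rss = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", proj, proj)
    # rounding can leave a tiny negative residual on an exact fit
    return np.maximum(rss, 0.0) / n


def polyfit_order(y: np.ndarray, degree: int) -> tuple[np.ndarray, float]:
    """Degree-d least-squares fit of y against equally spaced [0,1] positions.

    Returns (coefficients in increasing power order, MSE).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < degree + 2:
        raise ValueError(f"need at least degree+2={degree + 2} points, got {n}")
    x = np.linspace(0.0, 1.0, n)
    V = np.vander(x, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, y, rcond=None)
    resid = y - V @ coef
    return coef, float(resid @ resid / n)


def linear_slope(y: np.ndarray) -> float:
    """Slope of the degree-1 fit of y against equally spaced [0,1] positions."""
    coef, _ = polyfit_order(np.asarray(y, dtype=float), 1)
    return float(coef[1])
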