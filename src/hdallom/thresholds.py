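"""Smoothed error-vs-sample-size trends and turning-point detection.

The mean height RMSE of a locally fitted model declines with training
sample size, with diminishing returns.  To locate the sample size
beyond which extra height measurements buy little, the mean-RMSE
series is smoothed with a low-rank penalised cubic regression spline
(basis dimension 4, smoothing parameter by generalised
cross-validation), evaluated on a unit-spaced grid, and the discrete
second derivative

    d2(n) = (I[n+2] - 2*I[n] + I[n-2]) / 4

is computed at interior grid points.  For a decreasing convex trend a
peak in the second derivative marks the slowdown in improvement: the
turning point.  The turning point is sensitive to the degree of
smoothing, so the full second-derivative series is returned for
inspection alongside the argmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class TrendCurve:
    """A smoothed trend I(n) evaluated on a unit-spaced integer grid."""

    n_grid: np.ndarray
    values: np.ndarray
    basis_dim: int = 4

    def __post_init__(self) -> None:
        self.n_grid = np.asarray(self.n_grid)
        self.values = np.asarray(self.values, float)
        if self.n_grid.size != self.values.size:
            raise ValueError("n_grid and values must have equal length")
        if np.any(np.diff(self.n_grid) <= 0):
            raise ValueError("n_grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trend values must be finite")


@dataclass
class TurningPoint:
    """Sample size of maximal second derivative, with the full series."""

    n_star: int
    series_n: np.ndarray
    second_derivative_series: np.ndarray


def _cr_basis(x: np.ndarray, knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic regression spline basis and curvature penalty.

    Returns the design matrix mapping function values at the knots to
    f(x), and the penalty matrix S with gamma' S gamma = integral of
    f''(t)^2.  The basis contains all linear functions with zero
    penalty, so linear data are reproduced exactly at any smoothing
    level.
    """
    k = len(knots)
    h = np.diff(knots)
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    F = np.zeros((k, k))
    F[1:-1, :] = np.linalg.solve(B, D)  # second derivatives at knots
    S = D.T @ np.linalg.solve(B, D)
    x = np.asarray(x, float)
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    X = np.zeros((x.size, k))
    for r in range(x.size):
        ji, hj = j[r], h[j[r]]
        dl = x[r] - knots[j[r]]
        dr = knots[j[r] + 1] - x[r]
        row = np.zeros(k)
        row[ji] += dr / hj
        row[ji + 1] += dl / hj
        cm = dr**3 / (6.0 * hj) - hj * dr / 6.0
        cp = dl**3 / (6.0 * hj) - hj * dl / 6.0
        row += cm * F[ji] + cp * F[ji + 1]
        X[r] = row
    return X, S


_LAMBDA_GRID = np.concatenate(([0.0], np.logspace(-4.0, 8.0, 61)))


def smooth_curve(n, y, basis_dim: int = 4) -> TrendCurve:
    """Fit a penalised cubic regression spline to mean error vs n.

    Knots sit at evenly spaced quantiles of the distinct n values
    (``basis_dim`` of them); the curvature penalty weight is chosen by
    generalised cross-validation over a wide grid.  The fitted trend
    is returned on the unit-spaced integer grid spanning the data, the
    grid on which the discrete second derivative is defined.
    """
    n = np.asarray(n, float)
    y = np.asarray(y, float)
    if np.unique(n).size < basis_dim:
        raise ValueError(f"need >= {basis_dim} distinct sample sizes")
    knots = np.quantile(np.unique(n), np.linspace(0.0, 1.0, basis_dim))
    X, S = _cr_basis(n, knots)
    best_gcv, best_beta = np.inf, None
    npts = n.size
    for lam in _LAMBDA_GRID:
        A = X.T @ X + lam * S
        try:
            beta = np.linalg.solve(A, X.T @ y)
            edf = float(np.trace(np.linalg.solve(A, X.T @ X)))
        except np.linalg.LinAlgError:
            continue
        if npts - edf < 1e-8:
            continue
        rss = float(np.sum((y - X @ beta) ** 2))
        gcv = npts * rss / (npts - edf) ** 2
        if gcv < best_gcv:
            best_gcv, best_beta = gcv, beta
    if best_beta is None:
        raise RuntimeError("spline fit failed at every smoothing level")
    grid = np.arange(int(np.ceil(n.min())), int(np.floor(n.max())) + 1)
    Xg, _ = _cr_basis(grid, knots)
    return TrendCurve(n_grid=grid, values=Xg @ best_beta, basis_dim=basis_dim)


def second_derivative(curve: TrendCurve, n: int) -> float:
    """Discrete second derivative (I[n+2] - 2*I[n] + I[n-2]) / 4.

    ``n`` must lie at least two grid steps from each edge.  The
    differencing assumes the unit-spaced grid that
    :func:`smooth_curve` produces; central differences of this form
    are exact for polynomials up to cubic.
    """
    grid = curve.n_grid
    pos = {}
    for offset in (-2, 0, 2):
        where = np.flatnonzero(grid == n + offset)
        if where.size == 0:
            raise ValueError(f"grid point {n + offset} not in trend curve")
        pos[offset] = where[0]
    I = curve.values
    return float((I[pos[2]] - 2.0 * I[pos[0]] + I[pos[-2]]) / 4.0)


def find_threshold(curve: TrendCurve, tol: float = 1e-10) -> TurningPoint:
    """Turning point: the interior grid point of maximal second derivative.

    Ties break toward the smallest n.  If the curve has no measurable
    curvature anywhere (all second derivatives ~0, e.g. a linear
    trend) a warning is raised and the smallest interior n returned.
    """
    grid = curve.n_grid
    if grid.size < 5:
        raise ValueError("need at least 5 grid points to locate a turning point")
    interior = grid[2:-2]
    series = np.array([second_derivative(curve, int(v)) for v in interior])
    if np.max(np.abs(series)) < tol:
        warnings.warn("trend curve has no curvature; turning point is arbitrary", stacklevel=2)
        n_star = int(interior[0])
    else:
        n_star = int(interior[int(np.argmax(series))])
    return TurningPoint(n_star=n_star, series_n=interior, second_derivative_series=series)
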