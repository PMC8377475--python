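"""Penalized B-spline smoothing with derivative confidence bands.

The numeric core shared by boundary detection and phenology: a P-spline
(cubic B-spline basis, difference penalty, GCV-selected smoothing parameter)
with a Bayesian coefficient covariance for pointwise confidence bands on the
fitted derivative, plus a monotone-increasing variant obtained by
constraining successive coefficient differences to be nonnegative.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from scipy.interpolate import BSpline
from scipy.optimize import lsq_linear

__all__ = [
    "SmoothFit",
    "DerivativeBand",
    "ConstantRun",
    "fit_pspline",
    "fit_monotone_pspline",
    "derivative_band",
    "find_constant_runs",
]

_DEGREE = 3  # cubic basis throughout

# Relative floor on the residual SD used for band construction: with exactly
# noise-free input sigma^2 collapses to spline approximation error and band
# membership of zero becomes numerically unstable; the floor (3e-4 of the
# response range) is far below any realistic measurement noise.
_SIGMA_FLOOR_REL = 3e-4


def _knot_vector(x_min: float, x_max: float, basis_dim: int, degree: int = _DEGREE) -> np.ndarray:
    if basis_dim < degree + 1:
        raise ValueError(f"basis_dim must be >= {degree + 1}, got {basis_dim}")
    n_interior = basis_dim - degree - 1
    interior = np.linspace(x_min, x_max, n_interior + 2)[1:-1]
    return np.concatenate([np.repeat(x_min, degree + 1), interior, np.repeat(x_max, degree + 1)])


def _design_matrix(x: np.ndarray, knots: np.ndarray, degree: int = _DEGREE) -> np.ndarray:
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def _difference_matrix(basis_dim: int, order: int) -> np.ndarray:
    """Plain order-th difference penalty rows (Eilers–Marx P-spline).

    The null space holds coefficient polynomials of degree < order; with
    clamped knots the induced function null space is exact for order 1
    (constants, by partition of unity) and exact away from the boundary
    columns for higher orders.
    """
    return np.diff(np.eye(basis_dim), n=order, axis=0)


def _deriv_design_matrix(x: np.ndarray, knots: np.ndarray, basis_dim: int,
                         degree: int = _DEGREE) -> np.ndarray:
    """Matrix C with C @ coef = d/dx of the fitted spline at x."""
    cols = np.empty((x.size, basis_dim))
    for j in range(basis_dim):
        e = np.zeros(basis_dim)
        e[j] = 1.0
        cols[:, j] = BSpline(knots, e, degree, extrapolate=False).derivative()(x)
    return cols


@dataclass
class SmoothFit:
    """A fitted penalized spline with coefficient uncertainty.

    Gaussian response, identity link. ``cov`` is the Bayesian posterior
    covariance sigma^2 (B'B + lam*P)^-1 used for pointwise bands.
    Predictions are defined only on the training domain [x_min, x_max].
    """

    knots: np.ndarray
    degree: int
    coef: np.ndarray
    cov: np.ndarray
    lam: float
    x_min: float
    x_max: float
    edf: float
    sigma2: float
    penalty_order: int
    monotone: bool = False
    n_obs: int = 0

    def __post_init__(self) -> None:
        asym = np.max(np.abs(self.cov - self.cov.T))
        scale = max(np.max(np.abs(self.cov)), 1e-300)
        if asym > 1e-8 * scale:
            raise ValueError("coefficient covariance must be symmetric")

    @property
    def basis_dim(self) -> int:
        return self.coef.size

    def _check_domain(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        pad = 1e-9 * (self.x_max - self.x_min + 1.0)
        if np.any(x < self.x_min - pad) or np.any(x > self.x_max + pad):
            raise ValueError(
                f"prediction grid outside training domain [{self.x_min}, {self.x_max}]"
            )
        return np.clip(x, self.x_min, self.x_max)

    def predict(self, x) -> np.ndarray:
        x = self._check_domain(x)
        return _design_matrix(x, self.knots, self.degree) @ self.coef

    def derivative(self, x) -> np.ndarray:
        x = self._check_domain(x)
        return _deriv_design_matrix(x, self.knots, self.basis_dim, self.degree) @ self.coef

    def residual_sd(self) -> float:
        return float(np.sqrt(self.sigma2))

    def to_json(self) -> str:
        """Serialize the fit (provenance record)."""
        d = dataclasses.asdict(self)
        for k in ("knots", "coef", "cov"):
            d[k] = np.asarray(d[k]).tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "SmoothFit":
        d = json.loads(s)
        for k in ("knots", "coef", "cov"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


@dataclass
class DerivativeBand:
    """Pointwise confidence band for the derivative of a SmoothFit."""

    grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (np.all(self.lower <= self.estimate + 1e-12)
                and np.all(self.estimate <= self.upper + 1e-12)):
            raise ValueError("band must satisfy lower <= estimate <= upper")

    def contains_zero(self) -> np.ndarray:
        return (self.lower <= 0.0) & (self.upper >= 0.0)


@dataclass
class ConstantRun:
    """A maximal stretch of grid points whose derivative CI contains 0."""

    start: float
    end: float
    length: int
    indices: tuple = field(repr=False, default=())

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("run start must be <= end")


def _solve_penalized(BtB, Bty, P, lam):
    A = BtB + lam * P
    try:
        c, low = linalg.cho_factor(A)
    except linalg.LinAlgError as exc:
        raise ValueError(f"rank-deficient penalized system (lambda={lam:g}): {exc}") from exc
    coef = linalg.cho_solve((c, low), Bty)
    Ainv = linalg.cho_solve((c, low), np.eye(A.shape[0]))
    return coef, Ainv


def _gcv_lambda(B, y, P, lam_grid=None):
    """Generalized cross-validation over a log-spaced lambda grid."""
    n = y.size
    BtB = B.T @ B
    Bty = B.T @ y
    # scale-free grid: lambda relative to tr(B'B)/tr(P)
    tr_ratio = np.trace(BtB) / max(np.trace(P), 1e-300)
    if lam_grid is None:
        lam_grid = tr_ratio * np.logspace(-10, 6, 49)
    best = None
    for lam in lam_grid:
        try:
            coef, Ainv = _solve_penalized(BtB, Bty, P, lam)
        except ValueError:
            continue
        edf = float(np.trace(Ainv @ BtB))
        if n - edf < 1.0:
            continue
        rss = float(np.sum((y - B @ coef) ** 2))
        gcv = n * rss / (n - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef, Ainv, edf, rss)
    if best is None:
        raise ValueError("rank deficiency: no lambda on the grid yields a solvable fit")
    return best[1:]


def _prepare(x, y, basis_dim, penalty_order):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 5:
        raise ValueError(f"need at least 5 points to fit a penalized spline, got {x.size}")
    if basis_dim is None:
        basis_dim = int(min(20, max(_DEGREE + 2, x.size // 2)))
    if basis_dim < 5:
        raise ValueError(f"basis_dim must be >= 5, got {basis_dim}")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if x[0] == x[-1]:
        raise ValueError("predictor has zero range")
    knots = _knot_vector(x[0], x[-1], basis_dim)
    B = _design_matrix(x, knots)
    D = _difference_matrix(basis_dim, penalty_order)
    P = D.T @ D
    return x, y, knots, B, D, P, basis_dim


def fit_pspline(x, y, basis_dim: int | None = None, penalty_order: int = 2,
                lam: float | None = None) -> SmoothFit:
    """Fit a penalized cubic B-spline by GCV-selected ridge least squares.

    Parameters
    ----------
    x, y : array-like
        Predictor and Gaussian response.
    basis_dim : int, optional
        Number of basis functions; default min(20, n/2).
    penalty_order : int
        Order of the coefficient difference penalty (default 2: linear
        functions are unpenalized).
    lam : float, optional
        Fix the smoothing parameter instead of selecting it by GCV.
    """
    x, y, knots, B, _D, P, basis_dim = _prepare(x, y, basis_dim, penalty_order)
    n = x.size
    if lam is None:
        lam, coef, Ainv, edf, rss = _gcv_lambda(B, y, P)
    else:
        BtB, Bty = B.T @ B, B.T @ y
        coef, Ainv = _solve_penalized(BtB, Bty, P, lam)
        edf = float(np.trace(Ainv @ BtB))
        rss = float(np.sum((y - B @ coef) ** 2))
    sigma2 = rss / max(n - edf, 1.0)
    sigma2 = max(sigma2, _sigma2_floor(y))
    cov = sigma2 * Ainv
    cov = 0.5 * (cov + cov.T)
    return SmoothFit(knots=knots, degree=_DEGREE, coef=coef, cov=cov, lam=float(lam),
                     x_min=float(x[0]), x_max=float(x[-1]), edf=edf, sigma2=sigma2,
                     penalty_order=penalty_order, n_obs=n)


def _sigma2_floor(y: np.ndarray) -> float:
    # absolute term keeps exactly-constant responses (ptp = 0) well-posed
    return float((_SIGMA_FLOOR_REL * np.ptp(y) + 1e-9 * (np.max(np.abs(y)) + 1.0)) ** 2)


# Dense-grid monotonicity check tolerance, relative to the response range.
_MONO_TOL_REL = 1e-8


def fit_monotone_pspline(x, y, basis_dim: int | None = None, penalty_order: int = 2,
                         lam: float | None = None) -> SmoothFit:
    """Fit a nondecreasing penalized spline (SCAM-style monotone P-spline).

    Monotonicity is enforced by requiring nonnegative successive coefficient
    differences, solved as a bounded least-squares problem on the increment
    parametrization. The smoothing parameter comes from GCV on the
    unconstrained problem; the reported covariance is the unconstrained
    expression (an approximation, documented).
    """
    x, y, knots, B, D, P, basis_dim = _prepare(x, y, basis_dim, penalty_order)
    n = x.size
    BtB, Bty = B.T @ B, B.T @ y
    if lam is None:
        lam = _gcv_lambda(B, y, P)[0]
    # beta = L theta with L lower-triangular ones: theta_0 free, theta_{j>0} >= 0
    m = basis_dim
    L = np.tril(np.ones((m, m)))
    A = np.vstack([B @ L, np.sqrt(lam) * (D @ L)])
    b = np.concatenate([y, np.zeros(D.shape[0])])
    lb = np.full(m, 0.0)
    ub = np.full(m, np.inf)
    lb[0] = -np.inf
    res = lsq_linear(A, b, bounds=(lb, ub), method="bvls", tol=1e-12)
    if not res.success and res.status <= 0:
        raise ValueError(f"monotone fit failed: {res.message}")
    coef = L @ res.x
    _, Ainv = _solve_penalized(BtB, Bty, P, lam)
    edf = float(np.trace(Ainv @ BtB))
    rss = float(np.sum((y - B @ coef) ** 2))
    sigma2 = rss / max(n - edf, 1.0)
    sigma2 = max(sigma2, _sigma2_floor(y))
    cov = sigma2 * Ainv
    cov = 0.5 * (cov + cov.T)
    fit = SmoothFit(knots=knots, degree=_DEGREE, coef=coef, cov=cov, lam=float(lam),
                    x_min=float(x[0]), x_max=float(x[-1]), edf=edf, sigma2=sigma2,
                    penalty_order=penalty_order, monotone=True, n_obs=n)
    dense = np.linspace(fit.x_min, fit.x_max, 512)
    pred = fit.predict(dense)
    tol = _MONO_TOL_REL * (np.ptp(y) + 1e-300)
    if np.min(np.diff(pred)) < -tol:
        raise AssertionError("monotone fit violates nondecrease on the dense grid")
    return fit


def derivative_band(fit: SmoothFit, grid, level: float = 0.95,
                    method: str = "analytic", n_sim: int = 2000,
                    seed: int | None = None) -> DerivativeBand:
    """Pointwise confidence band for the fitted derivative.

    ``method="analytic"`` propagates the coefficient covariance through the
    derivative design matrix (delta method); ``method="simulation"`` draws
    coefficient vectors from N(coef, cov) and takes pointwise quantiles.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    grid = fit._check_domain(grid)
    if grid.size == 0:
        raise ValueError("empty grid")
    C = _deriv_design_matrix(grid, fit.knots, fit.basis_dim, fit.degree)
    est = C @ fit.coef
    if method == "analytic":
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, fit.cov, C), 0.0))
        z = stats.norm.ppf(0.5 + level / 2.0)
        lower, upper = est - z * se, est + z * se
    elif method == "simulation":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(fit.coef, fit.cov, size=n_sim,
                                        method="svd") @ C.T
        alpha = (1.0 - level) / 2.0
        lower = np.quantile(draws, alpha, axis=0)
        upper = np.quantile(draws, 1.0 - alpha, axis=0)
        lower, upper = np.minimum(lower, est), np.maximum(upper, est)
    else:
        raise ValueError(f"unknown band method {method!r}")
    return DerivativeBand(grid=grid, estimate=est, lower=lower, upper=upper, level=level)


def find_constant_runs(band: DerivativeBand, min_run_length: int = 1) -> list[ConstantRun]:
    """Maximal contiguous grid stretches whose derivative CI contains 0.

    Runs shorter than ``min_run_length`` grid points are discarded; the
    result is ordered by start position. An empty list is a valid outcome.
    """
    inside = band.contains_zero()
    if inside.size == 0:
        raise ValueError("empty band")
    runs: list[ConstantRun] = []
    i = 0
    n = inside.size
    while i < n:
        if inside[i]:
            j = i
            while j + 1 < n and inside[j + 1]:
                j += 1
            if j - i + 1 >= min_run_length:
                runs.append(ConstantRun(start=float(band.grid[i]), end=float(band.grid[j]),
                                        length=j - i + 1, indices=(i, j)))
            i = j + 1
        else:
            i += 1
    return runs
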