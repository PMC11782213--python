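"""Penalized cubic regression splines with GCV smoothing selection.

The model is y = B(x) beta + eps with B a cubic B-spline basis whose
interior knots sit at empirical quantiles of x, penalized by the exact
integrated-squared-second-derivative matrix P (computed by Gaussian
quadrature, which is exact because the integrand is piecewise
quadratic).  The fit minimizes ||y - B beta||^2 + lambda beta' P beta;
lambda is either supplied or chosen by generalized cross-validation
over a logarithmic grid.  Constant and linear functions span the
penalty nullspace, so the effective degrees of freedom run from 2
(lambda -> inf, a straight line) up to the basis dimension k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

_DEGREE = 3  # cubic


@dataclass(frozen=True)
class PredictionResult:
    mean: np.ndarray
    se: np.ndarray
    extrapolated: np.ndarray  # boolean mask: grid point outside the data range


class CubicSplineBasis:
    """Cubic B-spline basis on [min(x), max(x)] with quantile knots."""

    def __init__(self, x, k: int = 10):
        x = np.asarray(x, dtype=float)
        distinct = np.unique(x)
        if k < 4:
            raise ValueError("CubicSplineBasis: k must be >= 4")
        if len(distinct) < k:
            raise ValueError(
                f"CubicSplineBasis: need >= k={k} distinct x values, got {len(distinct)}"
            )
        lo, hi = float(distinct[0]), float(distinct[-1])
        n_interior = k - _DEGREE - 1
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(distinct, qs)
        else:
            interior = np.array([])
        knots = np.concatenate(
            [[lo] * (_DEGREE + 1), interior, [hi] * (_DEGREE + 1)]
        )
        if np.any(np.diff(knots) < 0) or len(np.unique(interior)) != len(interior):
            raise ValueError("CubicSplineBasis: degenerate knot sequence from quantiles")
        self.knots = knots
        self.k = k
        self.x_min = lo
        self.x_max = hi
        self._penalty: np.ndarray | None = None

    def design(self, x) -> np.ndarray:
        """Basis matrix at arbitrary x (polynomial extension outside range)."""
        x = np.asarray(x, dtype=float)
        return BSpline.design_matrix(x, self.knots, _DEGREE, extrapolate=True).toarray()

    @property
    def penalty(self) -> np.ndarray:
        """P_ij = integral of B_i''(t) B_j''(t) dt over the data range.

        Symmetric PSD; its nullspace contains the coefficient vectors of
        constant and linear functions (zero curvature).
        """
        if self._penalty is None:
            d2 = BSpline(self.knots, np.eye(self.k), _DEGREE).derivative(2)
            breakpoints = np.unique(self.knots)
            P = np.zeros((self.k, self.k))
            # 2-point Gauss-Legendre per interval: exact for the piecewise
            # quadratic product of two piecewise-linear second derivatives
            gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
            for a, b in zip(breakpoints[:-1], breakpoints[1:]):
                half = (b - a) / 2.0
                mid = (a + b) / 2.0
                for g in gauss:
                    vals = d2(mid + half * g)  # (k,)
                    P += half * np.outer(vals, vals)
            self._penalty = (P + P.T) / 2.0
        return self._penalty

    def greville_sites(self) -> np.ndarray:
        """Knot averages: coefficient vector representing f(x) = x exactly."""
        t = self.knots
        return np.array(
            [t[i + 1 : i + 1 + _DEGREE].mean() for i in range(self.k)]
        )


@dataclass
class SplineFitResult:
    basis: CubicSplineBasis
    coefficients: np.ndarray
    lam: float
    edf: float
    sigma2: float
    n: int
    gcv_score: float
    _inv: np.ndarray  # (B'B + lam P)^-1
    _btb: np.ndarray

    def predict(self, grid) -> PredictionResult:
        """Point predictions with model-based pointwise standard errors.

        Grid points outside the observed x range are evaluated by
        polynomial extension and flagged as extrapolated.
        """
        grid = np.asarray(grid, dtype=float)
        Bg = self.basis.design(grid)
        mean = Bg @ self.coefficients
        # Var(fitted) = sigma^2 * Bg A B'B A Bg'  with A = (B'B + lam P)^-1
        M = self._inv @ self._btb @ self._inv
        var = self.sigma2 * np.einsum("ij,jk,ik->i", Bg, M, Bg)
        se = np.sqrt(np.clip(var, 0.0, None))
        extrapolated = (grid < self.basis.x_min) | (grid > self.basis.x_max)
        return PredictionResult(mean=mean, se=se, extrapolated=extrapolated)

    def fitted_values(self, x) -> np.ndarray:
        return self.basis.design(x) @ self.coefficients


def _solve_penalized(btb, bty, P, lam, n):
    C = btb + lam * P
    try:
        coef = np.linalg.solve(C, bty)
        inv = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "penalized system is rank deficient; increase lambda or reduce k"
        ) from err
    edf = float(np.trace(inv @ btb))
    return coef, inv, edf


def fit_penalized_spline(
    x,
    y,
    k: int = 10,
    lam: float | str = "gcv",
    lam_grid: np.ndarray | None = None,
    basis: CubicSplineBasis | None = None,
) -> SplineFitResult:
    """Fit the penalized spline; ``lam='gcv'`` picks the smoothing
    parameter minimizing n * RSS / (n - edf)^2 over a log grid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("fit_penalized_spline: x and y lengths differ")
    n = len(x)
    if k > n:
        raise ValueError(f"fit_penalized_spline: k={k} exceeds n={n}")
    if basis is None:
        basis = CubicSplineBasis(x, k=k)
    B = basis.design(x)
    btb = B.T @ B
    bty = B.T @ y
    P = basis.penalty

    if isinstance(lam, str):
        if lam != "gcv":
            raise ValueError(f"fit_penalized_spline: unknown lam option {lam!r}")
        scale = np.trace(btb) / max(np.trace(P), 1e-300)
        grid = lam_grid if lam_grid is not None else np.logspace(-7, 9, 65) * scale
        best = None
        for lam_try in grid:
            try:
                coef, inv, edf = _solve_penalized(btb, bty, P, lam_try, n)
            except np.linalg.LinAlgError:
                continue
            rss = float(np.sum((y - B @ coef) ** 2))
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, lam_try, coef, inv, edf, rss)
        if best is None:
            raise np.linalg.LinAlgError("fit_penalized_spline: no lambda on the grid is feasible")
        gcv, lam_val, coef, inv, edf, rss = best
    else:
        lam_val = float(lam)
        coef, inv, edf = _solve_penalized(btb, bty, P, lam_val, n)
        rss = float(np.sum((y - B @ coef) ** 2))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2

    sigma2 = rss / (n - edf) if n - edf > 1e-8 else 0.0
    return SplineFitResult(
        basis=basis,
        coefficients=coef,
        lam=float(lam_val),
        edf=edf,
        sigma2=sigma2,
        n=n,
        gcv_score=gcv,
        _inv=inv,
        _btb=btb,
    )
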