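"""Penalized spline bases for the hierarchical beta GAM.

Two low-rank smoothers:

* :class:`CyclicCubicBasis` — a cyclic cubic regression spline on a
  period (here 24 h): the spline's value and first two derivatives match
  at the cycle boundary, so the fitted diel curve is exactly periodic.
  Construction follows the standard value/second-derivative
  parameterization of interpolating natural cubics on cyclic knots, with
  the integrated-squared-second-derivative penalty.
* :class:`PSplineBasis` — a cubic B-spline basis with the exact
  second-derivative Gram penalty (a thin-plate-like smoother: linear
  functions span the penalty null space).

Both expose ``design(x)`` and a symmetric positive semi-definite
``penalty`` matrix.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["CyclicCubicBasis", "PSplineBasis", "center_basis"]


class CyclicCubicBasis:
    """Cyclic cubic regression spline basis with k knots over [x0, x0+period).

    The free coefficients are the spline values at the k-1 distinct knots
    (the k-th knot is identified with the first).  The penalty is the
    integral of the squared second derivative; constants lie in its null
    space.
    """

    def __init__(self, k: int = 10, period: float = 24.0, x0: float = 0.0):
        if k < 4:
            raise ValueError("cyclic cubic basis needs k >= 4")
        self.k = k
        self.period = period
        self.x0 = x0
        self.knots = x0 + np.linspace(0.0, period, k)  # k knots, last == first + period
        m = k - 1
        h = np.diff(self.knots)  # m interval lengths
        B = np.zeros((m, m))
        D = np.zeros((m, m))
        for i in range(m):
            im1 = (i - 1) % m
            ip1 = (i + 1) % m
            B[i, i] = (h[im1] + h[i]) / 3.0
            B[i, ip1] += h[i] / 6.0
            B[i, im1] += h[im1] / 6.0
            D[i, i] = -(1.0 / h[im1] + 1.0 / h[i])
            D[i, ip1] += 1.0 / h[i]
            D[i, im1] += 1.0 / h[im1]
        self._h = h
        self._F = np.linalg.solve(B, D)  # maps values -> second derivatives at knots
        S = D.T @ self._F
        self.penalty = (S + S.T) / 2.0

    @property
    def n_coef(self) -> int:
        return self.k - 1

    def design(self, x) -> np.ndarray:
        """Evaluate the m basis functions at `x` (wrapped into the period)."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        xr = self.x0 + np.mod(x - self.x0, self.period)
        m = self.k - 1
        X = np.zeros((x.size, m))
        j = np.clip(np.searchsorted(self.knots, xr, side="right") - 1, 0, m - 1)
        h = self._h[j]
        x_lo = self.knots[j]
        x_hi = self.knots[j + 1]
        a_lo = (x_hi - xr) / h
        a_hi = (xr - x_lo) / h
        c_lo = ((x_hi - xr) ** 3 / h - h * (x_hi - xr)) / 6.0
        c_hi = ((xr - x_lo) ** 3 / h - h * (xr - x_lo)) / 6.0
        rows = np.arange(x.size)
        X[rows, j] += a_lo
        X[rows, (j + 1) % m] += a_hi
        X += c_lo[:, None] * self._F[j, :]
        X += c_hi[:, None] * self._F[(j + 1) % m, :]
        return X[0] if scalar else X


class PSplineBasis:
    """Cubic B-spline basis of size k with the exact curvature penalty.

    Knots are spread uniformly over [lo, hi]; the penalty is the Gram
    matrix of second derivatives, integrated exactly (2-point
    Gauss-Legendre per knot span, exact for the piecewise-quadratic
    integrand of cubic splines).
    """

    def __init__(self, x, k: int = 22, lo: float | None = None, hi: float | None = None):
        x = np.asarray(x, dtype=float)
        if lo is None:
            lo = float(x.min())
        if hi is None:
            hi = float(x.max())
        if len(np.unique(x)) < 3:
            raise ValueError("day smooth needs at least 3 distinct values")
        if k < 4:
            raise ValueError("cubic B-spline basis needs k >= 4")
        self.k = k
        self.lo, self.hi = lo, hi
        n_interior = k - 4
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        self.t = np.concatenate([[lo] * 4, interior, [hi] * 4])
        self.penalty = self._curvature_penalty()

    @property
    def n_coef(self) -> int:
        return self.k

    def design(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        xc = np.clip(x, self.lo, self.hi)  # linear-tail extrapolation not supported
        X = BSpline.design_matrix(xc, self.t, 3).toarray()
        return X[0] if scalar else X

    def _second_deriv_matrix(self, x: np.ndarray) -> np.ndarray:
        cols = []
        eye = np.eye(self.k)
        for i in range(self.k):
            spl = BSpline(self.t, eye[i], 3)
            cols.append(spl.derivative(2)(x))
        return np.column_stack(cols)

    def _curvature_penalty(self) -> np.ndarray:
        spans = np.unique(self.t)
        S = np.zeros((self.k, self.k))
        gl_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        for a, b in zip(spans[:-1], spans[1:]):
            mid, half = (a + b) / 2.0, (b - a) / 2.0
            pts = mid + half * gl_x
            d2 = self._second_deriv_matrix(pts)
            S += half * (d2.T @ d2)  # weights are 1 at both GL nodes
        return (S + S.T) / 2.0


def center_basis(X: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the sum-to-zero identifiability constraint to a smooth.

    Reparameterizes so the smooth's fitted values sum to zero over the
    data, removing the confound with the model intercept.  Returns the
    constrained design, penalty and the (k x k-1) transform used, so new
    design matrices can be mapped into the same parameterization.
    """
    c = X.sum(axis=0, keepdims=True)
    # orthonormal basis of the null space of c
    q, _r = np.linalg.qr(c.T, mode="complete")
    Z = q[:, 1:]
    return X @ Z, Z.T @ S @ Z, Z
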