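"""Nonnegative baseline hazards as M-spline expansions.

An M-spline basis of order :math:`k` on a knot sequence is a rescaling of the
B-spline basis, :math:`M_j(t) = k\\,B_j(t)/(t_{j+k}-t_j)`, chosen so that each
basis function is nonnegative and integrates to one over its support.  A
baseline hazard :math:`h_0(t)=\\sum_j c_j M_j(t)` with coefficients
:math:`c_j\\ge 0` is therefore nonnegative everywhere, and its cumulative
hazard :math:`\\Lambda_0(t)=\\sum_j c_j I_j(t)` is available exactly through
the I-splines :math:`I_j` (the running integrals of the :math:`M_j`), with
:math:`\\Lambda_0(0)=0` and :math:`\\Lambda_0(t_{\\max})=\\sum_j c_j`.

Order 1 gives a piecewise-constant hazard (order 1 with no interior knots is
a constant hazard); order 4 (cubic, the default elsewhere) is the usual
smooth choice under a curvature penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline


class SupportError(ValueError):
    """A time fell outside the basis support [0, t_max]."""


@dataclass(frozen=True)
class MSplineBasis:
    """M-spline basis on ``[boundary[0], boundary[1]]`` with optional coefficients.

    Parameters
    ----------
    order:
        Spline order (degree + 1); 4 = cubic.
    interior_knots:
        Strictly increasing knots inside the boundary interval.
    boundary:
        ``(t_min, t_max)``; ``t_min`` is 0 for hazards measured from origin.
    coefficients:
        Optional nonnegative weights, one per basis function; ``None`` for a
        scaffold whose coefficients are estimated later.
    """

    order: int
    interior_knots: tuple[float, ...]
    boundary: tuple[float, float]
    coefficients: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        lo, hi = self.boundary
        if not hi > lo:
            raise ValueError("boundary interval is empty")
        ik = np.asarray(self.interior_knots, dtype=float)
        if ik.size and (np.any(np.diff(ik) <= 0) or ik[0] <= lo or ik[-1] >= hi):
            raise ValueError("interior knots must be strictly increasing inside the boundary")
        if self.coefficients is not None:
            c = np.asarray(self.coefficients, dtype=float)
            if c.shape != (self.n_basis,):
                raise ValueError(f"expected {self.n_basis} coefficients, got {c.shape}")
            if np.any(c < 0):
                raise ValueError("M-spline coefficients must be nonnegative")
            object.__setattr__(self, "coefficients", c)

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + self.order

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.concatenate([
            np.repeat(lo, self.order),
            np.asarray(self.interior_knots, dtype=float),
            np.repeat(hi, self.order),
        ])

    def with_coefficients(self, coefficients: np.ndarray) -> "MSplineBasis":
        return MSplineBasis(self.order, self.interior_knots, self.boundary,
                            np.asarray(coefficients, dtype=float))

    # -- basis matrices -----------------------------------------------------

    def _check_support(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lo, hi = self.boundary
        if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
            bad = t[(t < lo - 1e-12) | (t > hi + 1e-12)]
            raise SupportError(
                f"time(s) {bad[:3]} outside baseline support [{lo}, {hi}]")
        return np.clip(t, lo, hi)

    def basis_matrix(self, t) -> np.ndarray:
        """``(len(t), n_basis)`` matrix of M-spline values M_j(t)."""
        t = self._check_support(np.atleast_1d(t))
        kv = self.knot_vector
        k = self.order
        # evaluate at hi from the left so the last basis functions are finite
        lo, hi = self.boundary
        teval = np.where(t >= hi, np.nextafter(hi, lo), t)
        B = BSpline.design_matrix(teval, kv, k - 1).toarray()
        denom = kv[k:] - kv[:-k]
        M = B * (k / denom)
        # right-continuity convention: at t == hi use the left limit
        return M

    def integral_matrix(self, t) -> np.ndarray:
        """``(len(t), n_basis)`` matrix of I-spline values I_j(t) in [0, 1]."""
        t = self._check_support(np.atleast_1d(t))
        kv = self.knot_vector
        k = self.order
        denom = kv[k:] - kv[:-k]
        out = np.empty((t.size, self.n_basis))
        for j in range(self.n_basis):
            coef = np.zeros(self.n_basis)
            coef[j] = k / denom[j]
            anti = BSpline(kv, coef, k - 1, extrapolate=False).antiderivative()
            vals = anti(t)
            # antiderivative of a spline extrapolates its polynomial pieces;
            # clamp to the exact limits 0 and 1 outside the support
            vals = np.where(t <= kv[0], 0.0, vals)
            vals = np.where(t >= kv[-1], 1.0, vals)
            out[:, j] = vals
        return out

    def hazard(self, t) -> np.ndarray:
        """h0(t) = sum_j c_j M_j(t); requires coefficients."""
        c = self._coef()
        return self.basis_matrix(t) @ c

    def cumulative_hazard(self, t) -> np.ndarray:
        """Lambda0(t) = sum_j c_j I_j(t), exactly; requires coefficients."""
        c = self._coef()
        return self.integral_matrix(t) @ c

    def _coef(self) -> np.ndarray:
        if self.coefficients is None:
            raise ValueError("basis has no coefficients set")
        return self.coefficients

    # -- curvature penalty --------------------------------------------------

    def second_derivative_gram(self) -> np.ndarray:
        """Gram matrix P with P_jl = integral of M_j'' M_l'' over the support.

        Exact for polynomial splines: Gauss–Legendre quadrature per knot
        interval at enough nodes for the (2*order-6)-degree integrand.
        Requires order >= 3 (piecewise-smooth second derivative).
        """
        if self.order < 3:
            raise ValueError("curvature penalty requires spline order >= 3")
        kv = self.knot_vector
        k = self.order
        denom = kv[k:] - kv[:-k]
        breaks = np.unique(kv)
        npts = max(1, k - 2)  # degree of M_j'' is order-3; product degree 2k-6
        xg, wg = np.polynomial.legendre.leggauss(npts)
        P = np.zeros((self.n_basis, self.n_basis))
        d2 = []
        for j in range(self.n_basis):
            coef = np.zeros(self.n_basis)
            coef[j] = k / denom[j]
            d2.append(BSpline(kv, coef, k - 1, extrapolate=False).derivative(2))
        for a, b in zip(breaks[:-1], breaks[1:]):
            mid, half = 0.5 * (a + b), 0.5 * (b - a)
            ts = mid + half * xg
            vals = np.column_stack([np.nan_to_num(s(ts)) for s in d2])
            P += half * (vals * wg[:, None]).T @ vals
        return 0.5 * (P + P.T)


def mspline_design(times, n_interior_knots: int, order: int = 4,
                   t_max: float | None = None) -> MSplineBasis:
    """Place knots for a baseline hazard from observed event times.

    Boundary knots sit at 0 and the maximum follow-up time; interior knots at
    equispaced quantiles of the distinct observed event times (``i/(m+1)`` for
    ``i=1..m``).  Returns a scaffold with no coefficients.
    """
    times = np.asarray(times, dtype=float)
    distinct = np.unique(times)
    if distinct.size < 2:
        raise ValueError("need at least 2 distinct times to place knots")
    if t_max is None:
        t_max = float(distinct[-1])
    if distinct.size < n_interior_knots + 2:
        raise ValueError(
            f"only {distinct.size} distinct times for {n_interior_knots} "
            f"interior knots; use fewer knots")
    if n_interior_knots > 0:
        qs = np.arange(1, n_interior_knots + 1) / (n_interior_knots + 1)
        interior = np.quantile(distinct, qs)
        interior = np.unique(interior)
        interior = interior[(interior > 0) & (interior < t_max)]
        if len(interior) < n_interior_knots:
            raise ValueError(
                f"only {len(interior)} distinct interior knot positions available; "
                f"use fewer knots (requested {n_interior_knots})")
    else:
        interior = np.array([])
    return MSplineBasis(order=order, interior_knots=tuple(float(x) for x in interior),
                        boundary=(0.0, float(t_max)))


def roughness_penalty(basis: MSplineBasis,
                      coefficients: np.ndarray | None = None) -> float:
    """Curvature penalty ``integral of h0''(t)^2 dt`` for the given coefficients.

    A kappa-free quadratic form ``c' P c`` with ``P`` the exact Gram matrix of
    second derivatives; 0 when h0 is linear in t.
    """
    c = np.asarray(coefficients if coefficients is not None else basis._coef(),
                   dtype=float)
    P = basis.second_derivative_gram()
    return float(c @ P @ c)
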