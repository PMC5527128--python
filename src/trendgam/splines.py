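"""Cubic regression spline bases with second-derivative penalties.

The basis is parameterized by the function values at the knots: coefficient
``j`` multiplies the natural cubic spline that interpolates the ``j``-th unit
vector at the knots.  The penalty is the exact integrated squared second
derivative of the interpolating natural cubic spline, which is a quadratic
form in the knot values.  Outside the knot range the basis extrapolates
linearly (natural-spline boundary behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import null_space, solve_banded


def _penalty_matrices(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (B, D) of the natural-spline second-derivative system.

    With h_j = x_{j+1} - x_j, the interior knot second derivatives m satisfy
    B m = D beta, where beta are the knot values.  The roughness penalty is
    then D' B^{-1} D.
    """
    h = np.diff(knots)
    k = knots.size
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    return B, D


@dataclass(frozen=True)
class BasisSystem:
    """A cubic-regression-spline basis on a fixed knot vector.

    Attributes
    ----------
    knots
        Strictly increasing knot locations (time values, e.g. days).
    penalty
        ``k x k`` symmetric positive semi-definite matrix; the quadratic form
        ``coef' penalty coef`` equals the integral of the squared second
        derivative of the spline with knot values ``coef``.  Its null space
        is spanned by constant and linear functions (rank ``k - 2``).
    """

    knots: np.ndarray
    penalty: np.ndarray = field(repr=False)

    @property
    def dimension(self) -> int:
        return int(self.knots.size)

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        """Evaluate the basis at ``times``; rows = observations, cols = basis.

        Points outside ``[knots[0], knots[-1]]`` are extrapolated linearly
        from the boundary value and slope.
        """
        t = np.asarray(times, dtype=float)
        if t.ndim != 1:
            t = t.ravel()
        if not np.all(np.isfinite(t)):
            raise ValueError("evaluation times must be finite")
        k = self.dimension
        cs = CubicSpline(self.knots, np.eye(k), bc_type="natural", axis=0)
        lo, hi = self.knots[0], self.knots[-1]
        inner = np.clip(t, lo, hi)
        X = cs(inner)
        below = t < lo
        above = t > hi
        if below.any():
            X[below] += np.outer(t[below] - lo, cs(lo, 1))
        if above.any():
            X[above] += np.outer(t[above] - hi, cs(hi, 1))
        return X

    def is_extrapolating(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask flagging points outside the knot range."""
        t = np.asarray(times, dtype=float)
        return (t < self.knots[0]) | (t > self.knots[-1])


@dataclass(frozen=True)
class ConstrainedBasis:
    """A :class:`BasisSystem` with the sum-to-zero constraint absorbed.

    ``transform`` is a ``k x (k-1)`` matrix whose columns span the null space
    of the constraint ``sum over design rows of the basis matrix``.  The
    constrained basis matrix is ``parent.evaluate(t) @ transform`` and every
    constrained column sums to zero over the design times.
    """

    parent: BasisSystem
    transform: np.ndarray = field(repr=False)
    design_times: np.ndarray = field(repr=False)

    @property
    def dimension(self) -> int:
        return int(self.transform.shape[1])

    @property
    def penalty(self) -> np.ndarray:
        return self.transform.T @ self.parent.penalty @ self.transform

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        return self.parent.evaluate(times) @ self.transform

    def is_extrapolating(self, times: np.ndarray) -> np.ndarray:
        return self.parent.is_extrapolating(times)


def build_cr_basis(times: np.ndarray, k: int) -> BasisSystem:
    """Build a cubic regression spline basis with knots at quantiles of the
    unique time values (min and max included).

    Parameters
    ----------
    times
        Observed sampling times; duplicates allowed, knots use unique values.
    k
        Basis dimension (number of knots), ``k >= 3``.
    """
    t = np.asarray(times, dtype=float).ravel()
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if k < 3:
        raise ValueError(f"basis dimension k={k} must be >= 3")
    uniq = np.unique(t)
    if uniq.size < k:
        raise ValueError(
            f"need at least k={k} distinct time values to place knots, got {uniq.size}"
        )
    knots = np.quantile(uniq, np.linspace(0.0, 1.0, k))
    if np.any(np.diff(knots) <= 0):
        raise ValueError("quantile knots are not strictly increasing")
    B, D = _penalty_matrices(knots)
    # S = D' B^{-1} D via a banded solve of B M = D
    ab = np.zeros((3, k - 2))
    ab[0, 1:] = np.diag(B, 1)
    ab[1, :] = np.diag(B)
    ab[2, :-1] = np.diag(B, -1)
    M = solve_banded((1, 1), ab, D)
    S = D.T @ M
    S = 0.5 * (S + S.T)
    return BasisSystem(knots=knots, penalty=S)


def apply_centering(basis: BasisSystem, design_times: np.ndarray) -> ConstrainedBasis:
    """Absorb the sum-to-zero-over-design-points constraint into the basis.

    The returned basis has dimension ``k - 1``; its penalty is the congruent
    transform of the parent penalty.
    """
    t = np.asarray(design_times, dtype=float).ravel()
    X = basis.evaluate(t)
    c = X.sum(axis=0)
    Z = null_space(c[None, :])
    if Z.shape != (basis.dimension, basis.dimension - 1):
        raise ValueError("constraint absorption failed: unexpected null-space shape")
    return ConstrainedBasis(parent=basis, transform=Z, design_times=t)
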