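"""Penalized regression-spline bases: cyclic, non-cyclic, tensor, random.

Builds design-matrix blocks and quadratic penalty matrices for the
additive terms of the movement models:

* **cyclic cubic B-splines** for periodic covariates (wind direction,
  period 360 deg; day of year, period 365.25 d): a uniform cubic
  B-spline basis whose end columns are folded onto the start, so value
  and first two derivatives match at the period endpoints by
  construction;
* **cubic regression splines** with quantile-placed knots and a
  second-derivative (curvature) penalty for non-periodic covariates
  (solar radiation, wind strength, age);
* **tensor-product smooths** as row-wise Kronecker products of two
  marginal bases, with one Kronecker-expanded marginal penalty (and one
  smoothing parameter) per margin;
* **random-intercept blocks** (indicator columns, identity penalty),
  i.e. i.i.d. Gaussian intercepts in the ridge formulation.

Penalties integrate the squared second derivative exactly using
two-point Gauss-Legendre quadrature per knot interval (the integrand is
piecewise quadratic for cubic splines).  Each smooth is made
identifiable by a sum-to-zero constraint over the observed data,
absorbed by a null-space reparametrisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

GAUSS2 = (np.array([-1.0, 1.0]) / np.sqrt(3.0), np.array([1.0, 1.0]))


@dataclass
class BasisBlock:
    """A design block with its penalty matrices (one lambda each)."""

    name: str
    design: np.ndarray                  # (n, p) after constraint absorption
    penalties: list[np.ndarray]         # each (p, p), PSD
    predict: object                     # callable(data) -> (m, p) design
    null_dim: int = 0                   # penalty null-space dimension


def _bspline_design(x: np.ndarray, knots: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Evaluate all cubic B-spline basis functions (columns) at x."""
    p = len(knots) - 4
    out = np.empty((len(x), p))
    for j in range(p):
        c = np.zeros(p)
        c[j] = 1.0
        out[:, j] = BSpline(knots, c, 3, extrapolate=False)(x) if deriv == 0 else \
            BSpline(knots, c, 3, extrapolate=False).derivative(deriv)(x)
    return np.nan_to_num(out)


def _curvature_penalty(knots: np.ndarray, fold: int = 0) -> np.ndarray:
    """Exact integral of products of second derivatives over the knot span."""
    interior = np.unique(knots[3:-3])
    p = len(knots) - 4
    S = np.zeros((p, p))
    nodes, weights = GAUSS2
    for a, b in zip(interior[:-1], interior[1:]):
        mid, half = (a + b) / 2.0, (b - a) / 2.0
        xs = mid + half * nodes
        D2 = _bspline_design(xs, knots, deriv=2)
        S += half * (D2.T * weights) @ D2
    if fold:
        S = _fold(S.T, fold).T
        S = _fold(S, fold)
    return S


def _fold(mat: np.ndarray, fold: int) -> np.ndarray:
    """Fold the last ``fold`` columns onto the first (cyclic wrap)."""
    out = mat[:, :-fold].copy()
    out[:, :fold] += mat[:, -fold:]
    return out


def cyclic_basis(x: np.ndarray, k: int, period: float, x0: float = 0.0):
    """Cyclic cubic B-spline basis of dimension ``k`` on [x0, x0+period].

    Returns ``(design, penalty, evaluate)`` where ``evaluate`` maps new
    covariate values to design rows (periodic in the covariate).
    """
    if k < 4:
        raise ValueError("cyclic basis requires k >= 4")
    h = period / k
    knots = x0 + h * np.arange(-3, k + 4)

    def evaluate(v: np.ndarray) -> np.ndarray:
        vv = x0 + np.mod(np.asarray(v, dtype=float) - x0, period)
        return _fold(_bspline_design(vv, knots), 3)

    S = _curvature_penalty(knots, fold=3)
    return evaluate(x), S, evaluate


def crs_basis(x: np.ndarray, k: int):
    """Cubic regression spline with quantile knots and curvature penalty."""
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < k:
        raise ValueError(f"fewer unique covariate values than basis size {k}")
    if k < 4:
        raise ValueError("basis size must be >= 4")
    interior = np.quantile(x, np.linspace(0, 1, k - 2))
    interior = np.unique(interior)
    lo, hi = interior[0], interior[-1]
    span = max(hi - lo, 1e-9)
    knots = np.concatenate([np.full(3, lo - 1e-6 * span), interior,
                            np.full(3, hi + 1e-6 * span)])

    def evaluate(v: np.ndarray) -> np.ndarray:
        vv = np.clip(np.asarray(v, dtype=float), knots[0], knots[-1])
        return _bspline_design(vv, knots)

    S = _curvature_penalty(knots)
    return evaluate(x), S, evaluate


def sum_to_zero(design: np.ndarray, penalties: list[np.ndarray]):
    """Absorb the sum-to-zero constraint 1'Xb = 0 via a null-space basis.

    Returns the reduced design, reduced penalties and the (p, p-1)
    transform Z for use at prediction time.
    """
    c = design.sum(axis=0)
    nc = np.linalg.norm(c)
    if nc < 1e-12:
        return design, penalties, np.eye(design.shape[1])
    # Householder: columns 2..p of the reflector that maps c to e1
    v = c / nc
    e = np.zeros_like(v)
    e[0] = 1.0
    w = v + np.sign(v[0] if v[0] != 0 else 1.0) * e
    w = w / np.linalg.norm(w)
    Hh = np.eye(len(c)) - 2.0 * np.outer(w, w)
    Z = Hh[:, 1:]
    return design @ Z, [Z.T @ S @ Z for S in penalties], Z


def tensor_design(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker product of two marginal designs."""
    return (A[:, :, None] * B[:, None, :]).reshape(len(A), -1)


def tensor_penalties(Sa: np.ndarray, Sb: np.ndarray, pa: int, pb: int):
    """Marginal penalties expanded to the tensor coefficient space."""
    return [np.kron(Sa, np.eye(pb)), np.kron(np.eye(pa), Sb)]
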