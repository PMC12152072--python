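"""Emax mean response, gradients, reparametrization and information matrices.

The model is ``y = eta(x, theta) + eps`` with Gaussian errors of known
standard deviation sigma, where

    eta(x, theta) = theta0 + theta1 * x / (x + theta2).

On a dose range [a, b] with a >= 0 the admissible parameter space is
theta2 > -a with theta1*theta2 > 0, which makes eta increasing and concave
on [a, b] (for theta2 > 0 this is the familiar theta1 > 0).
When a > 0 the model is more naturally expressed in the shifted coordinate
``x_tilde = x - a``; :func:`to_shifted` / :func:`from_shifted` map between the
two parametrizations.

The locally D-optimal design puts weight 1/3 at each of {a, x*(theta2), b},
where x* is the dose at which the mean response equals the average of the
responses at the two extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmaxParams",
    "ShiftedEmaxParams",
    "ThreePointDesign",
    "InformationMatrices",
    "eta",
    "grad_eta",
    "to_shifted",
    "from_shifted",
    "d_optimal_x2",
    "d_optimal_design",
    "expected_information",
    "observed_information",
    "information_matrices",
]

#: numeric margin kept between parameters and the admissibility boundary
POLE_MARGIN = 1e-8


@dataclass(frozen=True)
class EmaxParams:
    """Parameter vector theta = (theta0, theta1, theta2).

    theta0 is the response at dose zero (placebo level), theta1 > 0 the
    asymptotic maximum effect, and theta2 the dose-scale half-effect
    parameter (the dose producing half the maximum effect when a = 0).
    """

    theta0: float
    theta1: float
    theta2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.theta0, self.theta1, self.theta2], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "EmaxParams":
        t0, t1, t2 = np.asarray(arr, dtype=float)
        return cls(float(t0), float(t1), float(t2))

    def validate(self, a: float = 0.0, margin: float = POLE_MARGIN) -> "EmaxParams":
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("Emax parameters must be finite")
        if self.theta2 <= -a + margin:
            raise ValueError(
                f"theta2 must exceed -a = {-a} (margin {margin}), got {self.theta2}"
            )
        # increasing-concave branch: theta1 > 0 when theta2 > 0; when the
        # vertical asymptote lies in (-a, 0) the same branch has theta1 < 0
        if self.theta1 * self.theta2 <= 0:
            raise ValueError(
                f"need theta1*theta2 > 0 for an increasing concave curve, "
                f"got theta1={self.theta1}, theta2={self.theta2}"
            )
        return self


@dataclass(frozen=True)
class ShiftedEmaxParams:
    """Parameters of the same curve in the shifted coordinate x_tilde = x - a.

    t0 is the mean response at the lowest dose a, t1 the maximum effect
    relative to that response, and t2 = theta2 + a > 0.
    """

    t0: float
    t1: float
    t2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.t0, self.t1, self.t2], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ShiftedEmaxParams":
        t0, t1, t2 = np.asarray(arr, dtype=float)
        return cls(float(t0), float(t1), float(t2))

    def validate(self, margin: float = POLE_MARGIN) -> "ShiftedEmaxParams":
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("shifted Emax parameters must be finite")
        if self.t1 <= 0 or self.t2 <= margin:
            raise ValueError(f"need t1 > 0 and t2 > 0, got t1={self.t1}, t2={self.t2}")
        return self


@dataclass(frozen=True)
class ThreePointDesign:
    """Three-point design {a, x2, b} with weights summing to one."""

    a: float
    x2: float
    b: float
    weights: tuple = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self):
        if not (0 <= self.a < self.x2 < self.b):
            raise ValueError(
                f"need 0 <= a < x2 < b, got a={self.a}, x2={self.x2}, b={self.b}"
            )
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be three nonnegative values summing to 1")

    @property
    def support(self) -> np.ndarray:
        return np.array([self.a, self.x2, self.b], dtype=float)

    def counts(self, n_per_point) -> np.ndarray:
        """Explicit per-point replicate counts (positive integers)."""
        n = np.broadcast_to(np.asarray(n_per_point), (3,)).astype(float)
        if np.any(n < 1) or np.any(n != np.round(n)):
            raise ValueError("replicate counts must be positive integers")
        return n.astype(int)


@dataclass(frozen=True)
class InformationMatrices:
    """Expected (Fisher) and observed information at a given theta."""

    expected: np.ndarray
    observed: np.ndarray | None
    sigma: float


def _theta_tuple(params) -> tuple:
    if isinstance(params, EmaxParams):
        return params.theta0, params.theta1, params.theta2
    if isinstance(params, ShiftedEmaxParams):
        return params.t0, params.t1, params.t2
    t0, t1, t2 = np.asarray(params, dtype=float)
    return float(t0), float(t1), float(t2)


def eta(x, params):
    """Emax mean response theta0 + theta1 * x / (x + theta2); vectorized in x."""
    t0, t1, t2 = _theta_tuple(params)
    x = np.asarray(x, dtype=float)
    denom = x + t2
    if np.any(np.abs(denom) < POLE_MARGIN):
        raise ValueError(f"dose {x} too close to the pole at -theta2 = {-t2}")
    out = t0 + t1 * x / denom
    return out if out.ndim else float(out)


def grad_eta(x, params):
    """Gradient of eta w.r.t. theta: (1, x/(x+theta2), -theta1*x/(x+theta2)^2).

    Returns shape (3,) for scalar x, else (3,) + x.shape.
    """
    t0, t1, t2 = _theta_tuple(params)
    x = np.asarray(x, dtype=float)
    denom = x + t2
    if np.any(np.abs(denom) < POLE_MARGIN):
        raise ValueError(f"dose {x} too close to the pole at -theta2 = {-t2}")
    g = np.stack([np.ones_like(x), x / denom, -t1 * x / denom**2])
    return g


def to_shifted(params: EmaxParams, a: float) -> ShiftedEmaxParams:
    """Reparametrize to the shifted coordinate x_tilde = x - a.

    t0 = theta0 + a*theta1/(theta2+a); t1 = theta1 - a*theta1/(theta2+a);
    t2 = theta2 + a.  The curve is unchanged: eta(x, theta) = eta(x-a, t).
    """
    t0, t1, t2 = _theta_tuple(params)
    if t2 + a <= 0:
        raise ValueError(f"theta2 + a must be positive, got {t2 + a}")
    shift = a * t1 / (t2 + a)
    return ShiftedEmaxParams(t0 + shift, t1 - shift, t2 + a)


def from_shifted(params: ShiftedEmaxParams, a: float) -> EmaxParams:
    """Inverse of :func:`to_shifted` (exact algebraic inverse)."""
    t0, t1, t2 = _theta_tuple(params)
    if t2 <= 0:
        raise ValueError(f"shifted t2 must be positive, got {t2}")
    # theta2 = t2 - a; theta1 solves t1 = theta1 * t2' / (t2' + a) with t2' = theta2
    theta2 = t2 - a
    theta1 = t1 * t2 / (t2 - a) if t2 != a else np.inf
    if not np.isfinite(theta1):
        raise ValueError("shifted parameters map to an inadmissible theta (pole at a)")
    shift = a * theta1 / t2
    return EmaxParams(t0 - shift, theta1, theta2)


def d_optimal_x2(a: float, b: float, theta2: float) -> float:
    """Middle dose of the locally D-optimal design.

    x*(theta2) = (b(a+theta2) + a(b+theta2)) / ((a+theta2) + (b+theta2)).
    Always lies strictly inside (a, (a+b)/2] and satisfies
    eta(x*) = (eta(a) + eta(b)) / 2.
    """
    if b <= a:
        raise ValueError(f"need b > a, got a={a}, b={b}")
    if theta2 <= -a:
        raise ValueError(f"need theta2 > -a = {-a}, got {theta2}")
    return (b * (a + theta2) + a * (b + theta2)) / ((a + theta2) + (b + theta2))


def d_optimal_design(a: float, b: float, theta2: float) -> ThreePointDesign:
    """Locally D-optimal design: equal weights 1/3 at {a, x*(theta2), b}."""
    return ThreePointDesign(a, d_optimal_x2(a, b, theta2), b)


def expected_information(support, counts, params, sigma: float) -> np.ndarray:
    """Expected (Fisher) information (1/sigma^2) sum_i n_i grad_i grad_i^T."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if isinstance(support, ThreePointDesign):
        support = support.support
    x = np.atleast_1d(np.asarray(support, dtype=float))
    n = np.broadcast_to(np.asarray(counts, dtype=float), x.shape)
    g = grad_eta(x, params)  # (3, m)
    return (g * n) @ g.T / sigma**2


def information_matrices(
    support, counts, params, sigma: float, data=None
) -> InformationMatrices:
    """Bundle expected and (if per-observation data given) observed information.

    ``data`` is an optional pair of per-observation arrays (x, y).
    """
    expected = expected_information(support, counts, params, sigma)
    observed = None
    if data is not None:
        observed = observed_information(data[0], data[1], params, sigma)
    return InformationMatrices(expected=expected, observed=observed, sigma=float(sigma))


def observed_information(x, y, params, sigma: float) -> np.ndarray:
    """Observed information (negative log-likelihood Hessian) at theta.

    Per-observation doses x and responses y.  Differs from the expected
    information only through the residuals y - eta(x, theta) in the
    (2,3)/(3,2) and (3,3) entries; with zero residuals it equals the
    expected information.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t0, t1, t2 = _theta_tuple(params)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    d = x + t2
    if np.any(np.abs(d) < POLE_MARGIN):
        raise ValueError("dose too close to the pole at -theta2")
    O = np.empty((3, 3))
    r = x / d
    O[0, 0] = len(x)
    O[0, 1] = O[1, 0] = np.sum(r)
    O[0, 2] = O[2, 0] = np.sum(-t1 * x / d**2)
    O[1, 1] = np.sum(r**2)
    O[1, 2] = O[2, 1] = np.sum(x / d**2 * (y - t0 - 2 * t1 * r))
    O[2, 2] = np.sum(3 * t1**2 * x**2 / d**4 - 2 * t1 * x * (y - t0) / d**3)
    return O / sigma**2
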