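"""Exact shape-region probabilities, the Case-1 power function and design choice.

The per-dose sample means are independent Gaussians,
ybar_i ~ N(eta(x_i, theta), sigma^2/n_i).  Every shape region (existence,
the two Case-1 subcases, Case 2) is a set of linear inequalities in
contrasts of the ybar_i, so each probability reduces to the mass of a
polyhedral cone under a bivariate Gaussian in the contrast coordinates
(u, v) = (ybar2 - ybar1, ybar3 - ybar1).  These are computed by adaptive
1-D quadrature of the conditional-normal slice, to absolute tolerance
~1e-10 - deterministic and fast.

Observing Case 1 (concave non-increasing means) rejects the one-sided
hypothesis H0: theta2 >= theta2_guess in favor of H1: theta2 < theta2_guess.
The power function beta(theta2; x2) = P(Case 1) is increasing in x2, so
bisection inverts it: x2_for_alpha picks the middle dose whose significance
level is a prescribed alpha, and recommend_augmentation proposes where to
add observations after a Case-1 outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .model import EmaxParams, ThreePointDesign, d_optimal_x2, eta

__all__ = [
    "ShapeProbabilities",
    "PowerCurve",
    "AugmentationPlan",
    "shape_probabilities",
    "power_beta",
    "x2_for_alpha",
    "recommend_augmentation",
]

#: absolute tolerance of the cone-probability quadrature
INTEGRATION_TOL = 1e-10


@dataclass(frozen=True)
class ShapeProbabilities:
    """Probabilities of the shape regions for one design/parameter setting."""

    p_exists: float
    p_case1: float
    p_case1_below: float
    p_case1_above: float
    p_case2: float
    design: ThreePointDesign
    counts: tuple
    theta: tuple
    sigma: float
    method: str = "gauss-cone-quadrature"
    tol: float = INTEGRATION_TOL


@dataclass(frozen=True)
class PowerCurve:
    """beta(theta2; x2) evaluated on a grid of true theta2 values."""

    theta2_grid: np.ndarray
    beta: np.ndarray
    x2: float
    alpha: float | None = None


@dataclass(frozen=True)
class AugmentationPlan:
    """Recommended follow-up dose after observing Case 1.

    The hypothesis H0: theta2 >= theta2_guess has been rejected, so new
    observations should go to x*(theta2_new) for some theta2_new below the
    guess; the admissible interval for the new dose is (a, x*(theta2_guess)).
    """

    theta2_guess: float
    theta2_new: float
    interval: tuple
    recommended_x2: float
    alpha: float | None
    note: str = (
        "H0: theta2 >= theta2_guess rejected by the Case-1 outcome; "
        "theta2_new = theta2_guess/2 is a convention, not an estimate"
    )


def _cone_probability(B: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """P(B w < 0) for bivariate Gaussian w ~ N(mean, cov); rows of B in 2-D."""
    mu_u, mu_v = mean
    su = np.sqrt(cov[0, 0])
    sv = np.sqrt(cov[1, 1])
    rho = cov[0, 1] / (su * sv)
    cs = sv * np.sqrt(max(1.0 - rho**2, 1e-16))
    ulo, uhi = -np.inf, np.inf
    v_rows = []
    for cu, cv in B:
        if cv == 0:
            if cu > 0:
                uhi = min(uhi, 0.0)
            elif cu < 0:
                ulo = max(ulo, 0.0)
        else:
            v_rows.append((cu, cv))

    def integrand(u):
        vlo, vhi = -np.inf, np.inf
        for cu, cv in v_rows:
            bnd = -cu * u / cv
            if cv > 0:
                vhi = min(vhi, bnd)
            else:
                vlo = max(vlo, bnd)
        if vhi <= vlo:
            return 0.0
        cm = mu_v + rho * sv / su * (u - mu_u)
        p = stats.norm.cdf((vhi - cm) / cs) - stats.norm.cdf((vlo - cm) / cs)
        return stats.norm.pdf(u, mu_u, su) * max(p, 0.0)

    lo = max(ulo, mu_u - 12 * su)
    hi = min(uhi, mu_u + 12 * su)
    if hi <= lo:
        return 0.0
    val, _ = integrate.quad(
        integrand, lo, hi, epsabs=INTEGRATION_TOL, epsrel=1e-10, limit=200
    )
    return float(min(max(val, 0.0), 1.0))


def _contrast_gaussian(design: ThreePointDesign, counts, theta, sigma):
    """Mean and covariance of (u, v) = (ybar2 - ybar1, ybar3 - ybar1)."""
    x = design.support
    n = np.asarray(counts, dtype=float)
    mu = eta(x, theta)
    s2 = sigma**2 / n
    mean = np.array([mu[1] - mu[0], mu[2] - mu[0]])
    cov = np.array([[s2[0] + s2[1], s2[0]], [s2[0], s2[0] + s2[2]]])
    return mean, cov


def shape_probabilities(
    design: ThreePointDesign, counts, theta, sigma: float
) -> ShapeProbabilities:
    """Exact probabilities of every shape region for Gaussian sample means.

    All regions are cones in the contrasts (u, v); each linear-inequality
    matrix A acts on ybar only through its last two columns because every
    row is a contrast (rows sum to zero).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    n = np.asarray(counts, dtype=float)
    if n.shape != (3,) or np.any(n < 1):
        raise ValueError("counts must be three values >= 1")
    mean, cov = _contrast_gaussian(design, counts, theta, sigma)
    x = design.support
    d21, d31 = x[1] - x[0], x[2] - x[0]
    concave = np.array([-1 / d21, 1 / d31])  # row.(u,v) < 0  <=>  m1 > m2
    w2 = n[1] / (n[1] + n[2])
    w3 = n[2] / (n[1] + n[2])
    p_exists = _cone_probability(
        np.array([concave, [-1.0, 0.0], [1.0, -1.0]]), mean, cov
    )
    p_c1_below = _cone_probability(
        np.array([concave, [-w2, -w3], [-1.0, 1.0]]), mean, cov
    )
    p_c1_above = _cone_probability(
        np.array([concave, [w2, w3], [-1.0, 1.0]]), mean, cov
    )
    # Case 2 is the single event m1 <= m2, i.e. concave.(u,v) >= 0
    m = concave @ mean
    sd = float(np.sqrt(concave @ cov @ concave))
    p_case2 = float(stats.norm.cdf(m / sd))
    if isinstance(theta, EmaxParams):
        theta_t = (theta.theta0, theta.theta1, theta.theta2)
    else:
        theta_t = tuple(float(t) for t in np.asarray(theta, dtype=float))
    return ShapeProbabilities(
        p_exists=p_exists,
        p_case1=p_c1_below + p_c1_above,
        p_case1_below=p_c1_below,
        p_case1_above=p_c1_above,
        p_case2=p_case2,
        design=design,
        counts=tuple(int(c) for c in n),
        theta=theta_t,
        sigma=float(sigma),
    )


def power_beta(theta2: float, x2: float, fixed: dict) -> float:
    """Power beta(theta2; x2) = P(Case 1) of the one-sided test on theta2.

    ``fixed`` carries a, b, theta0, theta1, sigma and counts (per-point
    replicate numbers).  theta2 is substituted as the true value.
    """
    design = ThreePointDesign(fixed["a"], x2, fixed["b"])
    theta = (fixed["theta0"], fixed["theta1"], theta2)
    probs = shape_probabilities(design, fixed["counts"], theta, fixed["sigma"])
    return probs.p_case1


def x2_for_alpha(
    alpha: float,
    theta2_guess: float,
    fixed: dict,
    tol: float = 1e-8,
) -> tuple:
    """Middle dose x2 whose significance level beta(theta2_guess; x2) = alpha.

    Solved by bisection on x2 in [a + 1e-6 (b-a), (a+b)/2]; beta is
    continuous and increasing in x2 over this bracket.  Returns
    (x2, achieved_beta); raises if alpha is outside the attainable range.
    """
    a, b = fixed["a"], fixed["b"]
    lo = a + 1e-6 * (b - a)
    hi = (a + b) / 2
    blo = power_beta(theta2_guess, lo, fixed)
    bhi = power_beta(theta2_guess, hi, fixed)
    if not (min(blo, bhi) <= alpha <= max(blo, bhi)):
        raise ValueError(
            f"alpha={alpha} not attainable: beta ranges over "
            f"[{min(blo, bhi):.3e}, {max(blo, bhi):.3e}] for x2 in "
            f"[{lo:.6g}, {hi:.6g}]"
        )
    sign = 1.0 if bhi >= blo else -1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if sign * (power_beta(theta2_guess, mid, fixed) - alpha) < 0:
            lo = mid
        else:
            hi = mid
    x2 = 0.5 * (lo + hi)
    return x2, power_beta(theta2_guess, x2, fixed)


def recommend_augmentation(
    theta2_guess: float,
    fixed: dict,
    alpha: float | None = None,
    theta2_new: float | None = None,
) -> AugmentationPlan:
    """Follow-up plan after a Case-1 outcome.

    New observations should be taken at x*(theta2_new) for some
    theta2_new < theta2_guess; the default convention is
    theta2_new = theta2_guess / 2.
    """
    a, b = fixed["a"], fixed["b"]
    if theta2_new is None:
        theta2_new = theta2_guess / 2
    if not (-a < theta2_new < theta2_guess):
        raise ValueError("theta2_new must lie in (-a, theta2_guess)")
    upper = d_optimal_x2(a, b, theta2_guess)
    return AugmentationPlan(
        theta2_guess=theta2_guess,
        theta2_new=theta2_new,
        interval=(a, upper),
        recommended_x2=d_optimal_x2(a, b, theta2_new),
        alpha=alpha,
    )
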