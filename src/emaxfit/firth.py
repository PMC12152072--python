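"""Firth's modified-score estimation for the Emax model.

Firth's bias-reducing adjustment adds A_t = (1/2) trace{I^{-1}(P_t + Q_t)}
to the t-th score component.  For Gaussian nonlinear regression P_t = 0,
and for the Emax model the Q_t matrices are sparse (only the (2,3)/(3,2)
and (3,3) entries are nonzero), which yields the closed forms

    A1 =  (V11*M13 - Cov12*M12) / (theta1 * D),
    A2 =  (V11*M24 - Cov12*M23) / (theta1 * D),
    A3 = -(V11*M25 - Cov12*M24) / D,

with design moments M[l1,l2] = E_xi[x^l1/(theta2+x)^l2], variances
V11 = M22 - M11^2, V12 = M24 - M12^2, covariance Cov12 = M23 - M11*M12 and
D = V11*V12 - Cov12^2 (positive for any nondegenerate design by strict
Cauchy-Schwarz).  A depends only on the design weights and (theta1,
theta2) - not on n or sigma - while the score U scales as n/sigma^2, so
the adjustment vanishes asymptotically.

The modified-score equations U + A = 0 admit no penalized-likelihood
formulation (their Jacobian is asymmetric); they are solved by a damped
multi-start root finder over the unconstrained reparametrization
theta1 = exp(phi1), theta2 = -a + exp(phi2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .model import EmaxParams, eta, grad_eta
from .shape import SampleSummary

__all__ = [
    "FirthTerms",
    "ModifiedScoreSolution",
    "score",
    "firth_terms",
    "modified_score",
    "solve_modified_score",
]

_D_TOL = 1e-300  # D is compared against this to detect degenerate designs


@dataclass(frozen=True)
class FirthTerms:
    """Design moments and the resulting additive score adjustment A."""

    M: dict  # {(l1, l2): moment}
    V11: float
    V12: float
    Cov12: float
    D: float
    A: np.ndarray


@dataclass(frozen=True)
class ModifiedScoreSolution:
    """Root of the modified score equations U* = 0 (or a failure report)."""

    params: EmaxParams | None
    converged: bool
    admissible: bool
    residual_norm: float
    n_starts_used: int
    message: str = ""


def score(data, params, sigma: float | None = None) -> np.ndarray:
    """Score vector U = (1/sigma^2) sum_i [y_i - eta(x_i)] grad_eta(x_i).

    ``data`` is either a :class:`SampleSummary` (sufficiency: the sum runs
    over the three per-dose means with their counts) or a pair of
    per-observation arrays ``(x, y)``, in which case ``sigma`` is required.
    """
    if isinstance(data, SampleSummary):
        x, y, n = data.x, data.ybar, data.n
        sigma = data.sigma if sigma is None else sigma
    else:
        x, y = (np.atleast_1d(np.asarray(v, dtype=float)) for v in data)
        n = np.ones_like(x)
        if sigma is None:
            raise ValueError("sigma is required with per-observation data")
    resid = y - eta(x, params)
    g = grad_eta(x, params)
    return (g * (n * resid)).sum(axis=1) / sigma**2


def firth_terms(support, weights, params) -> FirthTerms:
    """Moments, variances and the adjustment A for a design and parameters.

    ``weights`` are design proportions (they are normalized internally, so
    replicate counts work too).  Requires at least two distinct support
    points, which makes D > 0.
    """
    if isinstance(params, EmaxParams):
        t1, t2 = params.theta1, params.theta2
    else:
        _, t1, t2 = np.asarray(params, dtype=float)
    if t1 == 0:
        raise ValueError("theta1 must be nonzero for the Firth adjustment")
    x = np.atleast_1d(np.asarray(support, dtype=float))
    w = np.atleast_1d(np.asarray(weights, dtype=float))
    w = w / w.sum()
    d = x + t2
    if np.any(d <= 0):
        raise ValueError("design points must satisfy x + theta2 > 0")
    M = {
        (l1, l2): float(np.sum(w * x**l1 / d**l2))
        for l1 in (1, 2)
        for l2 in range(1, 6)
    }
    V11 = M[(2, 2)] - M[(1, 1)] ** 2
    V12 = M[(2, 4)] - M[(1, 2)] ** 2
    Cov12 = M[(2, 3)] - M[(1, 1)] * M[(1, 2)]
    D = V11 * V12 - Cov12**2
    if D <= _D_TOL:
        raise ValueError(
            "degenerate design: the Firth adjustment requires at least two "
            "distinct support points with positive weight"
        )
    A = np.array(
        [
            (V11 * M[(1, 3)] - Cov12 * M[(1, 2)]) / (t1 * D),
            (V11 * M[(2, 4)] - Cov12 * M[(2, 3)]) / (t1 * D),
            -(V11 * M[(2, 5)] - Cov12 * M[(2, 4)]) / D,
        ]
    )
    return FirthTerms(M, float(V11), float(V12), float(Cov12), float(D), A)


def modified_score(summary: SampleSummary, params, sigma: float | None = None) -> np.ndarray:
    """Modified score U* = U + A; A uses the summary's design weights."""
    U = score(summary, params, sigma)
    terms = firth_terms(summary.x, summary.n, params)
    return U + terms.A


def _default_starts(summary: SampleSummary) -> list:
    """Deterministic multi-start list (theta0, theta1, theta2)."""
    y = summary.ybar
    x2, b = summary.design.x2, summary.design.b
    t1 = max(y[2] - y[0], 1e-2 * max(1.0, float(np.max(np.abs(y)))))
    starts = [(float(y[0]), float(t1), float(g)) for g in (x2 / 4, x2, 2 * x2, b)]
    # analytic-MLE-like plug-in when the closed form lands in the admissible region
    from .estimation import MLEDoesNotExistError, mle_original

    try:
        p = mle_original(summary)
        starts.append((p.theta0, p.theta1, p.theta2))
    except (MLEDoesNotExistError, ValueError):
        pass
    return starts


def solve_modified_score(
    summary: SampleSummary,
    sigma: float | None = None,
    init: EmaxParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> ModifiedScoreSolution:
    """Find an admissible root of U* = 0 by multi-start damped root finding.

    The search runs in the unconstrained coordinates
    ``(theta0, log theta1, log(theta2 + a))``.  A root is admissible when
    the solver converged, ||U*||_inf < tol * (n/sigma^2) * scale,
    theta1 > 1e-8, theta2 > -a + 1e-8 and |theta2| < 1e6 * b.  Starts are
    tried in a fixed deterministic order and the first admissible root
    wins; if none is found the solution is returned with
    ``converged=False`` (no exception).
    """
    sigma = summary.sigma if sigma is None else sigma
    a, b = summary.design.a, summary.design.b
    x, ybar, n = summary.x, summary.ybar, summary.n
    w = n / n.sum()
    n_total = float(n.sum())
    scale = max(1.0, float(np.max(np.abs(ybar))))
    res_tol = tol * (n_total / sigma**2) * scale
    inv_s2 = 1.0 / sigma**2

    def fun(phi):
        # inline U + A (same math as score() + firth_terms().A, minus overhead)
        t0 = phi[0]
        t1 = np.exp(phi[1])
        t2 = -a + np.exp(phi[2])
        d = x + t2
        r = x / d
        resid = ybar - t0 - t1 * r
        U0 = inv_s2 * np.sum(n * resid)
        U1 = inv_s2 * np.sum(n * resid * r)
        U2 = -t1 * inv_s2 * np.sum(n * resid * x / d**2)
        m11 = np.sum(w * r)
        m12 = np.sum(w * x / d**2)
        m13 = np.sum(w * x / d**3)
        m22 = np.sum(w * r**2)
        m23 = np.sum(w * x**2 / d**3)
        m24 = np.sum(w * x**2 / d**4)
        m25 = np.sum(w * x**2 / d**5)
        V11 = m22 - m11**2
        V12 = m24 - m12**2
        Cov = m23 - m11 * m12
        D = V11 * V12 - Cov**2
        return np.array(
            [
                U0 + (V11 * m13 - Cov * m12) / (t1 * D),
                U1 + (V11 * m24 - Cov * m23) / (t1 * D),
                U2 - (V11 * m25 - Cov * m24) / D,
            ]
        )

    starts = []
    if init is not None:
        starts.append((init.theta0, init.theta1, init.theta2))
    starts.extend(_default_starts(summary))

    best = None
    n_used = 0
    for t0, t1, t2 in starts:
        if t1 <= 0 or t2 + a <= 0:
            continue
        n_used += 1
        phi0 = np.array([t0, np.log(t1), np.log(t2 + a)])
        with np.errstate(all="ignore"):
            try:
                sol = optimize.root(
                    fun, phi0, method="hybr", options={"maxfev": max_iter * 4}
                )
            except (ValueError, FloatingPointError):
                continue
        resid = float(np.max(np.abs(sol.fun)))
        th = np.array([sol.x[0], np.exp(sol.x[1]), -a + np.exp(sol.x[2])])
        ok = (
            resid < res_tol
            and th[1] > 1e-8
            and th[2] > -a + 1e-8
            and abs(th[2]) < 1e6 * b
            and np.all(np.isfinite(th))
        )
        if ok:
            best = (th, resid)
            break
    if best is None:
        return ModifiedScoreSolution(
            params=None,
            converged=False,
            admissible=False,
            residual_norm=np.inf,
            n_starts_used=n_used,
            message="no admissible root of the modified score equations found",
        )
    th, resid = best
    return ModifiedScoreSolution(
        params=EmaxParams(float(th[0]), float(th[1]), float(th[2])),
        converged=True,
        admissible=True,
        residual_norm=resid,
        n_starts_used=n_used,
        message="admissible root found",
    )
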