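"""Closed-form MLE for increasing-concave data; limit-class fits otherwise.

For a three-point design with increasing concave sample means the weighted
least-squares problem is solved by exact interpolation of the three points,
giving the MLE in closed form (in the shifted parametrization):

    t0 = ybar1,
    t1 = m1*m2/(m1 - m2) * (x3 - x2),
    t2 = (ybar3 - ybar2)/(m1 - m2).

For any other shape the MLE does not exist: the infimum of the residual sum
is attained only by a pointwise limit of Emax curves - an increasing straight
line, a horizontal line, or a step function at the lowest dose.  The fit
returned in those cases is the dominating limit function itself, together
with a non-existence certificate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import EmaxParams, ShiftedEmaxParams, eta, from_shifted
from .shape import SampleSummary, ShapeLabel, ShapeVerdict, classify

__all__ = ["LimitFit", "FitResult", "mle_shifted", "mle_original", "limit_fit", "fit"]

#: diagnostic threshold: t2 beyond this multiple of the dose range flags a
#: near-boundary fit that is numerically indistinguishable from a limit class
T2_DIAGNOSTIC_FACTOR = 1e6


class MLEDoesNotExistError(ValueError):
    """Raised when the analytic MLE is requested for a shape where none exists."""

    def __init__(self, verdict: ShapeVerdict):
        self.verdict = verdict
        super().__init__(
            f"the MLE does not exist for data of shape {verdict.label.value} "
            f"(m1={verdict.m1:.6g}, m2={verdict.m2:.6g})"
        )


@dataclass(frozen=True)
class LimitFit:
    """A dominating fit from one of the three limit classes.

    class_id 1: increasing straight line m0*x + q0;
    class_id 2: horizontal line at ``level``;
    class_id 3: step function - ``level`` at x = a, ``upper_level`` on (a, b].
    """

    class_id: int
    level: float | None = None
    upper_level: float | None = None
    slope: float | None = None
    intercept: float | None = None

    def predict(self, x, a: float):
        x = np.asarray(x, dtype=float)
        if self.class_id == 1:
            out = self.slope * x + self.intercept
        elif self.class_id == 2:
            out = np.full_like(x, self.level)
        else:
            out = np.where(x <= a, self.level, self.upper_level)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting an Emax model to a three-point summary."""

    method: str  # ANALYTIC_MLE | LIMIT_CLASS | FIRTH
    verdict: ShapeVerdict
    params: EmaxParams | None = None
    shifted: ShiftedEmaxParams | None = None
    limit: LimitFit | None = None
    sse: float = np.nan
    converged: bool = True
    message: str = ""
    t2_near_boundary: bool = False

    def predict(self, x, a: float = 0.0):
        if self.params is not None:
            return eta(x, self.params)
        if self.limit is not None:
            return self.limit.predict(x, a)
        raise ValueError("fit carries no usable estimate")


def _slopes(summary: SampleSummary):
    x, y = summary.x, summary.ybar
    m1 = (y[1] - y[0]) / (x[1] - x[0])
    m2 = (y[2] - y[0]) / (x[2] - x[0])
    return m1, m2


def mle_shifted(summary: SampleSummary) -> ShiftedEmaxParams:
    """Closed-form MLE in the shifted parametrization (x_tilde = x - a).

    Requires increasing-concave data; the returned curve interpolates all
    three (x_i, ybar_i) exactly, so the weighted SSE is zero.
    """
    verdict = classify(summary)
    if verdict.label is not ShapeLabel.INCREASING_CONCAVE:
        raise MLEDoesNotExistError(verdict)
    x, y = summary.x, summary.ybar
    m1, m2 = _slopes(summary)
    t0 = y[0]
    t1 = m1 * m2 / (m1 - m2) * (x[2] - x[1])
    t2 = (y[2] - y[1]) / (m1 - m2)
    return ShiftedEmaxParams(float(t0), float(t1), float(t2))


def mle_original(summary: SampleSummary) -> EmaxParams:
    """Closed-form MLE in the original parametrization theta.

    Algebraically identical to mapping :func:`mle_shifted` back through the
    reparametrization; in particular theta2 = (ybar3 - ybar2)/(m1 - m2) - a.
    """
    shifted = mle_shifted(summary)
    return from_shifted(shifted, summary.design.a)


def limit_fit(summary: SampleSummary) -> LimitFit:
    """Best-fitting limit-class function for Case-1 or Case-2 data.

    Case 1 with ybar1 < ybar23: step function (ybar1 at a, ybar23 above);
    Case 1 with ybar1 >= ybar23 and Case 2 with nonpositive regression
    slope: horizontal line at the overall weighted mean; Case 2 with
    positive slope: the weighted simple linear regression line.
    """
    verdict = classify(summary)
    label = verdict.label
    if label is ShapeLabel.INCREASING_CONCAVE:
        raise ValueError("the MLE exists for increasing-concave data; no limit fit")
    if label is ShapeLabel.CASE1_Y1_BELOW:
        return LimitFit(class_id=3, level=float(summary.ybar[0]), upper_level=verdict.y23)
    if label in (ShapeLabel.CASE1_Y1_ABOVE, ShapeLabel.CASE2_NONPOS_SLOPE):
        return LimitFit(class_id=2, level=verdict.ybar)
    return LimitFit(class_id=1, slope=verdict.m0, intercept=verdict.q0)


def fit(summary: SampleSummary, firth_fallback: bool = True) -> FitResult:
    """Fit dispatcher over the shape classes.

    Increasing-concave data get the analytic MLE (zero SSE).  Case-2 data
    get the Firth-modified score estimate when ``firth_fallback`` is set
    (falling back to the limit-class fit if no admissible root is found).
    Case-1 data get the limit-class fit with a non-existence certificate -
    consider design augmentation (see
    :func:`emaxfit.design.recommend_augmentation`).
    """
    verdict = classify(summary)
    a = summary.design.a
    if verdict.label is ShapeLabel.INCREASING_CONCAVE:
        shifted = mle_shifted(summary)
        params = from_shifted(shifted, a)
        sse = summary.sse(eta(summary.x, params))
        near = shifted.t2 > T2_DIAGNOSTIC_FACTOR * (summary.design.b - a)
        return FitResult(
            method="ANALYTIC_MLE",
            verdict=verdict,
            params=params,
            shifted=shifted,
            sse=sse,
            t2_near_boundary=near,
            message="analytic MLE (exact interpolation)",
        )
    if verdict.label.is_case2 and firth_fallback:
        from .firth import solve_modified_score

        sol = solve_modified_score(summary)
        if sol.admissible:
            sse = summary.sse(eta(summary.x, sol.params))
            return FitResult(
                method="FIRTH",
                verdict=verdict,
                params=sol.params,
                sse=sse,
                message="Firth-modified score estimate (MLE does not exist)",
            )
        lim = limit_fit(summary)
        return FitResult(
            method="LIMIT_CLASS",
            verdict=verdict,
            limit=lim,
            sse=summary.sse(lim.predict(summary.x, a)),
            converged=False,
            message="Firth solver found no admissible root; reporting limit-class fit",
        )
    lim = limit_fit(summary)
    msg = (
        "MLE does not exist (Case 1): consider augmenting the design below x2"
        if verdict.label.is_case1
        else "MLE does not exist (Case 2); limit-class fit reported"
    )
    return FitResult(
        method="LIMIT_CLASS",
        verdict=verdict,
        limit=lim,
        sse=summary.sse(lim.predict(summary.x, a)),
        message=msg,
    )
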