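"""Sufficient statistics and geometric classification of three-point data.

With a Gaussian error of known sigma, the per-dose replicate counts n_i and
sample means ybar_i are sufficient.  The geometry of the three points
(x_i, ybar_i) decides whether the MLE exists:

* increasing concave (ybar1 < ybar2 < ybar3 and chord slope m1 > m2):
  the MLE exists and has a closed form;
* Case 1 - concave but non-increasing: no MLE; the best fit is a step
  function or a flat line (two subcases split by ybar1 vs the pooled mean
  ybar23 of the upper two doses);
* Case 2 - convex (m1 <= m2): no MLE; the best fit is the weighted simple
  linear regression line or a flat line (subcases split by its slope m0).

Each region is also expressed as a linear inequality A ybar < 0, which is
what makes its probability computable by Gaussian integration (see
:mod:`emaxfit.design`).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .model import ThreePointDesign

__all__ = [
    "ShapeLabel",
    "SampleSummary",
    "ShapeVerdict",
    "ConstraintMatrix",
    "summarize",
    "classify",
    "constraint_matrix",
    "weighted_linear_regressor",
]


class ShapeLabel(str, Enum):
    """Mutually exclusive shape classes of the three sample means."""

    INCREASING_CONCAVE = "INCREASING_CONCAVE"
    CASE1_Y1_BELOW = "CASE1_Y1_BELOW"  # concave non-increasing, ybar1 < ybar23
    CASE1_Y1_ABOVE = "CASE1_Y1_ABOVE"  # concave non-increasing, ybar1 >= ybar23
    CASE2_POS_SLOPE = "CASE2_POS_SLOPE"  # convex, regression slope m0 > 0
    CASE2_NONPOS_SLOPE = "CASE2_NONPOS_SLOPE"  # convex, m0 <= 0

    @property
    def is_case1(self) -> bool:
        return self in (ShapeLabel.CASE1_Y1_BELOW, ShapeLabel.CASE1_Y1_ABOVE)

    @property
    def is_case2(self) -> bool:
        return self in (ShapeLabel.CASE2_POS_SLOPE, ShapeLabel.CASE2_NONPOS_SLOPE)


@dataclass(frozen=True)
class SampleSummary:
    """Sufficient statistics: design, replicate counts, per-dose means, sigma."""

    design: ThreePointDesign
    counts: tuple
    means: tuple
    sigma: float

    def __post_init__(self):
        n = np.asarray(self.counts, dtype=float)
        y = np.asarray(self.means, dtype=float)
        if n.shape != (3,) or y.shape != (3,):
            raise ValueError("counts and means must have length 3")
        if np.any(n < 1) or np.any(n != np.round(n)):
            raise ValueError("replicate counts must be positive integers")
        if not np.all(np.isfinite(y)):
            raise ValueError("sample means must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def x(self) -> np.ndarray:
        return self.design.support

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @property
    def ybar(self) -> np.ndarray:
        return np.asarray(self.means, dtype=float)

    def sse(self, fitted) -> float:
        """Weighted residual sum sum_i n_i (ybar_i - fitted_i)^2."""
        f = np.asarray(fitted, dtype=float)
        return float(np.sum(self.n * (self.ybar - f) ** 2))


@dataclass(frozen=True)
class ShapeVerdict:
    """Classification of the data geometry with its diagnostic quantities.

    m1, m2 are the chord slopes from the lowest dose to the middle and
    highest dose; y23 the count-weighted mean of the upper two doses;
    ybar the overall weighted mean; (m0, q0) the weighted simple linear
    regression line (slope, intercept).
    """

    label: ShapeLabel
    m1: float
    m2: float
    y23: float
    ybar: float
    m0: float
    q0: float


@dataclass(frozen=True)
class ConstraintMatrix:
    """Linear-inequality representation A ybar < 0 of one shape region."""

    A: np.ndarray
    region: str


def summarize(raw, design: ThreePointDesign, sigma: float) -> SampleSummary:
    """Group raw (dose, response) records by design support point.

    Every dose must match a support point exactly (within 1e-9 relative);
    each support point must receive at least one response.
    """
    recs = np.asarray(raw, dtype=float)
    if recs.ndim != 2 or recs.shape[1] != 2 or recs.shape[0] == 0:
        raise ValueError("raw data must be a nonempty list of (dose, response)")
    x = design.support
    doses, resp = recs[:, 0], recs[:, 1]
    tol = 1e-9 * max(1.0, design.b)
    idx = np.argmin(np.abs(doses[:, None] - x[None, :]), axis=1)
    if np.any(np.abs(doses - x[idx]) > tol):
        bad = doses[np.abs(doses - x[idx]) > tol][0]
        raise ValueError(f"dose {bad} does not match any design support point")
    counts, means = [], []
    for i in range(3):
        sel = resp[idx == i]
        if sel.size == 0:
            raise ValueError(f"no responses observed at design point x={x[i]}")
        counts.append(int(sel.size))
        means.append(float(sel.mean()))
    return SampleSummary(design, tuple(counts), tuple(means), sigma)


def weighted_linear_regressor(summary: SampleSummary) -> tuple:
    """Slope and intercept minimizing sum_i n_i (ybar_i - m x_i - q)^2."""
    x, y, n = summary.x, summary.ybar, summary.n
    w = n / n.sum()
    xm = np.sum(w * x)
    ym = np.sum(w * y)
    sxx = np.sum(w * (x - xm) ** 2)
    m0 = float(np.sum(w * (x - xm) * (y - ym)) / sxx)
    return m0, float(ym - m0 * xm)


def classify(summary: SampleSummary) -> ShapeVerdict:
    """Classify the three sample means into the shape regions.

    Boundary conventions follow the defining inequalities literally:
    m1 = m2 counts as convex (Case 2), ybar1 = ybar23 as the upper
    Case-1 subcase, m0 = 0 as the nonpositive-slope Case-2 subcase.
    """
    x, y, n = summary.x, summary.ybar, summary.n
    m1 = (y[1] - y[0]) / (x[1] - x[0])
    m2 = (y[2] - y[0]) / (x[2] - x[0])
    y23 = (n[1] * y[1] + n[2] * y[2]) / (n[1] + n[2])
    ybar = float(np.sum(summary.n * y) / summary.n.sum())
    m0, q0 = weighted_linear_regressor(summary)
    if m1 > m2:
        if y[0] < y[1] < y[2]:
            label = ShapeLabel.INCREASING_CONCAVE
        elif y[0] < y23:
            label = ShapeLabel.CASE1_Y1_BELOW
        else:
            label = ShapeLabel.CASE1_Y1_ABOVE
    else:
        label = ShapeLabel.CASE2_POS_SLOPE if m0 > 0 else ShapeLabel.CASE2_NONPOS_SLOPE
    return ShapeVerdict(label, float(m1), float(m2), float(y23), ybar, m0, q0)


def constraint_matrix(region: str, design: ThreePointDesign, counts) -> ConstraintMatrix:
    """Matrix A such that the region is exactly {ybar : A ybar < 0}.

    Regions: ``"exists"`` (increasing concave), ``"case1_below"`` /
    ``"case1_above"`` (the two concave non-increasing subcases) and
    ``"case2"`` (convex; a single row whose event is A ybar <= 0 with the
    *reversed* sign, i.e. the complement row of the concavity constraint).
    """
    x = design.support
    n = np.asarray(counts, dtype=float)
    d21 = x[1] - x[0]
    d31 = x[2] - x[0]
    concave = np.array([1 / d21 - 1 / d31, -1 / d21, 1 / d31])  # row < 0 iff m1 > m2
    w2 = n[1] / (n[1] + n[2])
    w3 = n[2] / (n[1] + n[2])
    if region == "exists":
        A = np.array([concave, [1, -1, 0], [0, 1, -1]])
    elif region == "case1_below":
        A = np.array([concave, [1, -w2, -w3], [0, -1, 1]])
    elif region == "case1_above":
        A = np.array([concave, [-1, w2, w3], [0, -1, 1]])
    elif region == "case2":
        # convex shape is the single event (-concave) . ybar <= 0
        A = -concave[None, :]
    else:
        raise ValueError(f"unknown region tag {region!r}")
    return ConstraintMatrix(A, region)
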