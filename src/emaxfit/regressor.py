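"""scikit-learn style estimator wrapping the Emax fitting pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .estimation import fit as _fit_summary
from .model import ThreePointDesign
from .shape import summarize

__all__ = ["EmaxRegressor"]


class EmaxRegressor(RegressorMixin, BaseEstimator):
    """Emax dose-response regressor for three-point designs.

    Fits the three-parameter Emax mean response
    ``eta(x) = theta0 + theta1 * x / (x + theta2)`` to (dose, response)
    data observed at exactly three distinct doses, with known error
    standard deviation ``sigma``.  Dispatches on the sample-mean geometry:
    analytic MLE when it exists, Firth-modified score estimate for convex
    (Case-2) data when ``firth_fallback`` is set, and the dominating
    limit-class fit otherwise.

    Parameters
    ----------
    sigma : float, default 1.0
        Known error standard deviation.
    a, b : float or None
        Dose-range limits; inferred from the data when None.
    firth_fallback : bool, default True
        Attempt the Firth-modified score solve on Case-2 data.

    Attributes
    ----------
    design_ : ThreePointDesign
    summary_ : SampleSummary
    verdict_ : ShapeVerdict
        Shape classification of the per-dose sample means.
    result_ : FitResult
    method_ : str
        One of ``ANALYTIC_MLE``, ``FIRTH``, ``LIMIT_CLASS``.
    theta_ : ndarray of shape (3,) or None
        (theta0, theta1, theta2); None when only a limit-class fit exists.
    sse_ : float
        Weighted residual sum of squares at the fitted mean function.

    Examples
    --------
    >>> import numpy as np
    >>> from emaxfit import EmaxRegressor
    >>> X = np.repeat([0.0, 30.0, 150.0], 2)
    >>> y = 2 + 0.467 * X / (X + 50)
    >>> reg = EmaxRegressor(sigma=0.1).fit(X, y)
    >>> reg.method_
    'ANALYTIC_MLE'
    >>> np.round(reg.theta_, 3)
    array([ 2.   ,  0.467, 50.   ])
    """

    def __init__(
        self,
        sigma: float = 1.0,
        a: float | None = None,
        b: float | None = None,
        firth_fallback: bool = True,
    ):
        self.sigma = sigma
        self.a = a
        self.b = b
        self.firth_fallback = firth_fallback

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single column of doses")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1-D or a single-column 2-D array")
        if not np.all(np.isfinite(X)) or np.any(X < 0):
            raise ValueError("doses must be finite and nonnegative")
        return X

    def fit(self, X, y):
        """Fit from doses X (n_samples,) or (n_samples, 1) and responses y."""
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape != X.shape:
            raise ValueError("X and y must have the same number of samples")
        doses = np.unique(X)
        if doses.size != 3:
            raise ValueError(
                f"exactly three distinct doses are required, got {doses.size}"
            )
        a = float(doses[0]) if self.a is None else float(self.a)
        b = float(doses[2]) if self.b is None else float(self.b)
        if not (a <= doses[0] and doses[2] <= b):
            raise ValueError("observed doses fall outside [a, b]")
        if a != doses[0] or b != doses[2]:
            raise ValueError("the extreme doses must sit at the range limits a and b")
        design = ThreePointDesign(a, float(doses[1]), b)
        self.summary_ = summarize(np.column_stack([X, y]), design, self.sigma)
        self.design_ = design
        self.result_ = _fit_summary(self.summary_, firth_fallback=self.firth_fallback)
        self.verdict_ = self.result_.verdict
        self.method_ = self.result_.method
        self.theta_ = (
            self.result_.params.as_array() if self.result_.params is not None else None
        )
        self.limit_ = self.result_.limit
        self.sse_ = self.result_.sse
        return self

    def predict(self, X):
        """Fitted mean response at doses X."""
        check_is_fitted(self, "result_")
        X = self._validate_X(X)
        return np.asarray(self.result_.predict(X, a=self.design_.a), dtype=float)
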