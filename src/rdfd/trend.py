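"""Polynomial trend fitting and fatigue-state breakpoints.

Fatigue-degree series traced over a drive follow an S-shaped curve; a cubic
trend captures that shape, and its inflection point ``t* = -b2/(3 b3)``
marks the transition between fatigue states (mild -> moderate -> severe).
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import Polynomial
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["CubicTrendRegressor", "detect_breakpoints"]


class CubicTrendRegressor(RegressorMixin, BaseEstimator):
    """Least-squares polynomial trend in time with ANOVA diagnostics.

    The design is centered and scaled internally (via the ``Polynomial``
    domain mapping) for conditioning; fitted coefficients are reported on
    the original time scale.

    Parameters
    ----------
    degree : int, default 3
        Polynomial degree.  Degree 3 is the model of interest: its single
        inflection point is the fatigue-state breakpoint.

    Attributes
    ----------
    coef_ : ndarray, shape (degree + 1,)
        Coefficients b0..b_degree on the original time scale.
    residual_ss_, total_ss_ : float
        Error and total sums of squares.
    f_statistic_, f_pvalue_ : float
        Overall regression ANOVA F with (degree, n - degree - 1) degrees of
        freedom and its significance; ``nan`` for a constant series.
    inflection_time_ : float or None
        ``-b2/(3 b3)`` when degree is 3, b3 != 0 and the point lies inside
        the fitted span; None otherwise.
    time_span_ : tuple of float
        (min, max) of the fitted times.
    """

    def __init__(self, degree: int = 3):
        self.degree = degree

    # -- construction from known coefficients (reference trend models) ------
    @classmethod
    def from_coefficients(cls, coef, time_span=(0.0, np.inf)) -> "CubicTrendRegressor":
        coef = np.asarray(coef, dtype=float)
        est = cls(degree=coef.size - 1)
        est.coef_ = coef
        est.time_span_ = (float(time_span[0]), float(time_span[1]))
        est.residual_ss_ = est.total_ss_ = np.nan
        est.f_statistic_ = est.f_pvalue_ = np.nan
        est.n_ = 0
        est.inflection_time_ = _inflection(coef, est.time_span_)
        return est

    def fit(self, X, y=None):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.size != y.size:
            raise ValueError("time and value arrays must have equal length")
        n = t.size
        if n < self.degree + 2:
            raise ValueError(
                f"need at least {self.degree + 2} points to fit degree {self.degree}"
            )
        if np.ptp(t) == 0:
            raise ValueError("degenerate design: all times identical")
        self.n_ = n
        self.time_span_ = (float(t.min()), float(t.max()))

        if np.ptp(y) == 0:
            self.coef_ = np.zeros(self.degree + 1)
            self.coef_[0] = y[0]
            self.residual_ss_ = 0.0
            self.total_ss_ = 0.0
            self.f_statistic_ = np.nan
            self.f_pvalue_ = np.nan
            self.inflection_time_ = None
            return self

        poly = Polynomial.fit(t, y, self.degree)
        coef = poly.convert().coef
        self.coef_ = np.pad(coef, (0, self.degree + 1 - coef.size))

        resid = y - poly(t)
        sse = float(resid @ resid)
        sst = float(np.sum((y - y.mean()) ** 2))
        dfm, dfe = self.degree, n - self.degree - 1
        self.residual_ss_ = sse
        self.total_ss_ = sst
        if sse > 0 and dfe > 0:
            self.f_statistic_ = ((sst - sse) / dfm) / (sse / dfe)
            self.f_pvalue_ = float(stats.f.sf(self.f_statistic_, dfm, dfe))
        else:  # perfect fit
            self.f_statistic_ = np.inf
            self.f_pvalue_ = 0.0
        self.inflection_time_ = _inflection(self.coef_, self.time_span_)
        return self

    def predict(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        return np.polynomial.polynomial.polyval(t, self.coef_)


def _inflection(coef, span) -> float | None:
    if coef.size < 4 or coef[3] == 0:
        return None
    t_star = -coef[2] / (3.0 * coef[3])
    if span[0] <= t_star <= span[1]:
        return float(t_star)
    return None


def detect_breakpoints(trend: CubicTrendRegressor, span=None) -> float | None:
    """Fatigue-state breakpoint: the fitted cubic's inflection time.

    Returns ``t* = -b2/(3 b3)`` when the cubic coefficient is nonzero and
    ``t*`` lies inside ``span`` (default: the fitted time span); absence of
    an interior inflection is a valid result and returns None.
    """
    if span is None:
        span = trend.time_span_
    return _inflection(np.asarray(trend.coef_, dtype=float), span)
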