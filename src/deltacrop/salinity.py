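"""Salinity-yield regression and inversion into suitability breakpoints.

Field-trial observations pair topsoil salinity (per mille) with forage fresh
weight. A linear fit y = a + b*x (b < 0 on saline land) is inverted at yield
fractions of the salinity-free maximum (the intercept): solving
a + b*x = f*a gives the salinity x_f = a*(1 - f)/(-b) at which yield drops
to fraction f. Breakpoints at f = 0.75, 0.50, 0.25 delimit four suitability
classes; they are truncated (not rounded) to two decimals for reporting,
matching the convention used to publish them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .spatial import CLASS_LABELS

__all__ = [
    "SalinityYieldModel",
    "SalinityYieldFit",
    "fit_linear",
    "fit_quadratic",
    "thresholds_from_linear",
    "classify_salinity",
    "truncate_2dp",
]

DEFAULT_FRACTIONS = (0.75, 0.50, 0.25)


def truncate_2dp(x: float) -> float:
    """Truncate toward zero to two decimal places (reporting convention)."""
    return math.trunc(x * 100.0) / 100.0


@dataclass
class SalinityYieldFit:
    """Regression coefficients plus derived suitability thresholds."""

    form: str  # "linear" | "quadratic"
    intercept: float
    slope: float
    curvature: float | None
    r_squared: float
    p_value: float
    max_yield: float | None = None
    thresholds: tuple[float, float, float] | None = None

    def predict(self, salinity) -> np.ndarray:
        x = np.asarray(salinity, dtype=float)
        y = self.intercept + self.slope * x
        if self.curvature is not None:
            y = y + self.curvature * x**2
        return y


class SalinityYieldModel(RegressorMixin, BaseEstimator):
    """OLS salinity-yield response, linear (degree 1) or quadratic (degree 2).

    Fitted attributes: ``intercept_``, ``slope_``, ``curvature_`` (quadratic
    only), ``r_squared_``, ``p_value_`` (slope t-test for the line, overall
    F-test for the quadratic), and for the linear form ``max_yield_`` and
    ``thresholds_`` — the salinity breakpoints at the configured yield
    fractions, truncated to 2 decimals.
    """

    def __init__(self, degree: int = 1, fractions: tuple[float, ...] = DEFAULT_FRACTIONS):
        self.degree = degree
        self.fractions = fractions

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        min_n = 2 if self.degree == 1 else 4  # 2 points saturate the line exactly
        if x.size != y.size or x.size < min_n:
            raise ValueError(f"need at least {min_n} paired observations")
        if np.ptp(x) == 0:
            raise np.linalg.LinAlgError("constant predictor: design matrix is rank deficient")

        if self.degree == 1:
            res = stats.linregress(x, y)
            self.intercept_ = float(res.intercept)
            self.slope_ = float(res.slope)
            self.curvature_ = None
            self.r_squared_ = float(res.rvalue**2)
            self.p_value_ = float(res.pvalue)
            self.max_yield_ = self.intercept_
            if self.slope_ < 0 and self.intercept_ > 0:
                self.thresholds_ = thresholds_from_linear(self.intercept_, self.slope_, self.fractions)
            else:
                self.thresholds_ = None
        else:
            design = sm.add_constant(np.column_stack([x, x**2]))
            if np.linalg.matrix_rank(design) < 3:
                raise np.linalg.LinAlgError("rank-deficient quadratic design")
            ols = sm.OLS(y, design).fit()
            self.intercept_, self.slope_, self.curvature_ = (float(c) for c in ols.params)
            self.r_squared_ = float(ols.rsquared)
            self.p_value_ = float(ols.f_pvalue)
            self.max_yield_ = None
            self.thresholds_ = None
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "intercept_")
        return self.to_fit().predict(np.asarray(X, dtype=float).reshape(-1))

    def to_fit(self) -> SalinityYieldFit:
        check_is_fitted(self, "intercept_")
        return SalinityYieldFit(
            form="linear" if self.degree == 1 else "quadratic",
            intercept=self.intercept_,
            slope=self.slope_,
            curvature=self.curvature_,
            r_squared=self.r_squared_,
            p_value=self.p_value_,
            max_yield=self.max_yield_,
            thresholds=self.thresholds_,
        )


def fit_linear(salinity, yields) -> SalinityYieldFit:
    """OLS line through (salinity, yield) trials, with derived thresholds."""
    return SalinityYieldModel(degree=1).fit(salinity, yields).to_fit()


def fit_quadratic(salinity, yields) -> SalinityYieldFit:
    """OLS quadratic through (salinity, yield) trials."""
    return SalinityYieldModel(degree=2).fit(salinity, yields).to_fit()


def thresholds_from_linear(
    intercept: float,
    slope: float,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
) -> tuple[float, ...]:
    """Salinity breakpoints where the fitted line drops to each yield fraction.

    The salinity-free maximum yield is the intercept; solving
    intercept + slope*x = f*intercept gives x = intercept*(1-f)/(-slope).
    Results are truncated to two decimals.
    """
    if slope >= 0:
        raise ValueError("threshold inversion requires a negative slope")
    if intercept <= 0:
        raise ValueError("threshold inversion requires a positive intercept (maximum yield)")
    return tuple(truncate_2dp(intercept * (1.0 - f) / (-slope)) for f in fractions)


def classify_salinity(salinity: float, thresholds: tuple[float, float, float]) -> str:
    """Map a salinity (per mille) to one of the four suitability classes."""
    if salinity < 0:
        raise ValueError("salinity must be nonnegative")
    t = np.asarray(thresholds, dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError("thresholds must be strictly increasing")
    return CLASS_LABELS[int(np.searchsorted(t, salinity, side="left"))]
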