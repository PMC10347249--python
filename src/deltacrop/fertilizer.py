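"""Quadratic fertilizer-response fits and apparent nutrient recovery efficiency.

Yield responds to fertilizer rate with diminishing returns; a concave
quadratic Y = b0 + b1*X + b2*X^2 (b2 < 0) summarizes the response. From the
fit: the control yield b0 (no fertilizer), the rate at maximum yield
X* = -b1/(2*b2), and the maximum yield Y(X*) = b0 - b1^2/(4*b2).

Apparent recovery efficiency RE = 100 * (U - U0) / F is the increase in
above-ground nutrient uptake per unit of nutrient applied, where uptake is
grain and straw mass times their nutrient content fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ResponseFit",
    "FertilizerResponseModel",
    "fit_response",
    "nutrient_uptake",
    "recovery_efficiency",
    "yield_with_fertilizer",
    "DEFAULT_NUTRIENT_CONTENT",
]

# Literature-typical above-ground N/P2O5/K2O content fractions of cereal grain
# and straw dry matter; exposed so analyses can configure measured values.
DEFAULT_NUTRIENT_CONTENT = {
    "N": {"grain": 0.0220, "straw": 0.0060},
    "P2O5": {"grain": 0.0080, "straw": 0.0018},
    "K2O": {"grain": 0.0050, "straw": 0.0150},
}


@dataclass
class ResponseFit:
    """Quadratic response coefficients and derived agronomic quantities."""

    b0: float
    b1: float
    b2: float
    r_squared: float
    p_value: float
    x_at_max: float | None
    y_max: float | None
    concave: bool

    def predict(self, rates) -> np.ndarray:
        x = np.asarray(rates, dtype=float)
        return self.b0 + self.b1 * x + self.b2 * x**2


class FertilizerResponseModel(RegressorMixin, BaseEstimator):
    """OLS quadratic yield response to fertilizer rate.

    Fitted attributes: ``b0_``, ``b1_``, ``b2_``, ``r_squared_``,
    ``p_value_`` (overall F-test), ``x_at_max_`` and ``y_max_`` (vertex;
    None with a warning when the fit is not concave).
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size or x.size < 4:
            raise ValueError("need at least 4 paired (rate, yield) points")
        design = sm.add_constant(np.column_stack([x, x**2]))
        if np.linalg.matrix_rank(design) < 3:
            raise np.linalg.LinAlgError("rank-deficient design: rates must take >= 3 distinct values")
        ols = sm.OLS(y, design).fit()
        self.b0_, self.b1_, self.b2_ = (float(c) for c in ols.params)
        self.r_squared_ = float(ols.rsquared)
        self.p_value_ = float(ols.f_pvalue) if not np.isnan(ols.f_pvalue) else 1.0
        self.concave_ = self.b2_ < 0
        if self.concave_:
            self.x_at_max_ = -self.b1_ / (2.0 * self.b2_)
            self.y_max_ = self.b0_ - self.b1_**2 / (4.0 * self.b2_)
        else:
            warnings.warn(
                "fertilizer response is not concave (b2 >= 0); no interior maximum",
                UserWarning,
                stacklevel=2,
            )
            self.x_at_max_ = None
            self.y_max_ = None
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "b0_")
        return self.to_fit().predict(np.asarray(X, dtype=float).reshape(-1))

    def to_fit(self) -> ResponseFit:
        check_is_fitted(self, "b0_")
        return ResponseFit(
            b0=self.b0_,
            b1=self.b1_,
            b2=self.b2_,
            r_squared=self.r_squared_,
            p_value=self.p_value_,
            x_at_max=self.x_at_max_,
            y_max=self.y_max_,
            concave=self.concave_,
        )


def fit_response(rates, yields) -> ResponseFit:
    """Fit the quadratic fertilizer-response curve by OLS."""
    return FertilizerResponseModel().fit(rates, yields).to_fit()


def nutrient_uptake(yield_grain: float, yield_straw: float, c_grain: float, c_straw: float) -> float:
    """Above-ground nutrient uptake = grain*c_grain + straw*c_straw (mass/area)."""
    if yield_grain < 0 or yield_straw < 0:
        raise ValueError("yields must be nonnegative")
    for c in (c_grain, c_straw):
        if not 0.0 <= c <= 1.0:
            raise ValueError("nutrient content fractions must lie in [0, 1]")
    return yield_grain * c_grain + yield_straw * c_straw


def recovery_efficiency(u: float, u0: float, f: float) -> float:
    """Apparent recovery efficiency RE = 100 * (U - U0) / F, in percent.

    Negative values (fertilized uptake below the control) are returned with
    a warning rather than suppressed: small survey samples make them real.
    """
    if f <= 0:
        raise ValueError("fertilizer input F must be positive")
    if u < 0 or u0 < 0:
        raise ValueError("uptakes must be nonnegative")
    re = 100.0 * (u - u0) / f
    if re < 0:
        warnings.warn(f"negative apparent recovery efficiency ({re:.2f}%)", UserWarning, stacklevel=2)
    return re


def yield_with_fertilizer(current_yield: float, previous_yield: float, control_yield: float) -> float:
    """Fertilizer-attributable yield: mean of current and previous year minus control."""
    for v in (current_yield, previous_yield, control_yield):
        if v < 0:
            raise ValueError("yields must be nonnegative")
    dy = 0.5 * (current_yield + previous_yield) - control_yield
    if dy < 0:
        warnings.warn(f"yield with fertilizer is negative ({dy:.3f})", UserWarning, stacklevel=2)
    return dy
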