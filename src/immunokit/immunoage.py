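"""Quadratic age-response calibration and inverse "immunological response age".

A second-order polynomial response = a + b*age + c*age^2 is fitted by ordinary
least squares to a calibration cohort (e.g. vaccine-induced tetramer+ CD8
frequencies across ages), giving residual degrees of freedom n - 3, an R^2,
and pointwise 95% confidence bands for the fitted mean. Inverting the curve
maps a treated animal's observed response to the calibration age at which that
response would be expected - its immunological vaccination response age.
Group differences in estimated ages are compared with a two-tailed unpaired
Student's t-test (pooled variance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AgeResponseCurve",
    "ImmunoAgeEstimate",
    "fit_quadratic",
    "predict_band",
    "invert_age",
    "compare_groups",
    "QuadraticCalibration",
]


@dataclass
class ImmunoAgeEstimate:
    animal_id: str
    response: float
    estimated_age: float  # weeks; NaN when out of range
    root_status: str  # unique | selected | out_of_range
    group: str = ""


@dataclass
class GroupComparison:
    t: float
    p: float
    df: int
    degenerate: bool = False  # zero pooled variance with unequal means


def _design(ages: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(ages), ages, ages**2])


class QuadraticCalibration:
    """OLS quadratic calibration model for an age-response cohort."""

    def __init__(self, ages: Sequence[float], responses: Sequence[float]):
        self.ages = np.asarray(ages, dtype=float)
        self.responses = np.asarray(responses, dtype=float)
        if len(self.ages) != len(self.responses):
            raise ValueError("ages and responses must have equal length")
        if len(self.ages) < 4:
            raise ValueError("need >= 4 observations to fit a quadratic with df >= 1")
        if len(np.unique(self.ages)) < 3:
            raise ValueError("need >= 3 distinct ages (rank-deficient design)")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, age_col: str = "age", response_col: str = "response"
    ) -> "QuadraticCalibration":
        return cls(df[age_col].to_numpy(), df[response_col].to_numpy())

    def fit(self) -> "AgeResponseCurve":
        X = _design(self.ages)
        res = sm.OLS(self.responses, X).fit()
        return AgeResponseCurve(self, res)


class AgeResponseCurve:
    """Fitted quadratic calibration curve (Results object).

    Attributes
    ----------
    coeffs : (a, b, c) with response = a + b*age + c*age^2
    cov : 3x3 coefficient covariance
    df : residual degrees of freedom, n - 3
    rsquared : coefficient of determination
    age_range : (min, max) of the calibration ages
    """

    def __init__(self, model: QuadraticCalibration, res):
        self.model = model
        self._res = res
        self.coeffs = tuple(float(v) for v in res.params)
        self.cov = np.asarray(res.cov_params())
        self.df = int(res.df_resid)
        self.rsquared = float(res.rsquared)
        self.resid_var = float(res.mse_resid)
        self.n = int(res.nobs)
        self.age_range = (float(self.model.ages.min()), float(self.model.ages.max()))

    def predict(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        a, b, c = self.coeffs
        return a + b * age + c * age**2

    def predict_band(self, age, level: float = 0.95):
        """Fitted mean with pointwise confidence band at ``level``.

        Returns (mean, lower, upper); band = mean +/- t_{df,1-alpha/2} *
        sqrt(x0' Cov x0) from the coefficient covariance.
        """
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        age = np.atleast_1d(np.asarray(age, dtype=float))
        if not np.all(np.isfinite(age)):
            raise ValueError("age must be finite")
        x0 = _design(age)
        mean = x0 @ np.asarray(self.coeffs)
        se = np.sqrt(np.einsum("ij,jk,ik->i", x0, self.cov, x0))
        tcrit = stats.t.ppf(0.5 + level / 2, self.df)
        return mean, mean - tcrit * se, mean + tcrit * se

    def invert(
        self,
        response: float,
        extrapolation_margin: float = 0.0,
        animal_id: str = "",
        group: str = "",
    ) -> ImmunoAgeEstimate:
        """Inverse prediction: the calibration age at which the fitted mean
        equals ``response``.

        Solves c*age^2 + b*age + (a - response) = 0 and keeps real roots in
        [age_min - margin, age_max + margin]. With two valid roots, the root
        on the monotone branch covering the majority of calibration ages is
        selected. No silent extrapolation: out-of-range responses are flagged.
        """
        a, b, c = self.coeffs
        lo = self.age_range[0] - extrapolation_margin
        hi = self.age_range[1] + extrapolation_margin
        if c == 0:
            roots = np.array([]) if b == 0 else np.array([(response - a) / b])
        else:
            disc = b * b - 4 * c * (a - response)
            if disc < 0:
                roots = np.array([])
            else:
                sq = np.sqrt(disc)
                roots = np.array([(-b - sq) / (2 * c), (-b + sq) / (2 * c)])
        # tolerance keeps roots that land on the range boundary up to
        # floating-point error (e.g. inverting the youngest calibration age)
        tol = 1e-9 * max(1.0, abs(hi - lo))
        valid = np.unique(
            np.clip(roots[(roots >= lo - tol) & (roots <= hi + tol)], lo, hi)
        )
        if valid.size == 0:
            return ImmunoAgeEstimate(animal_id, float(response), float("nan"),
                                     "out_of_range", group)
        if valid.size == 1:
            return ImmunoAgeEstimate(animal_id, float(response), float(valid[0]),
                                     "unique", group)
        # Two in-range roots straddle the vertex: pick the monotone branch
        # holding the majority of calibration ages.
        vertex = -b / (2 * c)
        frac_right = float(np.mean(self.model.ages >= vertex))
        chosen = max(valid) if frac_right >= 0.5 else min(valid)
        return ImmunoAgeEstimate(animal_id, float(response), float(chosen),
                                 "selected", group)

    def summary(self) -> str:
        a, b, c = self.coeffs
        lines = [
            "Quadratic age-response calibration (OLS)",
            f"  n = {self.n}, residual d.f. = {self.df}, R^2 = {self.rsquared:.4f}",
            f"  response = {a:.4g} + {b:.4g}*age + {c:.4g}*age^2",
            f"  calibration age range: {self.age_range[0]:g}-"
            f"{self.age_range[1]:g} weeks",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, level: float = 0.95):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(*self.age_range, 200)
        mean, lower, upper = self.predict_band(grid, level)
        ax.scatter(self.model.ages, self.model.responses, s=14, color="k", zorder=3)
        ax.plot(grid, mean, color="C0")
        ax.fill_between(grid, lower, upper, alpha=0.25, color="C0")
        ax.set_xlabel("age (weeks)")
        ax.set_ylabel("response")
        return ax


def fit_quadratic(ages, responses) -> AgeResponseCurve:
    """Functional form of QuadraticCalibration(...).fit()."""
    return QuadraticCalibration(ages, responses).fit()


def predict_band(curve: AgeResponseCurve, age, level: float = 0.95):
    return curve.predict_band(age, level)


def invert_age(
    curve: AgeResponseCurve, response: float, extrapolation_margin: float = 0.0, **kw
) -> ImmunoAgeEstimate:
    return curve.invert(response, extrapolation_margin, **kw)


def compare_groups(ages1: Sequence[float], ages2: Sequence[float]) -> GroupComparison:
    """Two-sample pooled-variance Student's t-test (two-tailed).

    Degenerate zero-variance inputs are handled explicitly: equal means give
    t = 0, p = 1; unequal means give the p -> 0 limit with a flag.
    """
    x = np.asarray(ages1, dtype=float)
    y = np.asarray(ages2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 animals per group")
    df = len(x) + len(y) - 2
    sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return GroupComparison(t=0.0, p=1.0, df=df)
        return GroupComparison(
            t=float(np.inf) * np.sign(x.mean() - y.mean()), p=0.0, df=df,
            degenerate=True,
        )
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return GroupComparison(t=float(t), p=float(p), df=df)
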