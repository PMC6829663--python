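"""Condition-level aggregation and statistical comparisons.

A thin reporting layer over scipy/statsmodels: per-cell values are
summarized as mean ± SEM, conditions are compared with two-tailed
(paired or unpaired) t tests, linear trends with ordinary least
squares, and multi-group designs with a two-way ANOVA plus Tukey HSD
delegated to statsmodels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConditionSummary",
    "TestReport",
    "LinearTrend",
    "compare_conditions",
    "fit_linear_trend",
    "two_way_anova",
    "tukey_hsd",
]


@dataclass
class ConditionSummary:
    """Per-cell values for one experimental condition."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.size < 1:
            raise ValueError("a condition needs at least one value")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sem(self) -> float:
        if self.n < 2:
            return float("nan")
        return float(self.values.std(ddof=1) / math.sqrt(self.n))


@dataclass
class TestReport:
    design: str
    t: float
    p: float
    percent_change: float        # (mean_a - mean_b) / mean_a * 100
    percent_change_sem: float
    significant: bool
    alpha: float = 0.05

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def compare_conditions(
    a: ConditionSummary,
    b: ConditionSummary,
    design: str = "unpaired",
    alpha: float = 0.05,
) -> TestReport:
    """Two-tailed Student's t test between two conditions.

    Also reports the percent change of means relative to condition ``a``
    ("X% reduction" convention) with its propagated SEM.  Identical
    groups give t = 0, p = 1; two groups that are each constant but
    different are an error (zero variance, no test possible).
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("need n >= 2 per group")
    va, vb = a.values, b.values
    if design == "paired":
        if a.n != b.n:
            raise ValueError("paired design needs equal group sizes")
        diff = va - vb
        if np.allclose(diff.std(ddof=1), 0.0):
            if abs(diff.mean()) > 0:
                # perfectly consistent nonzero difference: the t -> inf limit
                t, p = math.copysign(math.inf, diff.mean()), 0.0
            else:
                t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(va, vb)
    elif design == "unpaired":
        if va.std(ddof=1) == 0.0 and vb.std(ddof=1) == 0.0:
            if a.mean != b.mean:
                raise ValueError("zero variance in both groups")
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(va, vb)
    else:
        raise ValueError("design must be 'paired' or 'unpaired'")

    if a.mean == 0:
        pct, pct_sem = float("nan"), float("nan")
    else:
        pct = (a.mean - b.mean) / a.mean * 100.0
        # first-order error propagation of (1 - mb/ma) * 100
        pct_sem = 100.0 / abs(a.mean) * math.sqrt(
            b.sem**2 + (b.mean * a.sem / a.mean) ** 2)
    return TestReport(design, float(t), float(p), pct, pct_sem,
                      bool(p < alpha), alpha)


@dataclass
class LinearTrend:
    slope: float
    intercept: float
    r_squared: float
    p_value: float               # slope-nonzero, two-tailed


def fit_linear_trend(x: np.ndarray, y: np.ndarray) -> LinearTrend:
    """Ordinary least squares y = slope * x + intercept with R^2 and
    the two-tailed p value for a nonzero slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return LinearTrend(float(res.slope), float(res.intercept),
                       float(res.rvalue**2), float(res.pvalue))


def two_way_anova(
    df: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
) -> pd.DataFrame:
    """Two-way ANOVA with interaction, delegated to statsmodels (type-II
    sums of squares).  Returns the ANOVA table as a DataFrame."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    formula = f"{response} ~ C({factor_a}) * C({factor_b})"
    model = smf.ols(formula, data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def tukey_hsd(df: pd.DataFrame, response: str, group: str, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons, delegated to statsmodels."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(df[response], df[group], alpha=alpha)
    table = res.summary()
    return pd.DataFrame(table.data[1:], columns=table.data[0])
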