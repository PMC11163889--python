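"""Cohort-level statistics: stratification, LOESS growth curves, trend
regression, sex comparisons, percent-change summaries and two-way ICC.

The analysis conventions follow pediatric spine morphometry practice:
spinal levels are grouped upper-thoracic (T1-T4), mid-thoracic (T5-T8),
low-thoracic (T9-T12) and lumbar (L1-L5); ages into the Scoliosis
Research Society groups infantile (0-3), juvenile (4-10) and adolescent
(11-18), applied to whole (floored) years.  "Percent increase" of a
growth curve is reported as final value as a percentage of the initial
value (a flat curve is 100%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .growth import level_group_of

AGE_GROUPS = (("infantile", 0, 3), ("juvenile", 4, 10), ("adolescent", 11, 18))


def age_group_of(age_years: float) -> str:
    if not 0 <= age_years <= 18:
        raise ValueError(f"age {age_years} outside [0, 18]")
    whole = int(np.floor(age_years))
    for name, lo, hi in AGE_GROUPS:
        if lo <= whole <= hi:
            return name
    raise AssertionError("unreachable")


def stratify(records: pd.DataFrame,
             ages: pd.Series | None = None,
             sexes: pd.Series | None = None) -> pd.DataFrame:
    """Attach level_group and age_group columns to per-disk records.

    ``records`` needs ``level_index`` plus either ``age_years``/``sex``
    columns or separate ``ages``/``sexes`` Series indexed by ``scan_id``.
    Assignment is total and deterministic.
    """
    out = records.copy()
    if ages is not None:
        out["age_years"] = out["scan_id"].map(ages)
    if sexes is not None:
        out["sex"] = out["scan_id"].map(sexes)
    for col in ("level_index", "age_years", "sex"):
        if col not in out.columns:
            raise ValueError(f"records lack column {col!r}")
    out["level_group"] = out["level_index"].map(level_group_of)
    out["age_group"] = out["age_years"].map(age_group_of)
    return out


@dataclass
class LoessFit:
    """Tricube-weighted local polynomial fit (LOESS).

    For each query point the span*n nearest neighbours (inclusive of
    ties) are weighted by (1 - (d/d_max)^3)^3 and a degree-``degree``
    polynomial is fitted by weighted least squares.  A window covering
    the whole sample uses uniform weights, so span=1, degree=1 reduces
    to the ordinary least-squares line.
    """

    x: np.ndarray
    y: np.ndarray
    span: float = 0.75
    degree: int = 1
    query: np.ndarray | None = None
    fitted: np.ndarray = field(init=False)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1D arrays")
        if not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if len(self.x) < self.degree + 2:
            raise ValueError(f"need at least degree+2={self.degree + 2} points")
        if self.query is None:
            self.query = np.unique(self.x)
        else:
            self.query = np.asarray(self.query, dtype=float)
        self.fitted = self.predict(self.query)
        if not np.all(np.isfinite(self.fitted)):
            raise ValueError("LOESS produced non-finite fitted values")

    def predict(self, points) -> np.ndarray:
        points = np.atleast_1d(np.asarray(points, dtype=float))
        n = len(self.x)
        q = max(self.degree + 1, int(np.ceil(self.span * n)))
        out = np.empty(len(points))
        for i, x0 in enumerate(points):
            d = np.abs(self.x - x0)
            if q >= n:
                w = np.ones(n)
            else:
                dq = np.partition(d, q - 1)[q - 1]
                in_win = d <= dq          # inclusive: duplicate-x ties enter
                w = np.zeros(n)
                if dq == 0:               # all in-window points at x0
                    w[in_win] = 1.0
                else:
                    w[in_win] = (1 - (d[in_win] / dq) ** 3) ** 3
                    w[in_win] = np.maximum(w[in_win], 1e-12)
            sw = np.sqrt(w[w > 0])
            xs, ys = self.x[w > 0] - x0, self.y[w > 0]
            X = np.vander(xs, self.degree + 1, increasing=True)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], ys * sw, rcond=None)
            out[i] = beta[0]
        return out

    def __call__(self, points):
        return self.predict(points)


def loess_fit(x, y, span: float = 0.75, degree: int = 1, query=None) -> LoessFit:
    return LoessFit(x=x, y=y, span=span, degree=degree, query=query)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    model: str = "two-way random, absolute agreement, single measure (ICC2,1)"

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.icc <= hi):
            raise ValueError("CI bounds must bracket the estimate")


def icc_two_way(measurements: np.ndarray, kind: str = "absolute_single",
                alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``measurements`` is an n_items x k_raters matrix (e.g. one row per
    segmented structure, one column per operator or session).  The
    estimate comes from the standard two-way ANOVA mean squares and the
    confidence interval from the usual F-distribution bounds.
    """
    if kind != "absolute_single":
        raise ValueError(f"unsupported ICC kind {kind!r}")
    X = np.asarray(measurements, dtype=float)
    if X.ndim != 2:
        raise ValueError("measurements must be a 2D matrix")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 items and 2 raters")
    if not np.all(np.isfinite(X)):
        raise ValueError("measurements contain non-finite values")
    grand = X.mean()
    if np.allclose(X, grand):
        raise ValueError("zero total variance; ICC undefined")
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = X - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom

    if mse <= 1e-12 * max(msr, 1.0) and msc <= 1e-12 * max(msr, 1.0):
        return ICCResult(icc=float(icc), ci95=(float(icc), float(icc)))

    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return ICCResult(icc=float(icc), ci95=(float(icc), float(icc)))
    v = ((a * msc + b * mse) ** 2
         / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    lower, upper = float(min(lower, icc)), float(max(upper, icc))
    return ICCResult(icc=float(icc), ci95=(lower, upper))


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test; returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    slope_se: float
    p_value: float
    sex_coef: float | None = None
    sex_p: float | None = None


def trend_fit(table: pd.DataFrame, outcome: str,
              adjust_for_sex: bool = False) -> TrendResult:
    """OLS trend of an outcome on age (optionally sex-adjusted).

    Age trends in disk morphology are tested with ordinary least squares
    of the outcome on age in years; with ``adjust_for_sex`` a male
    indicator enters as a covariate and its coefficient is reported.
    """
    df = table.dropna(subset=[outcome, "age_years"])
    age = df["age_years"].to_numpy(dtype=float)
    if len(df) < 3 or np.ptp(age) == 0:
        raise ValueError("need >= 3 rows and non-constant age")
    X = age[:, None]
    names = ["age_years"]
    if adjust_for_sex:
        X = np.column_stack([X, (df["sex"] == "M").astype(float)])
        names.append("sex_M")
    model = sm.OLS(df[outcome].to_numpy(dtype=float), sm.add_constant(X)).fit()
    res = TrendResult(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        slope_se=float(model.bse[1]), p_value=float(model.pvalues[1]),
        sex_coef=float(model.params[2]) if adjust_for_sex else None,
        sex_p=float(model.pvalues[2]) if adjust_for_sex else None,
    )
    return res


def percent_change(fit: LoessFit, age0: float = 0.0, age1: float = 18.0) -> float:
    """Final value as percent of initial: 100 * fit(age1) / fit(age0).

    A curve growing from 100 to 460 reports 460% (i.e. x4.6); a flat
    curve reports 100%.  This matches the convention of quoting growth
    "increase" as the end-of-growth value relative to birth.
    """
    v0, v1 = fit.predict([age0, age1])
    if v0 <= 0:
        raise ValueError("fit at the initial age is non-positive")
    return float(100.0 * v1 / v0)
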