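"""Dyad-level environmental and demographic covariates of strain sharing.

Simple predictors computed per sample dyad — diet dissimilarity between the
hosts' (group-aggregated) diet compositions, circular distance between
sampling months, total rainfall in the sampling months, years between
samples, host age difference — and ordinary least-squares models relating
each predictor to the dyad's strain-sharing rate.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import distance as ssd


def diet_dissimilarity(
    comp_a: Sequence[float],
    comp_b: Sequence[float],
    metric: str = "bray_curtis",
) -> float:
    """Dissimilarity between two non-negative diet-composition vectors.

    ``bray_curtis`` is the quantitative Bray-Curtis dissimilarity;
    ``jaccard`` is 1 minus the Jaccard similarity of the presence/absence
    supports (invariant to abundance rescaling).
    """
    a = np.asarray(comp_a, dtype=float)
    b = np.asarray(comp_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("diet vectors must be one-dimensional and equal-length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("diet compositions must be non-negative")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("both diet vectors are all-zero")
    if metric == "bray_curtis":
        return float(ssd.braycurtis(a, b))
    if metric == "jaccard":
        pa, pb = a > 0, b > 0
        union = np.count_nonzero(pa | pb)
        inter = np.count_nonzero(pa & pb)
        return 1.0 - inter / union
    raise ValueError("metric must be 'bray_curtis' or 'jaccard'")


def month_distance(m1: int, m2: int) -> int:
    """Minimum circular distance between calendar months (1-12), so December
    and January are 1 apart and the maximum is 6."""
    for m in (m1, m2):
        if not 1 <= m <= 12:
            raise ValueError(f"month {m} outside 1-12")
    d = abs(m1 - m2)
    return min(d, 12 - d)


def monthly_rainfall(daily_rain: pd.Series) -> pd.Series:
    """Sum a dated daily rainfall series (mm) by calendar month."""
    s = pd.Series(daily_rain)
    idx = pd.DatetimeIndex(s.index)
    return s.groupby(idx.to_period("M")).sum()


def rainfall_covariate(
    daily_rain: pd.Series,
    date_a: dt.date,
    date_b: dt.date,
    mode: str = "sum_both_months",
) -> float:
    """Rainfall covariate for a dyad: the monthly rainfall totals of the two
    samples' collection months, combined by sum (default) or mean. Months
    absent from the series raise an error (the two totals are summed even if
    the samples fall in the same calendar month)."""
    monthly = monthly_rainfall(daily_rain)
    totals = []
    for d in (date_a, date_b):
        period = pd.Period(d, freq="M")
        if period not in monthly.index:
            raise ValueError(f"rainfall series does not cover {period}")
        totals.append(float(monthly[period]))
    if mode == "sum_both_months":
        return float(sum(totals))
    if mode == "mean_both_months":
        return float(np.mean(totals))
    raise ValueError("mode must be 'sum_both_months' or 'mean_both_months'")


@dataclasses.dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    stderr: float
    df: int
    p_value: float
    n: int


def fit_simple_regression(
    x: Sequence[float], y: Sequence[float]
) -> RegressionFit:
    """OLS of a sharing-rate response on a single predictor.

    Returns the slope, its two-sided t-test p-value and the residual degrees
    of freedom (n - 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        stderr=float(model.bse[1]),
        df=int(model.df_resid),
        p_value=float(model.pvalues[1]),
        n=int(x.size),
    )


def aggregate_diet(diet: pd.DataFrame) -> dict[tuple[str, int], pd.Series]:
    """Aggregate long-form diet observations to (social group, year) vectors.

    ``diet`` columns: group, year, food_type, proportion. Proportions are
    summed per (group, year, food) and aligned on the full food vocabulary.
    """
    required = {"group", "year", "food_type", "proportion"}
    if not required.issubset(diet.columns):
        raise ValueError(f"diet table needs columns {sorted(required)}")
    foods = sorted(diet["food_type"].unique())
    out: dict[tuple[str, int], pd.Series] = {}
    for (group, year), g in diet.groupby(["group", "year"]):
        vec = g.groupby("food_type")["proportion"].sum()
        out[(str(group), int(year))] = vec.reindex(foods, fill_value=0.0)
    return out


def covariate_report(
    covariates: pd.DataFrame,
    response: str = "sharing_rate",
    predictors: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fit one simple regression per predictor column against the response.

    Rows with a missing response or predictor are dropped per fit; constant
    predictors are reported as not computable.
    """
    if predictors is None:
        predictors = [c for c in covariates.columns if c != response]
    rows = []
    for pred in predictors:
        sub = covariates[[pred, response]].dropna()
        try:
            fit = fit_simple_regression(sub[pred], sub[response])
            rows.append(
                {
                    "predictor": pred,
                    "slope": fit.slope,
                    "stderr": fit.stderr,
                    "df": fit.df,
                    "p_value": fit.p_value,
                    "n": fit.n,
                    "computable": True,
                }
            )
        except ValueError:
            rows.append(
                {
                    "predictor": pred,
                    "slope": np.nan,
                    "stderr": np.nan,
                    "df": 0,
                    "p_value": np.nan,
                    "n": len(sub),
                    "computable": False,
                }
            )
    return pd.DataFrame(rows)
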