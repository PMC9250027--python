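"""Descriptive statistics for organoid timelines.

Covers the simple inference used on cell-count-versus-age scatter data
and aggregate-type composition summaries: Pearson correlation with a
two-sided p via the t transform, an ordinary-least-squares trend line
with a pointwise confidence band, and per-category mean percentages with
the standard error of the mean across differentiations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataSufficiencyError, DegenerateInputError, RangeError, UsageError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimelineDataset:
    """Paired (age, response) observations, e.g. weeks vs cell counts."""

    x: np.ndarray
    y: np.ndarray
    x_label: str = "age_weeks"
    y_label: str = "count"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise UsageError("x and y must be 1-D arrays of equal length")
        if not np.isfinite(x).all() or not np.isfinite(y).all():
            raise UsageError("timeline coordinates must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its square and the two-sided p from the t transform."""

    r: float
    r_squared: float
    p_two_sided: float
    n: int


@dataclass(frozen=True)
class TrendResult:
    """OLS fit with a pointwise confidence band at the fitted x values."""

    slope: float
    intercept: float
    level: float
    x: np.ndarray
    fitted: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray


def pearson_corr(data: TimelineDataset) -> CorrelationResult:
    """Product-moment correlation with two-sided p.

    The p-value follows from t = r * sqrt(n-2) / sqrt(1-r^2) on n-2
    degrees of freedom, the standard test for zero correlation.
    """
    n = len(data)
    if n < 3:
        raise DataSufficiencyError(f"need >= 3 points for a correlation, got {n}")
    if np.std(data.x) == 0 or np.std(data.y) == 0:
        raise DegenerateInputError("zero variance in x or y; correlation undefined")
    r, p = stats.pearsonr(data.x, data.y)
    return CorrelationResult(r=float(r), r_squared=float(r) ** 2, p_two_sided=float(p), n=n)


def coefficient_of_determination(r: float) -> float:
    """R^2 from a correlation coefficient r in [-1, 1]."""
    if abs(r) > 1.0:
        raise RangeError(f"|r| must be <= 1, got {r}")
    return float(r) ** 2


def linear_trend(data: TimelineDataset, level: float = 0.95) -> TrendResult:
    """OLS trend line with a pointwise t-based confidence band for the mean."""
    if len(data) < 3:
        raise DataSufficiencyError("need >= 3 points for a trend fit")
    if not 0.0 < level < 1.0:
        raise RangeError(f"confidence level must be in (0, 1), got {level}")
    if np.std(data.x) == 0:
        raise DegenerateInputError("all x identical; trend undefined")
    X = sm.add_constant(data.x)
    fit = sm.OLS(data.y, X).fit()
    pred = fit.get_prediction(X)
    band = pred.conf_int(alpha=1.0 - level)
    return TrendResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        level=level,
        x=data.x.copy(),
        fitted=np.asarray(pred.predicted_mean, dtype=float),
        band_low=np.asarray(band[:, 0], dtype=float),
        band_high=np.asarray(band[:, 1], dtype=float),
    )


def summarize_proportions(
    observations: list[tuple[str, str]],
) -> pd.DataFrame:
    """Per-category mean percentage with SEM across units.

    `observations` pairs a unit id (one differentiation) with an observed
    category (one aggregate). Within each unit, category counts become
    percentages summing to 100; across units each category gets the mean
    percentage and the SEM (sample sd / sqrt(#units); reported as NaN for
    a single unit). Categories unobserved in a unit count as 0% there.
    """
    if not observations:
        raise UsageError("no observations to summarize")
    frame = pd.DataFrame(observations, columns=["unit", "category"])
    counts = frame.groupby(["unit", "category"]).size().unstack(fill_value=0)
    percentages = counts.div(counts.sum(axis=1), axis=0) * 100.0
    n_units = percentages.shape[0]
    mean = percentages.mean(axis=0)
    if n_units > 1:
        sem = percentages.std(axis=0, ddof=1) / np.sqrt(n_units)
    else:
        sem = pd.Series(np.nan, index=mean.index)
    out = pd.DataFrame(
        {"mean_pct": mean, "sem": sem, "n_units": n_units}
    )
    out.index.name = "category"
    return out.sort_index()
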