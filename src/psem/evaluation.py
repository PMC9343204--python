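"""Forecast evaluation: RMSE hold-out error and a Welch two-sample t-test.

Two forecast series for the same decade are compared by an
unequal-variance (Welch) t-test on their ten annual values, with the
Welch-Satterthwaite degrees of freedom floored to an integer before the
p-value and confidence interval are read off the t distribution.  Flooring
matches the reporting convention of classical statistics packages
(Minitab-style): with two samples of ten, fractional df 17.98 is reported
as 17.

RMSE between a predicted and an observed annual series is the usual
root-mean-square of the per-year differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats

from .core import round_half_up
from .forecasting import AnnualSeries

__all__ = [
    "SeriesSummary",
    "TTestResult",
    "ForecastEvaluation",
    "rmse",
    "summarize",
    "welch_t_test",
    "welch_t_test_values",
    "format_ttest_report",
]


@dataclass(frozen=True)
class SeriesSummary:
    """Sample size, mean, sample SD (n-1 denominator) and SE of a series."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"summary requires n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    @property
    def se(self) -> float:
        return self.sd / math.sqrt(self.n)


@dataclass(frozen=True)
class TTestResult:
    """Welch test summary: statistic, floored df, p, difference and CI."""

    t: float
    df: int
    p: float
    diff: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if not self.ci_low <= self.diff <= self.ci_high:
            raise ValueError("confidence interval must bracket the difference")


@dataclass(frozen=True)
class ForecastEvaluation:
    """Predicted vs observed annual series with their RMSE."""

    predicted: AnnualSeries
    observed: AnnualSeries
    n: int
    rmse: float

    @classmethod
    def evaluate(
        cls, predicted: AnnualSeries, observed: AnnualSeries
    ) -> "ForecastEvaluation":
        return cls(predicted, observed, len(predicted), rmse(predicted, observed))


def _values(series: Union[AnnualSeries, Sequence[float]]) -> np.ndarray:
    if isinstance(series, AnnualSeries):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


def rmse(
    predicted: Union[AnnualSeries, Sequence[float]],
    observed: Union[AnnualSeries, Sequence[float]],
) -> float:
    """Root mean square error sqrt(sum((P_i - O_i)^2) / n)."""
    if isinstance(predicted, AnnualSeries) and isinstance(observed, AnnualSeries):
        if predicted.years != observed.years:
            raise ValueError(
                f"year mismatch: predicted {predicted.years[0]}-{predicted.years[-1]}"
                f" vs observed {observed.years[0]}-{observed.years[-1]}"
            )
    p, o = _values(predicted), _values(observed)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape[0]} vs {o.shape[0]}")
    if p.size == 0:
        raise ValueError("rmse requires at least one pair")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def summarize(series: Union[AnnualSeries, Sequence[float]]) -> SeriesSummary:
    """Mean, sample SD and SE of a series (n >= 2)."""
    x = _values(series)
    if x.size < 2:
        raise ValueError(f"summarize requires n >= 2, got {x.size}")
    return SeriesSummary(n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)))


def welch_t_test(s1: SeriesSummary, s2: SeriesSummary, alpha: float = 0.05) -> TTestResult:
    """Welch two-sample t-test from summary statistics.

    t = (mean1 - mean2) / sqrt(se1^2 + se2^2); the Welch-Satterthwaite
    degrees of freedom are floored to an integer, and both the two-sided
    p-value and the (1 - alpha) confidence interval for the difference use
    the t distribution at that integer df.
    """
    diff = s1.mean - s2.mean
    v1, v2 = s1.se**2, s2.se**2
    pooled_se = math.sqrt(v1 + v2)

    if pooled_se == 0.0:
        if diff == 0.0:
            return TTestResult(
                t=0.0, df=s1.n + s2.n - 2, p=1.0, diff=0.0, ci_low=0.0, ci_high=0.0
            )
        raise ValueError("zero pooled standard error with unequal means")

    t_stat = diff / pooled_se
    df_ws = (v1 + v2) ** 2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1))
    df = max(int(math.floor(df_ws)), 1)
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    tcrit = float(stats.t.ppf(1 - alpha / 2, df))
    return TTestResult(
        t=t_stat,
        df=df,
        p=p,
        diff=diff,
        ci_low=diff - tcrit * pooled_se,
        ci_high=diff + tcrit * pooled_se,
    )


def welch_t_test_values(
    x: Union[AnnualSeries, Sequence[float]],
    y: Union[AnnualSeries, Sequence[float]],
    alpha: float = 0.05,
) -> TTestResult:
    """Welch test on two raw series (summarised internally)."""
    return welch_t_test(summarize(x), summarize(y), alpha=alpha)


def format_ttest_report(
    s1: SeriesSummary, s2: SeriesSummary, result: TTestResult,
    labels: tuple = ("series A", "series B"),
) -> str:
    """Classical-style plain-text report: means/SDs/SEs/CI as integers,
    t to two decimals, p to three."""
    lines = [
        "Two-sample t-test (Welch, unequal variances)",
        "",
        f"{'':12s}{'N':>6s}{'Mean':>10s}{'StDev':>10s}{'SE Mean':>10s}",
    ]
    for label, s in zip(labels, (s1, s2)):
        lines.append(
            f"{label[:12]:12s}{s.n:>6d}{round_half_up(s.mean, 0):>10.0f}"
            f"{round_half_up(s.sd, 0):>10.0f}{round_half_up(s.se, 0):>10.0f}"
        )
    lines += [
        "",
        f"Difference = {round_half_up(result.diff, 0):.0f}",
        f"95% CI for difference: ({round_half_up(result.ci_low, 0):.0f}, "
        f"{round_half_up(result.ci_high, 0):.0f})",
        f"T-Value = {round_half_up(result.t, 2):.2f}  "
        f"P-Value = {round_half_up(result.p, 3):.3f}  DF = {result.df}",
    ]
    return "\n".join(lines)
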