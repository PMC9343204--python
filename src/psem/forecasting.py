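"""Annual incidence aggregation and trend forecasting.

Registry records are aggregated into a year-indexed count series, then
extrapolated a decade ahead by one of two deterministic forecasters:

* a linear trend — ordinary least squares of count on year index, with
  normal-theory prediction intervals; and
* a lagged epsilon-SVR — support-vector regression on windows of the
  previous ``lag`` annual counts, forecasting iteratively by feeding each
  one-step prediction back in as the newest lag.

Yearly data has no sub-annual seasonality, so no seasonal machinery is
offered.  Both forecasters are deterministic for fixed inputs and
hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import statsmodels.api as sm
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "AnnualSeries",
    "ForecastResult",
    "LinearTrendModel",
    "aggregate_annual_counts",
    "fit_linear_trend",
    "forecast_linear",
    "fit_forecast_svr",
]


@dataclass(frozen=True)
class AnnualSeries:
    """A value per consecutive calendar year (counts, populations, ...)."""

    years: Tuple[int, ...]
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if len(years) != len(values):
            raise ValueError(
                f"years ({len(years)}) and values ({len(values)}) differ in length"
            )
        if len(years) == 0:
            raise ValueError("series must contain at least one year")
        for a, b in zip(years, years[1:]):
            if b != a + 1:
                raise ValueError(f"years must be consecutive; gap between {a} and {b}")
        if any(v < 0 for v in values):
            raise ValueError("values must be non-negative")

    def __len__(self) -> int:
        return len(self.years)

    @property
    def start_year(self) -> int:
        return self.years[0]

    @property
    def end_year(self) -> int:
        return self.years[-1]

    def total(self) -> float:
        return float(sum(self.values))

    def to_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.years, dtype=int), np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class ForecastResult:
    """Horizon predictions plus the fitted parameters that produced them."""

    method: str
    horizon: int
    predictions: AnnualSeries
    params: dict = field(default_factory=dict)
    ci_low: Optional[Tuple[float, ...]] = None
    ci_high: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.horizon != len(self.predictions):
            raise ValueError(
                f"horizon {self.horizon} != prediction length {len(self.predictions)}"
            )


def aggregate_annual_counts(
    records: Iterable[Union[int, Tuple[int, float]]],
    start_year: int,
    end_year: int,
) -> AnnualSeries:
    """Sum per-record counts into a contiguous annual series.

    Each record is either a bare year (one patient) or a ``(year, count)``
    pair.  Years absent from the records appear with count 0; a record
    outside ``[start_year, end_year]`` is a validation error.
    """
    if end_year < start_year:
        raise ValueError(f"end_year {end_year} before start_year {start_year}")
    totals = {y: 0.0 for y in range(start_year, end_year + 1)}
    for rec in records:
        if isinstance(rec, (tuple, list)):
            year, count = int(rec[0]), float(rec[1])
        else:
            year, count = int(rec), 1.0
        if year not in totals:
            raise ValueError(
                f"record year {year} outside declared range {start_year}-{end_year}"
            )
        totals[year] += count
    years = tuple(sorted(totals))
    return AnnualSeries(years=years, values=tuple(totals[y] for y in years))


@dataclass(frozen=True)
class LinearTrendModel:
    """OLS fit of annual count on calendar year."""

    intercept: float
    slope: float
    slope_se: float
    resid_sd: float
    n: int
    train_start: int
    train_end: int
    x_mean: float
    sxx: float


def fit_linear_trend(train: AnnualSeries) -> LinearTrendModel:
    """Fit count = intercept + slope * year by OLS."""
    if len(train) < 3:
        raise ValueError(f"need at least 3 training years, got {len(train)}")
    t = np.asarray(train.years, dtype=float)
    y = np.asarray(train.values, dtype=float)
    res = sm.OLS(y, sm.add_constant(t)).fit()
    resid_sd = float(np.sqrt(res.scale))
    return LinearTrendModel(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        resid_sd=resid_sd,
        n=len(train),
        train_start=train.start_year,
        train_end=train.end_year,
        x_mean=float(t.mean()),
        sxx=float(((t - t.mean()) ** 2).sum()),
    )


def forecast_linear(
    model: LinearTrendModel, horizon: int, alpha: float = 0.05
) -> ForecastResult:
    """Extrapolate the fitted line ``horizon`` years past the training end.

    The interval reported per year is the normal-theory prediction
    interval for a new observation at that year.
    """
    from scipy import stats

    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    t_new = model.train_end + np.arange(1, horizon + 1, dtype=float)
    pred = model.intercept + model.slope * t_new
    years = tuple(range(model.train_end + 1, model.train_end + 1 + horizon))

    dof = model.n - 2
    se_pred = model.resid_sd * np.sqrt(
        1.0 + 1.0 / model.n + (t_new - model.x_mean) ** 2 / model.sxx
    )
    tcrit = float(stats.t.ppf(1 - alpha / 2, dof)) if dof > 0 else np.inf
    low = np.maximum(pred - tcrit * se_pred, 0.0)
    high = pred + tcrit * se_pred

    return ForecastResult(
        method="linear-trend",
        horizon=horizon,
        predictions=AnnualSeries(years=years, values=tuple(np.maximum(pred, 0.0))),
        params={"intercept": model.intercept, "slope": model.slope},
        ci_low=tuple(float(v) for v in low),
        ci_high=tuple(float(v) for v in high),
    )


def _lag_matrix(values: np.ndarray, lag: int) -> Tuple[np.ndarray, np.ndarray]:
    X = np.stack([values[i : i + lag] for i in range(len(values) - lag)])
    y = values[lag:]
    return X, y


def fit_forecast_svr(
    train: AnnualSeries,
    lag: int = 1,
    horizon: int = 10,
    *,
    kernel: str = "linear",
    C: float = 1000.0,
    epsilon: float = 1e-3,
) -> ForecastResult:
    """Forecast by epsilon-SVR on lag-window features, iterated one step
    at a time.

    Features and target are standardised before fitting (``epsilon`` is in
    standardised units); each one-step forecast is appended to the history
    and becomes the newest lag for the next step.  Deterministic for fixed
    inputs and hyperparameters.
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    if len(train) <= lag + 2:
        raise ValueError(
            f"training length {len(train)} too short for lag {lag} (need > lag + 2)"
        )

    values = np.asarray(train.values, dtype=float)
    X, y = _lag_matrix(values, lag)

    x_scaler = StandardScaler().fit(X)
    y_scaler = StandardScaler().fit(y.reshape(-1, 1))
    model = SVR(kernel=kernel, C=C, epsilon=epsilon)
    model.fit(x_scaler.transform(X), y_scaler.transform(y.reshape(-1, 1)).ravel())

    history = list(values)
    preds = []
    for _ in range(horizon):
        window = np.asarray(history[-lag:], dtype=float).reshape(1, -1)
        z = model.predict(x_scaler.transform(window))
        nxt = float(y_scaler.inverse_transform(z.reshape(-1, 1))[0, 0])
        nxt = max(nxt, 0.0)
        preds.append(nxt)
        history.append(nxt)

    years = tuple(range(train.end_year + 1, train.end_year + 1 + horizon))
    return ForecastResult(
        method="svr-lagged",
        horizon=horizon,
        predictions=AnnualSeries(years=years, values=tuple(preds)),
        params={"lag": lag, "kernel": kernel, "C": C, "epsilon": epsilon},
    )
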