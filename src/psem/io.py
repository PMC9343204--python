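"""CSV reading and writing for annual series and family records.

Dialect: comma-separated, UTF-8, ``.`` decimal, mandatory header row.
Errors name the offending file, column or year.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .forecasting import AnnualSeries, ForecastResult

__all__ = [
    "read_annual_csv",
    "write_annual_csv",
    "read_families_csv",
    "write_forecast_csv",
]

FAMILY_COLUMNS = [
    "family_id",
    "affiliation",
    "is_working",
    "is_expired",
    "physical_status",
    "income_status",
    "expense_category",
    "n_working",
    "n_dependent",
    "n_expired",
]


def read_annual_csv(
    path: Union[str, Path], value_column: Optional[str] = None
) -> AnnualSeries:
    """Read a `year,<value>` CSV into an :class:`AnnualSeries`.

    ``value_column`` defaults to the single non-year column; non-contiguous
    years are rejected naming the missing ones.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "year" not in df.columns:
        raise ValueError(f"{path}: missing required column 'year'")
    if value_column is None:
        others = [c for c in df.columns if c != "year"]
        if len(others) != 1:
            raise ValueError(
                f"{path}: expected exactly one value column beside 'year', "
                f"found {others}"
            )
        value_column = others[0]
    elif value_column not in df.columns:
        raise ValueError(f"{path}: missing column {value_column!r}")

    df = df.sort_values("year")
    years = df["year"].astype(int).tolist()
    expected = list(range(years[0], years[-1] + 1))
    missing = sorted(set(expected) - set(years))
    if missing:
        raise ValueError(f"{path}: years not contiguous; missing {missing}")
    return AnnualSeries(
        years=tuple(years), values=tuple(df[value_column].astype(float))
    )


def write_annual_csv(
    series: AnnualSeries, path: Union[str, Path], value_column: str = "value"
) -> None:
    pd.DataFrame({"year": series.years, value_column: series.values}).to_csv(
        path, index=False
    )


def read_families_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read and schema-check a family-records CSV (may be empty)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in FAMILY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_forecast_csv(result: ForecastResult, path: Union[str, Path]) -> None:
    """Write `year,method,prediction,ci_low,ci_high` (blank CI if absent)."""
    n = result.horizon
    pd.DataFrame(
        {
            "year": result.predictions.years,
            "method": [result.method] * n,
            "prediction": result.predictions.values,
            "ci_low": result.ci_low if result.ci_low is not None else [""] * n,
            "ci_high": result.ci_high if result.ci_high is not None else [""] * n,
        }
    ).to_csv(path, index=False)
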