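"""Published worked-example tables shipped as in-package fixtures.

The registry behind the study (217,067 patients, 1998-2020, Punjab,
Pakistan) is not deposited, but the publication prints the worked examples
end to end: the member-stress factor grid, the family-stress grid, the
forecast decade (2021-2030) of family counts and area populations, and the
two competing forecast series.  Those printed values are the canonical
inputs for the reproduction pipeline, so they live here as constants with
small accessors returning pandas objects.
"""

from __future__ import annotations

import pandas as pd

from .forecasting import AnnualSeries

__all__ = [
    "member_stress_table",
    "family_stress_table",
    "area_stress_table",
    "lr_forecast_2021_2030",
    "smoreg_summary_2021_2030",
    "lr_forecast_2011_2020",
    "smoreg_forecast_2011_2020",
    "TS_MIN",
    "TS_AVG",
    "TS_MAX",
]

# Representative family-stress values used for the area-stress columns:
# the grid minimum, the quoted decade average, and the quoted maximum.
TS_MIN = 23
TS_AVG = 328.43
TS_MAX = 1003

# (A, wP, E, pS, iS, eT, Sf) — factor weight combinations observed to be
# common in the registry, with the member stress each one scores.
_MEMBER_STRESS_ROWS = [
    (5, 10, 7, 5, 3, 10, 100),
    (4, 10, 7, 5, 3, 10, 99),
    (3, 10, 7, 5, 3, 10, 98),
    (2, 10, 7, 5, 3, 10, 97),
    (1, 10, 7, 5, 3, 10, 96),
    (5, 5, 7, 5, 3, 10, 65),
    (5, 10, 4, 5, 3, 10, 70),
    (5, 10, 7, 2, 3, 10, 91),
    (5, 10, 7, 1, 3, 10, 88),
    (5, 10, 7, 5, 2, 10, 95),
    (5, 10, 7, 5, 1, 10, 90),
    (5, 10, 7, 5, 3, 7, 97),
    (5, 10, 7, 5, 3, 6, 96),
    (5, 10, 7, 5, 3, 5, 95),
    (5, 10, 7, 5, 3, 4, 94),
    (5, 10, 7, 5, 3, 2, 92),
    (5, 10, 7, 5, 3, 1, 91),
    (4, 5, 7, 5, 3, 10, 64),
    (3, 5, 7, 5, 3, 10, 63),
    (1, 5, 7, 5, 3, 10, 61),
    (5, 5, 4, 5, 3, 9, 49),
    (5, 5, 4, 5, 3, 8, 48),
    (5, 5, 4, 5, 3, 7, 47),
    (5, 5, 4, 5, 3, 6, 46),
    (5, 5, 4, 5, 3, 5, 45),
    (5, 5, 4, 5, 3, 2, 42),
    (5, 5, 4, 5, 3, 1, 41),
    (5, 5, 4, 5, 2, 10, 45),
    (1, 5, 4, 1, 1, 1, 23),
]

# (Sf, nW, nD, nE, TS) — common household compositions and their family
# stress.  Note the nW > nD row (41, 5, 1, 0) -> 205.
_FAMILY_STRESS_ROWS = [
    (100, 2, 11, 2, 1002),
    (99, 2, 5, 1, 397),
    (98, 1, 3, 1, 295),
    (97, 1, 4, 0, 388),
    (96, 2, 7, 0, 576),
    (65, 2, 8, 1, 456),
    (70, 1, 4, 1, 281),
    (91, 1, 3, 1, 274),
    (88, 1, 3, 1, 265),
    (95, 0, 4, 1, 476),
    (90, 0, 6, 1, 631),
    (97, 1, 5, 1, 486),
    (96, 3, 7, 1, 481),
    (95, 2, 6, 1, 476),
    (94, 1, 3, 0, 282),
    (93, 1, 5, 1, 466),
    (92, 1, 4, 1, 369),
    (91, 1, 3, 0, 273),
    (64, 0, 5, 1, 385),
    (63, 1, 2, 0, 126),
    (61, 1, 2, 0, 122),
    (49, 3, 4, 0, 98),
    (48, 1, 2, 0, 96),
    (47, 1, 6, 0, 282),
    (46, 1, 5, 1, 231),
    (45, 1, 3, 0, 135),
    (44, 0, 7, 1, 353),
    (42, 1, 2, 0, 84),
    (41, 5, 1, 0, 205),
    (45, 1, 2, 2, 92),
    (23, 1, 1, 0, 23),
]

# (year, forecast families with a cancer patient, forecast area
# population, printed OES with average / minimum / maximum TS).
_AREA_STRESS_ROWS = [
    (2021, 15493, 16637186, 30.49, 2.14, 93.31),
    (2022, 16119, 17166568, 30.74, 2.16, 94.08),
    (2023, 16658, 17690235, 30.83, 2.17, 94.35),
    (2024, 17183, 18207267, 30.90, 2.17, 94.57),
    (2025, 17707, 18718658, 30.97, 2.18, 94.79),
    (2026, 18231, 19226391, 31.05, 2.18, 95.01),
    (2027, 18755, 19733393, 31.12, 2.19, 95.23),
    (2028, 19280, 20242985, 31.19, 2.19, 95.43),
    (2029, 19805, 20758846, 31.24, 2.19, 95.59),
    (2030, 20330, 21283844, 31.28, 2.20, 95.71),
]

# Year-wise new cancer cases 2021-2030 forecast by the linear-regression
# trend model (the validated model; these counts drive the area-stress
# decade).  Their sum is the expected-patient total 179,561.
_LR_FORECAST_2021_2030 = (
    15493, 16119, 16658, 17183, 17707, 18231, 18755, 19280, 19805, 20330,
)

# Competing support-vector-regression forecast for the same decade is
# published only as summary statistics.
_SMOREG_SUMMARY = {"n": 10, "mean": 18177.0, "sd": 1667.0}

# Hold-out decade forecasts (trained on 1998-2010) by both models.
_LR_FORECAST_2011_2020 = (
    10004, 9851, 10516, 11390, 11396, 11950, 12832, 13051, 13402, 14253,
)
_SMOREG_FORECAST_2011_2020 = (
    10151, 10116, 10312, 11371, 11554, 11705, 12354, 13046, 13084, 13533,
)


def member_stress_table() -> pd.DataFrame:
    """Factor-weight grid with the published member stress column ``sf``."""
    return pd.DataFrame(
        _MEMBER_STRESS_ROWS, columns=["A", "wP", "E", "pS", "iS", "eT", "sf"]
    )


def family_stress_table() -> pd.DataFrame:
    """Household-composition grid with the published ``ts`` column."""
    return pd.DataFrame(
        _FAMILY_STRESS_ROWS, columns=["sf", "nW", "nD", "nE", "ts"]
    )


def area_stress_table() -> pd.DataFrame:
    """Forecast decade: family counts, populations and printed OES columns."""
    return pd.DataFrame(
        _AREA_STRESS_ROWS,
        columns=["year", "n_families", "population", "oes_avg", "oes_min", "oes_max"],
    )


def lr_forecast_2021_2030() -> AnnualSeries:
    return AnnualSeries(years=tuple(range(2021, 2031)), values=_LR_FORECAST_2021_2030)


def smoreg_summary_2021_2030() -> dict:
    """Published summary (n, mean, sd) of the SMOreg 2021-2030 forecast."""
    return dict(_SMOREG_SUMMARY)


def lr_forecast_2011_2020() -> AnnualSeries:
    return AnnualSeries(years=tuple(range(2011, 2021)), values=_LR_FORECAST_2011_2020)


def smoreg_forecast_2011_2020() -> AnnualSeries:
    return AnnualSeries(
        years=tuple(range(2011, 2021)), values=_SMOREG_FORECAST_2011_2020
    )
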