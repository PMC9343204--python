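"""Synthetic registry-like inputs for end-to-end testing.

The real hospital registry is not publicly deposited, so this module
generates inputs with the statistical structure the analysis assumes:

* an annual incidence series with a linear upward trend plus Gaussian
  noise, sized to the registry's magnitude (roughly 3,000 new patients in
  1998 rising to 16,000 by 2020, ~214k over 23 years);
* family records over the categorical factor space of the scoring model
  (affiliation, working/expired flags, physical and income status,
  treatment funding) plus household composition counts; and
* an area-population projection growing geometrically from the 2021 level.

Everything is reproducible from a single seed; the three generators draw
from independent child streams so adding one does not perturb another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from . import core
from .forecasting import AnnualSeries

__all__ = [
    "GeneratorConfig",
    "generate_incidence_series",
    "generate_family_records",
    "generate_population_series",
]

_AFFILIATIONS = tuple(core.AFFILIATION_WEIGHTS)
_PHYSICAL = tuple(core.PHYSICAL_STATUS_WEIGHTS)
_INCOME = tuple(core.INCOME_STATUS_WEIGHTS)
_EXPENSE = ("self", "free") + tuple(str(k) for k in range(2, 10))
_FLAGS = ("yes", "no")

_FACTOR_LABELS: Dict[str, Tuple[str, ...]] = {
    "affiliation": _AFFILIATIONS,
    "is_working": _FLAGS,
    "is_expired": _FLAGS,
    "physical_status": _PHYSICAL,
    "income_status": _INCOME,
    "expense_category": _EXPENSE,
}


def _uniform(labels: Tuple[str, ...]) -> Dict[str, float]:
    return {lab: 1.0 / len(labels) for lab in labels}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the synthetic registry.

    Defaults emulate the study setting: incidence 1998-2020 rising from
    ~2,800 to ~16,000 patients/year (annual slope 590, noise SD 400),
    population projected for 2021-2030 from 16,637,186 at 2.76%/yr, and
    factor labels drawn uniformly (no empirical frequencies exist to fit).
    """

    seed: int = 0
    years: Tuple[int, int] = (1998, 2020)
    trend_intercept: float = 2800.0
    trend_slope: float = 590.0
    noise_sd: float = 400.0
    n_families: int = 1000
    category_probabilities: Dict[str, Dict[str, float]] = field(default_factory=dict)
    composition_ranges: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {"nW": (0, 3), "nD": (0, 8), "nE": (0, 2)}
    )
    population_years: Tuple[int, int] = (2021, 2030)
    population_start: float = 16_637_186.0
    population_growth: float = 0.0276

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.population_growth < 0:
            raise ValueError(f"population_growth must be >= 0, got {self.population_growth}")
        if self.n_families < 0:
            raise ValueError(f"n_families must be >= 0, got {self.n_families}")
        for name, (start, end) in (
            ("years", self.years), ("population_years", self.population_years)
        ):
            if end < start:
                raise ValueError(f"{name}: end {end} before start {start}")
        probs = dict(self.category_probabilities)
        for factor, labels in _FACTOR_LABELS.items():
            table = probs.get(factor)
            if table is None:
                probs[factor] = _uniform(labels)
                continue
            unknown = set(table) - set(labels)
            if unknown:
                raise ValueError(f"{factor}: unknown labels {sorted(unknown)}")
            total = sum(table.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{factor}: probabilities sum to {total}, expected 1")
            if any(p < 0 for p in table.values()):
                raise ValueError(f"{factor}: negative probability")
            probs[factor] = {lab: table.get(lab, 0.0) for lab in labels}
        object.__setattr__(self, "category_probabilities", probs)
        for name, (lo, hi) in self.composition_ranges.items():
            if name not in ("nW", "nD", "nE"):
                raise ValueError(f"composition_ranges: unknown field {name!r}")
            if lo < 0 or hi < lo:
                raise ValueError(f"composition_ranges[{name!r}]: bad range ({lo}, {hi})")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


def generate_incidence_series(cfg: GeneratorConfig) -> AnnualSeries:
    """Annual counts round(intercept + slope*t + N(0, noise_sd)), clipped at 0."""
    start, end = cfg.years
    n = end - start + 1
    t = np.arange(n, dtype=float)
    noise = cfg._rng(1).normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
    counts = np.clip(np.round(cfg.trend_intercept + cfg.trend_slope * t + noise), 0, None)
    return AnnualSeries(years=tuple(range(start, end + 1)), values=tuple(counts))


def generate_family_records(cfg: GeneratorConfig) -> pd.DataFrame:
    """Family rows over the factor space, as the `families.csv` schema.

    Columns: family_id, affiliation, is_working, is_expired,
    physical_status, income_status, expense_category, n_working,
    n_dependent, n_expired.  Every emitted label is accepted by
    :func:`psem.core.encode_factors`.
    """
    rng = cfg._rng(2)
    cols: Dict[str, np.ndarray] = {}
    for factor, labels in _FACTOR_LABELS.items():
        p = np.array([cfg.category_probabilities[factor][lab] for lab in labels])
        cols[factor] = rng.choice(np.array(labels, dtype=object), size=cfg.n_families, p=p)
    comp = {}
    for name, key in (("n_working", "nW"), ("n_dependent", "nD"), ("n_expired", "nE")):
        lo, hi = cfg.composition_ranges[key]
        comp[name] = rng.integers(lo, hi + 1, size=cfg.n_families)
    return pd.DataFrame(
        {
            "family_id": np.arange(cfg.n_families),
            "affiliation": cols["affiliation"],
            "is_working": cols["is_working"],
            "is_expired": cols["is_expired"],
            "physical_status": cols["physical_status"],
            "income_status": cols["income_status"],
            "expense_category": cols["expense_category"],
            "n_working": comp["n_working"],
            "n_dependent": comp["n_dependent"],
            "n_expired": comp["n_expired"],
        }
    )


def generate_population_series(cfg: GeneratorConfig) -> AnnualSeries:
    """Geometric population projection start*(1+growth)^t, rounded."""
    start, end = cfg.population_years
    t = np.arange(end - start + 1, dtype=float)
    pop = np.round(cfg.population_start * (1.0 + cfg.population_growth) ** t)
    return AnnualSeries(years=tuple(range(start, end + 1)), values=tuple(pop))
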