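"""Family-stress scoring for cancer-patient households.

The model scores stress at three levels:

* member stress ``Sf`` — an integer composite of six weighted factors
  describing one family member's relation to the patient and the
  household's financial exposure,

      Sf = A + wP * E + pS * iS + eT

* family stress ``TS`` — ``Sf`` scaled by the imbalance between dependent
  and working members, plus the number of family members already lost to
  the disease,

      TS = Sf * (|nD - nW| + 1) + nE

* area stress ``OES`` — the summed family stress of an area expressed as a
  percentage of the area's population,

      OES = (sum of TS over families) / population * 100

All factor weights are fixed constants of the model (they encode interview
observations, not fitted parameters).  ``Sf`` and ``TS`` are exact
integers; ``OES`` is reported rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence, Union

__all__ = [
    "AFFILIATION_WEIGHTS",
    "PHYSICAL_STATUS_WEIGHTS",
    "INCOME_STATUS_WEIGHTS",
    "WORKING_WEIGHTS",
    "EXPIRED_WEIGHTS",
    "StressFactors",
    "FamilyComposition",
    "FamilyStressRecord",
    "AreaStressRow",
    "encode_factors",
    "family_member_stress",
    "family_total_stress",
    "overall_estimated_stress",
    "area_stress",
    "decade_summary",
    "round_half_up",
]

# Relationship of the stressed member to the patient; closer kin carries
# more weight.  Individual labels ("father", "sister") are accepted as
# synonyms for their slashed pair.
AFFILIATION_WEIGHTS = {
    "father/mother": 5,
    "child": 4,
    "brother/sister": 3,
    "friend": 2,
    "colleague/neighbor": 1,
}
_AFFILIATION_SYNONYMS = {
    "father": "father/mother",
    "mother": "father/mother",
    "brother": "brother/sister",
    "sister": "brother/sister",
    "colleague": "colleague/neighbor",
    "neighbor": "colleague/neighbor",
    "neighbour": "colleague/neighbor",
}

# Can the patient still work, and how much?
PHYSICAL_STATUS_WEIGHTS = {"cannot-work": 5, "can-work-25%": 2, "can-work-50%": 1}

# Household income class; poorer families carry more stress.
INCOME_STATUS_WEIGHTS = {"poor": 3, "average": 2, "rich": 1}

# Was the patient a working person (losing an earner weighs double)?
WORKING_WEIGHTS = {True: 10, False: 5}

# Has the patient died?
EXPIRED_WEIGHTS = {True: 7, False: 4}

# Treatment funding: fully self-paid = 10, fully funded = 1, and the
# integers 2-9 grade mixed funding by the self-paid share.
_EXPENSE_SELF = 10
_EXPENSE_FREE = 1

_TRUTHY = {"yes", "y", "true", "1"}
_FALSY = {"no", "n", "false", "0"}


def _normalize_label(value: str) -> str:
    return str(value).strip().lower().replace(" ", "-").replace("_", "-")


def _as_flag(value: Union[bool, str, int], field: str) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, int) and value in (0, 1):
        return bool(value)
    label = _normalize_label(value)
    if label in _TRUTHY:
        return True
    if label in _FALSY:
        return False
    raise ValueError(f"{field}: expected yes/no flag, got {value!r}")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention used in reports)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StressFactors:
    """The six encoded weights entering the member-stress score.

    Attributes
    ----------
    A : affiliation weight, 1-5
    wP : working-person weight, 10 (working) or 5
    E : expired weight, 7 (deceased) or 4
    pS : physical-status weight, one of {5, 2, 1}
    iS : income-status weight, one of {3, 2, 1}
    eT : treatment-expense weight, 1-10
    """

    A: int
    wP: int
    E: int
    pS: int
    iS: int
    eT: int

    def __post_init__(self) -> None:
        checks = {
            "A": (self.A, set(AFFILIATION_WEIGHTS.values())),
            "wP": (self.wP, set(WORKING_WEIGHTS.values())),
            "E": (self.E, set(EXPIRED_WEIGHTS.values())),
            "pS": (self.pS, set(PHYSICAL_STATUS_WEIGHTS.values())),
            "iS": (self.iS, set(INCOME_STATUS_WEIGHTS.values())),
            "eT": (self.eT, set(range(1, 11))),
        }
        for name, (value, allowed) in checks.items():
            if not isinstance(value, int) or isinstance(value, bool) or value not in allowed:
                raise ValueError(
                    f"{name}: weight {value!r} not in allowed set {sorted(allowed)}"
                )


@dataclass(frozen=True)
class FamilyComposition:
    """Counts of working (nW), dependent (nD) and expired (nE) members."""

    nW: int
    nD: int
    nE: int

    def __post_init__(self) -> None:
        for name in ("nW", "nD", "nE"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool) or value < 0:
                raise ValueError(f"{name}: expected non-negative integer, got {value!r}")


@dataclass(frozen=True)
class FamilyStressRecord:
    """One family's factors, composition and the two derived scores."""

    factors: StressFactors
    composition: FamilyComposition
    sf: int
    ts: int

    def __post_init__(self) -> None:
        if self.sf != family_member_stress(self.factors):
            raise ValueError(f"sf={self.sf} inconsistent with factors {self.factors}")
        if self.ts != family_total_stress(self.sf, self.composition):
            raise ValueError(f"ts={self.ts} inconsistent with sf/composition")

    @classmethod
    def build(
        cls, factors: StressFactors, composition: FamilyComposition
    ) -> "FamilyStressRecord":
        sf = family_member_stress(factors)
        return cls(factors, composition, sf, family_total_stress(sf, composition))


@dataclass(frozen=True)
class AreaStressRow:
    """Per-year area stress: family count, population and OES percentage."""

    year: int
    n_families: int
    population: int
    oes: float

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError(f"population must be > 0, got {self.population}")
        if self.n_families < 0:
            raise ValueError(f"n_families must be >= 0, got {self.n_families}")
        if self.oes < 0:
            raise ValueError(f"oes must be >= 0, got {self.oes}")


def encode_factors(
    affiliation: str,
    is_working: Union[bool, str],
    is_expired: Union[bool, str],
    physical_status: str,
    income_status: str,
    expense_category: Union[str, int],
) -> StressFactors:
    """Encode categorical factor labels into their integer weights.

    ``expense_category`` is ``"self"`` (no funding), ``"free"`` (fully
    funded) or an integer 2-9 grading mixed funding.  Unknown labels raise
    :class:`ValueError` naming the offending field.
    """
    aff = _normalize_label(affiliation)
    aff = _AFFILIATION_SYNONYMS.get(aff, aff)
    if aff not in AFFILIATION_WEIGHTS:
        raise ValueError(
            f"affiliation: unknown label {affiliation!r}; "
            f"expected one of {sorted(AFFILIATION_WEIGHTS)}"
        )

    phys = _normalize_label(physical_status)
    if phys not in PHYSICAL_STATUS_WEIGHTS:
        raise ValueError(
            f"physical_status: unknown label {physical_status!r}; "
            f"expected one of {sorted(PHYSICAL_STATUS_WEIGHTS)}"
        )

    income = _normalize_label(income_status)
    if income not in INCOME_STATUS_WEIGHTS:
        raise ValueError(
            f"income_status: unknown label {income_status!r}; "
            f"expected one of {sorted(INCOME_STATUS_WEIGHTS)}"
        )

    if isinstance(expense_category, str) and not expense_category.strip().lstrip("-").isdigit():
        label = _normalize_label(expense_category)
        if label == "self":
            eT = _EXPENSE_SELF
        elif label == "free":
            eT = _EXPENSE_FREE
        else:
            raise ValueError(
                f"expense_category: unknown label {expense_category!r}; "
                "expected 'self', 'free' or an integer 2-9"
            )
    else:
        eT = int(expense_category)
        if not 2 <= eT <= 9:
            raise ValueError(
                f"expense_category: mixed-funding weight must be in 2-9, got {eT}"
            )

    return StressFactors(
        A=AFFILIATION_WEIGHTS[aff],
        wP=WORKING_WEIGHTS[_as_flag(is_working, "is_working")],
        E=EXPIRED_WEIGHTS[_as_flag(is_expired, "is_expired")],
        pS=PHYSICAL_STATUS_WEIGHTS[phys],
        iS=INCOME_STATUS_WEIGHTS[income],
        eT=eT,
    )


def family_member_stress(f: StressFactors) -> int:
    """Member stress Sf = A + wP*E + pS*iS + eT (products before sums)."""
    return f.A + f.wP * f.E + f.pS * f.iS + f.eT


def family_total_stress(sf: int, c: FamilyComposition) -> int:
    """Family stress TS = Sf * (|nD - nW| + 1) + nE.

    The dependency-imbalance multiplier ``|nD - nW| + 1`` is at least 1, so
    a balanced household (nW == nD) carries exactly the member stress plus
    any expired count.
    """
    if sf < 0:
        raise ValueError(f"sf must be >= 0, got {sf}")
    return sf * (abs(c.nD - c.nW) + 1) + c.nE


def overall_estimated_stress(family_ts: Iterable[int], population: int) -> float:
    """Area stress: summed family TS as a percentage of the population.

    Returns the percentage rounded half-up to two decimals.  An empty
    family list gives 0.00.
    """
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    total = sum(family_ts)
    return round_half_up(total / population * 100.0, 2)


def area_stress(n_families: int, representative_ts: float, population: int) -> float:
    """OES when every one of ``n_families`` carries a representative TS."""
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    if n_families < 0:
        raise ValueError(f"n_families must be >= 0, got {n_families}")
    return round_half_up(n_families * representative_ts / population * 100.0, 2)


def decade_summary(rows: Sequence[Union[AreaStressRow, float]]) -> float:
    """Mean of per-year OES percentages, rounded half-up to two decimals."""
    if len(rows) == 0:
        raise ValueError("decade_summary requires at least one row")
    values = [r.oes if isinstance(r, AreaStressRow) else float(r) for r in rows]
    return round_half_up(sum(values) / len(values), 2)
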