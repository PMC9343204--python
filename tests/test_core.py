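"""Member, family and area stress scoring."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from psem import datasets
from psem.core import (
    AreaStressRow,
    FamilyComposition,
    FamilyStressRecord,
    StressFactors,
    area_stress,
    decade_summary,
    encode_factors,
    family_member_stress,
    family_total_stress,
    overall_estimated_stress,
    round_half_up,
)

ALL_LABELS = {
    "affiliation": ["father/mother", "child", "brother/sister", "friend",
                    "colleague/neighbor"],
    "is_working": [True, False],
    "is_expired": [True, False],
    "physical_status": ["cannot-work", "can-work-25%", "can-work-50%"],
    "income_status": ["poor", "average", "rich"],
    "expense_category": ["self", "free"] + list(range(2, 10)),
}

factors_strategy = st.builds(
    StressFactors,
    A=st.sampled_from([1, 2, 3, 4, 5]),
    wP=st.sampled_from([5, 10]),
    E=st.sampled_from([4, 7]),
    pS=st.sampled_from([1, 2, 5]),
    iS=st.sampled_from([1, 2, 3]),
    eT=st.integers(1, 10),
)
composition_strategy = st.builds(
    FamilyComposition,
    nW=st.integers(0, 10),
    nD=st.integers(0, 15),
    nE=st.integers(0, 5),
)


class TestEncodeFactors:
    @pytest.mark.parametrize(
        "inputs, expected",
        [
            (("father/mother", True, True, "cannot-work", "poor", "self"),
             (5, 10, 7, 5, 3, 10)),
            (("colleague/neighbor", False, False, "can-work-50%", "rich", "free"),
             (1, 5, 4, 1, 1, 1)),
            (("mother", "yes", "no", "can work 25%", "average", 6),
             (5, 10, 4, 2, 2, 6)),
            (("sister", "no", "yes", "cannot work", "poor", "3"),
             (3, 5, 7, 5, 3, 3)),
        ],
    )
    def test_known_encodings(self, inputs, expected):
        f = encode_factors(*inputs)
        assert (f.A, f.wP, f.E, f.pS, f.iS, f.eT) == expected

    @pytest.mark.parametrize(
        "inputs, field",
        [
            (("uncle", True, True, "cannot-work", "poor", "self"), "affiliation"),
            (("child", True, True, "bedridden", "poor", "self"), "physical_status"),
            (("child", True, True, "cannot-work", "wealthy", "self"), "income_status"),
            (("child", True, True, "cannot-work", "poor", "subsidised"),
             "expense_category"),
            (("child", True, True, "cannot-work", "poor", 11), "expense_category"),
            (("child", True, True, "cannot-work", "poor", 1), "expense_category"),
            (("child", "maybe", True, "cannot-work", "poor", "self"), "is_working"),
        ],
    )
    def test_unknown_label_names_field(self, inputs, field):
        with pytest.raises(ValueError, match=field):
            encode_factors(*inputs)

    def test_exhaustive_member_stress_bounds(self):
        """Over all 1800 valid encodings Sf spans exactly [23, 100]."""
        scores = [
            family_member_stress(encode_factors(a, w, e, p, i, c))
            for a, w, e, p, i, c in itertools.product(*ALL_LABELS.values())
        ]
        assert len(scores) == 1800
        assert min(scores) == 23
        assert max(scores) == 100


class TestMemberStress:
    def test_reproduces_published_grid(self):
        """Every row of the published factor grid scores as printed."""
        table = datasets.member_stress_table()
        for row in table.itertuples(index=False):
            f = StressFactors(row.A, row.wP, row.E, row.pS, row.iS, row.eT)
            assert family_member_stress(f) == row.sf

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="wP"):
            StressFactors(A=5, wP=7, E=7, pS=5, iS=3, eT=10)
        with pytest.raises(ValueError, match="eT"):
            StressFactors(A=5, wP=10, E=7, pS=5, iS=3, eT=0)


class TestFamilyStress:
    def test_reproduces_published_grid(self):
        """Every row of the published household grid scores as printed,
        including the family with more workers than dependents."""
        table = datasets.family_stress_table()
        for row in table.itertuples(index=False):
            comp = FamilyComposition(row.nW, row.nD, row.nE)
            assert family_total_stress(row.sf, comp) == row.ts

    @given(sf=st.integers(0, 100), n=st.integers(0, 10))
    def test_balanced_household_collapses_to_member_stress(self, sf, n):
        assert family_total_stress(sf, FamilyComposition(n, n, 0)) == sf

    @given(f=factors_strategy, c=composition_strategy)
    def test_family_stress_dominates_member_stress(self, f, c):
        sf = family_member_stress(f)
        assert family_total_stress(sf, c) >= sf

    @given(f=factors_strategy, c=composition_strategy)
    def test_monotone_in_expired_count_and_imbalance(self, f, c):
        sf = family_member_stress(f)
        ts = family_total_stress(sf, c)
        more_expired = FamilyComposition(c.nW, c.nD, c.nE + 1)
        assert family_total_stress(sf, more_expired) > ts
        wider = FamilyComposition(c.nW, c.nD + 1, c.nE) if c.nD >= c.nW else \
            FamilyComposition(c.nW + 1, c.nD, c.nE)
        assert family_total_stress(sf, wider) > ts

    def test_record_consistency_enforced(self):
        f = StressFactors(5, 10, 7, 5, 3, 10)
        c = FamilyComposition(2, 11, 2)
        rec = FamilyStressRecord.build(f, c)
        assert (rec.sf, rec.ts) == (100, 1002)
        with pytest.raises(ValueError, match="inconsistent"):
            FamilyStressRecord(f, c, sf=99, ts=1002)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nD"):
            FamilyComposition(1, -1, 0)


class TestAreaStress:
    @pytest.mark.parametrize(
        "nf, ts, pop, expected",
        [
            (15493, 23, 16637186, 2.14),
            (20330, 23, 21283844, 2.20),
        ],
    )
    def test_published_minimum_column_examples(self, nf, ts, pop, expected):
        assert area_stress(nf, ts, pop) == expected

    def test_empty_family_list_is_zero(self):
        assert overall_estimated_stress([], 1000) == 0.0

    def test_population_must_be_positive(self):
        with pytest.raises(ValueError, match="population"):
            overall_estimated_stress([10], 0)
        with pytest.raises(ValueError, match="population"):
            area_stress(10, 23, -5)

    @given(
        ts=st.lists(st.integers(1, 1000), min_size=1, max_size=30),
        pop=st.integers(1000, 10**7),
    )
    def test_doubling_total_stress_doubles_oes(self, ts, pop):
        once = overall_estimated_stress(ts, pop)
        twice = overall_estimated_stress([2 * t for t in ts], pop)
        assert abs(twice - 2 * once) <= 0.015  # rounding slack only

    def test_row_validation(self):
        with pytest.raises(ValueError, match="population"):
            AreaStressRow(2021, 100, 0, 2.14)
        with pytest.raises(ValueError, match="n_families"):
            AreaStressRow(2021, -1, 100, 2.14)


class TestDecadeSummary:
    def test_published_minimum_column_mean(self, area_table):
        values = [
            area_stress(int(r.n_families), 23, int(r.population))
            for r in area_table.itertuples()
        ]
        assert decade_summary(values) == 2.18

    def test_single_row_and_constant_rows(self):
        row = AreaStressRow(2021, 100, 10_000, 2.5)
        assert decade_summary([row]) == 2.5
        assert decade_summary([3.14] * 7) == 3.14

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            decade_summary([])


@pytest.mark.parametrize(
    "x, nd, expected",
    [(2.175, 2, 2.18), (2.165, 2, 2.17), (0.125, 2, 0.13), (-2.175, 2, -2.18),
     (17956.1, 0, 17956.0)],
)
def test_round_half_up_ties_away_from_zero(x, nd, expected):
    assert round_half_up(x, nd) == expected
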