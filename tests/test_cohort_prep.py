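import numpy as np
import pytest

from fertiopt import (
    apply_eligibility,
    build_patient_courses,
    compute_yield_proportion,
    label_transfer_day,
    split_patients,
)
from fertiopt.cohort_prep import make_day_table, make_yield_table
from fertiopt.core_registry import registry_tables_equal

from conftest import make_tables, retrieval_row, transfer_row


def _one_per_rule_tables():
    """Five eligible-violating cycles (one per rule) plus one clean cycle."""
    return make_tables([
        retrieval_row(patient_id="ok"),
        retrieval_row(patient_id="late", cycle_year=2021),
        retrieval_row(patient_id="zero", n_oocytes_retrieved=0,
                      transfer_day_label="none", n_blastocysts_frozen=np.nan),
        retrieval_row(patient_id="donor", donor_oocyte=True),
        retrieval_row(patient_id="carrier", gestational_carrier=True),
        retrieval_row(patient_id="pgt", pgt=True),
    ])


def test_eligibility_rules():
    out = apply_eligibility(_one_per_rule_tables())
    assert list(out.retrievals["patient_id"]) == ["ok"]


def test_eligibility_is_idempotent():
    once = apply_eligibility(_one_per_rule_tables())
    twice = apply_eligibility(once)
    assert registry_tables_equal(once, twice)


def test_eligibility_year_rule_is_patient_level():
    # second cycle in 2020 stays if the FIRST cycle started in-window
    tables = make_tables([
        retrieval_row(patient_id="A", cycle_index=1, cycle_year=2019),
        retrieval_row(patient_id="A", cycle_index=2, cycle_year=2020),
    ])
    out = apply_eligibility(tables)
    assert len(out.retrievals) == 2


def test_eligibility_renumbers_transfers():
    tables = make_tables(
        [retrieval_row(patient_id="A", cycle_index=1, pgt=True),
         retrieval_row(patient_id="A", cycle_index=2)],
        [transfer_row(patient_id="A", retrieval_cycle_index=1, transfer_index=1),
         transfer_row(patient_id="A", retrieval_cycle_index=2, transfer_index=2)],
    )
    out = apply_eligibility(tables)
    assert list(out.transfers["transfer_index"]) == [1]
    assert list(out.transfers["retrieval_cycle_index"]) == [2]


def test_split_deterministic_and_disjoint(small_cohort):
    tables, _ = small_cohort
    s1 = split_patients(tables, seed=42)
    s2 = split_patients(tables, seed=42)
    assert s1.assignment.equals(s2.assignment)
    train, test = set(s1.patients("train")), set(s1.patients("test"))
    assert train.isdisjoint(test)
    assert train | test == set(tables.retrievals["patient_id"])
    assert abs(len(train) - len(test)) <= 1
    s3 = split_patients(tables, seed=43)
    assert not s3.assignment.equals(s1.assignment)


def test_split_is_patient_level(small_cohort):
    tables, _ = small_cohort
    s = split_patients(tables, seed=1)
    arms = tables.retrievals["patient_id"].map(s.assignment)
    per_patient = arms.groupby(tables.retrievals["patient_id"]).nunique()
    assert (per_patient == 1).all()


@pytest.mark.parametrize("day,expected", [
    (2, "day3"), (3, "day3"), (4, "day3"), (5, "day5"), (6, "day5"), (7, "day5"),
])
def test_label_transfer_day(day, expected):
    assert label_transfer_day(day) == expected


@pytest.mark.parametrize("day", [1, 8, 0, -3])
def test_label_transfer_day_out_of_range(day):
    with pytest.raises(ValueError):
        label_transfer_day(day)


def test_yield_proportion_worked_values():
    assert compute_yield_proportion(1, 3, 10) == pytest.approx(0.40)
    assert compute_yield_proportion(0, 0, 5) == 0.0
    assert compute_yield_proportion(5, 5, 10) == 1.0


def test_yield_proportion_errors():
    with pytest.raises(ValueError):
        compute_yield_proportion(2, 7, 8)  # usable exceed retrieved
    with pytest.raises(ValueError):
        compute_yield_proportion(1, 0, 0)
    with pytest.raises(ValueError):
        compute_yield_proportion(-1, 0, 5)


def test_make_day_table_excludes_unlabelled(toy_tables):
    r = toy_tables.retrievals.copy()
    r.loc[len(r)] = retrieval_row(patient_id="C", transfer_day_label="none",
                                  n_blastocysts_frozen=np.nan)
    day = make_day_table(type(toy_tables)(r, toy_tables.transfers))
    assert set(day["patient_id"]) == {"A", "B"}
    assert set(day["day5"]) == {0, 1}


def test_make_yield_table_counts(toy_tables):
    y = make_yield_table(toy_tables).set_index(["patient_id", "cycle_index"])
    # A cycle 1: 2 transferred + 3 frozen of 12; A cycle 2: 1 + 1 of 8
    assert y.loc[("A", 1), "n_usable_blastocysts"] == 5
    assert y.loc[("A", 1), "yield_proportion"] == pytest.approx(5 / 12)
    assert y.loc[("A", 2), "n_usable_blastocysts"] == 2
    assert ("B", 1) not in y.index  # day-3 cycle has no yield outcome


def test_make_yield_table_freeze_all_cycle():
    tables = make_tables([retrieval_row(patient_id="F", n_oocytes_retrieved=10,
                                        n_blastocysts_frozen=4.0)])
    y = make_yield_table(tables)
    assert y.loc[0, "n_usable_blastocysts"] == 4
    assert y.loc[0, "yield_proportion"] == pytest.approx(0.4)


def test_courses_stop_at_first_live_birth():
    tables = make_tables(
        [retrieval_row(patient_id="A", n_oocytes_retrieved=20, n_blastocysts_frozen=6.0),
         retrieval_row(patient_id="B", n_oocytes_retrieved=20, n_blastocysts_frozen=6.0),
         retrieval_row(patient_id="C", n_oocytes_retrieved=20, n_blastocysts_frozen=6.0)],
        [
            # A: (2, no birth), (1, birth), then a post-birth transfer not counted
            transfer_row(patient_id="A", transfer_index=1, n_embryos_transferred=2),
            transfer_row(patient_id="A", transfer_index=2, n_embryos_transferred=1, live_birth=True),
            transfer_row(patient_id="A", transfer_index=3, n_embryos_transferred=2),
            # B: censored after (2, no), (2, no)
            transfer_row(patient_id="B", transfer_index=1, n_embryos_transferred=2),
            transfer_row(patient_id="B", transfer_index=2, n_embryos_transferred=2),
            # C: immediate birth
            transfer_row(patient_id="C", transfer_index=1, n_embryos_transferred=1, live_birth=True),
        ],
    )
    c = build_patient_courses(tables).set_index("patient_id")
    assert c.loc["A", "total_blastocysts_transferred"] == 3
    assert c.loc["A", "event"] == 1
    assert c.loc["B", "total_blastocysts_transferred"] == 4
    assert c.loc["B", "event"] == 0
    assert c.loc["C", "total_blastocysts_transferred"] == 1
    assert c.loc["C", "event"] == 1


def test_courses_ignore_day3_transfers():
    tables = make_tables(
        [retrieval_row(patient_id="A", transfer_day_label="day3",
                       n_blastocysts_frozen=np.nan)],
        [transfer_row(patient_id="A", transfer_day_label="day3",
                      n_embryos_transferred=3, live_birth=True)],
    )
    assert len(build_patient_courses(tables)) == 0
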