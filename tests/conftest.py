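"""Shared fixtures: one large default cohort (fitted once per session) and
small handcrafted registries for structural tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fertiopt import (
    FittedModelSet,
    RegistryTables,
    apply_eligibility,
    default_config,
    fit_aft_model,
    fit_day_model,
    fit_yield_model,
    simulate_cohort,
)
from fertiopt.cohort_prep import build_patient_courses, make_day_table, make_yield_table


@pytest.fixture(scope="session")
def default_cohort():
    """The shipped default calibration at n=100 000 (acceptance-scale)."""
    return simulate_cohort(default_config())


@pytest.fixture(scope="session")
def eligible(default_cohort):
    tables, _ = default_cohort
    return apply_eligibility(tables)


@pytest.fixture(scope="session")
def fits(eligible):
    """All three models fitted on the eligible default cohort."""
    return FittedModelSet(
        day_model=fit_day_model(make_day_table(eligible)),
        yield_model=fit_yield_model(make_yield_table(eligible)),
        aft_model=fit_aft_model(build_patient_courses(eligible)),
    )


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(default_config(n_patients=3000, seed=77))


def retrieval_row(**kw) -> dict:
    """A valid retrieval record with overridable fields."""
    base = dict(
        patient_id="P0", cycle_index=1, cycle_year=2016, age_years=30.0,
        age_group="<32", region="R00", amh_ng_ml=2.0, dor=False, icsi=False,
        n_oocytes_retrieved=10, donor_oocyte=False, gestational_carrier=False,
        pgt=False, transfer_day_label="day5", n_blastocysts_frozen=2.0,
        bmi=24.0, gravidity=0.0, fsh_miu_ml=7.0,
    )
    base.update(kw)
    return base


def transfer_row(**kw) -> dict:
    base = dict(
        patient_id="P0", retrieval_cycle_index=1, transfer_index=1,
        transfer_day_label="day5", n_embryos_transferred=1, live_birth=False,
    )
    base.update(kw)
    return base


def make_tables(retrievals: list[dict], transfers: list[dict] | None = None) -> RegistryTables:
    r = pd.DataFrame(retrievals)
    t = pd.DataFrame(transfers) if transfers else None
    return RegistryTables(r, t)


@pytest.fixture
def toy_tables() -> RegistryTables:
    """Two patients, one with a day-5 transfer course, one day-3."""
    retrievals = [
        retrieval_row(patient_id="A", cycle_index=1, n_oocytes_retrieved=12,
                      n_blastocysts_frozen=3.0),
        retrieval_row(patient_id="A", cycle_index=2, cycle_year=2017,
                      n_oocytes_retrieved=8, n_blastocysts_frozen=1.0),
        retrieval_row(patient_id="B", cycle_index=1, age_years=40.0,
                      age_group="38-40", amh_ng_ml=np.nan, dor=True,
                      transfer_day_label="day3", n_blastocysts_frozen=np.nan,
                      n_oocytes_retrieved=5),
    ]
    transfers = [
        transfer_row(patient_id="A", retrieval_cycle_index=1, transfer_index=1,
                     n_embryos_transferred=2, live_birth=False),
        transfer_row(patient_id="A", retrieval_cycle_index=2, transfer_index=2,
                     n_embryos_transferred=1, live_birth=True),
        transfer_row(patient_id="B", retrieval_cycle_index=1, transfer_index=1,
                     transfer_day_label="day3", n_embryos_transferred=2,
                     live_birth=False),
    ]
    return make_tables(retrievals, transfers)
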