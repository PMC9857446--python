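"""Eligibility filtering, patient-level splitting and end-point construction.

Three analysis tables are derived from a validated registry:

* the day-of-transfer table (one row per cycle with a realized transfer or
  freeze day) for the stage-1 classifier,
* the blastocyst-yield table (day-5 cycles, successes/trials counts) for
  the stage-2 proportion model, and
* the patient-course table (cumulative blastocysts transferred until the
  first live birth, right-censored) for the stage-2 survival model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fertiopt.core_registry import RegistryTables, derive_amh_bands

logger = logging.getLogger(__name__)

ELIGIBLE_YEARS = (2014, 2019)

#: covariate columns shared by all three models
MODEL_COVARIATES = ("age_group", "region", "amh_band", "dor", "n_oocytes_retrieved")


@dataclass(frozen=True)
class SplitAssignment:
    """Patient-level train/test assignment.

    All cycles of a patient share one label; arm sizes differ by at most one
    (the extra patient goes to train).
    """

    assignment: pd.Series  # index: patient_id, values: "train" | "test"
    split_seed: int

    def patients(self, arm: str) -> pd.Index:
        return self.assignment.index[self.assignment == arm]

    def mask(self, patient_ids: pd.Series, arm: str) -> pd.Series:
        return patient_ids.map(self.assignment).eq(arm)


def apply_eligibility(tables: RegistryTables) -> RegistryTables:
    """Apply the study's inclusion rules; idempotent.

    Retained are cycles of patients whose first stimulation cycle started in
    2014-2019, with at least one oocyte retrieved, excluding donor-oocyte,
    gestational-carrier and preimplantation-genetic-testing cycles.  Per-rule
    exclusion counts are logged.  Transfers of excluded cycles are dropped
    and the remaining transfers re-indexed consecutively per patient.
    """
    r = tables.retrievals
    first = r[r["cycle_index"] == 1].set_index("patient_id")["cycle_year"]
    first_ok = first.between(*ELIGIBLE_YEARS)
    patient_ok = r["patient_id"].map(first_ok).fillna(False).astype(bool)

    rules = {
        "first_cycle_outside_2014_2019": ~patient_ok,
        "zero_oocytes_retrieved": r["n_oocytes_retrieved"] < 1,
        "donor_oocyte": r["donor_oocyte"].astype(bool),
        "gestational_carrier": r["gestational_carrier"].astype(bool),
        "pgt": r["pgt"].astype(bool),
    }
    keep = pd.Series(True, index=r.index)
    counts = {}
    for name, violates in rules.items():
        counts[name] = int((keep & violates).sum())
        keep &= ~violates
    for name, n_excluded in counts.items():
        logger.info("eligibility: excluded %d cycles by rule %s", n_excluded, name)

    kept = r.loc[keep].reset_index(drop=True)
    key = pd.MultiIndex.from_frame(kept[["patient_id", "cycle_index"]])
    t = tables.transfers
    if len(t):
        tkey = pd.MultiIndex.from_frame(t[["patient_id", "retrieval_cycle_index"]])
        t = t.loc[tkey.isin(key)].sort_values(
            ["patient_id", "transfer_index"], kind="mergesort"
        ).reset_index(drop=True)
        t["transfer_index"] = t.groupby("patient_id").cumcount() + 1
    return RegistryTables(kept, t)


def split_patients(tables: RegistryTables, seed: int) -> SplitAssignment:
    """Randomly split patients into equal-sized train and test arms."""
    ids = np.sort(tables.retrievals["patient_id"].unique())
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = (len(ids) + 1) // 2  # odd counts: extra patient to train
    labels = np.empty(len(ids), dtype=object)
    labels[perm[:n_train]] = "train"
    labels[perm[n_train:]] = "test"
    return SplitAssignment(pd.Series(labels, index=pd.Index(ids, name="patient_id"), name="arm"), seed)


def label_transfer_day(day: int) -> str:
    """Collapse a post-fertilization transfer day onto the day3/day5 dichotomy.

    Transfers on day 5 or later count as blastocyst (day 5) transfers;
    days 2-4 count as cleavage-stage (day 3) transfers.
    """
    d = int(day)
    if not (2 <= d <= 7):
        raise ValueError(f"transfer day {day!r} outside the plausible range [2, 7]")
    return "day5" if d >= 5 else "day3"


def compute_yield_proportion(n_transferred_blasts: int, n_frozen_blasts: int, n_retrieved: int) -> float:
    """Usable-blastocyst yield: (transferred + frozen) / retrieved."""
    t, f, r = int(n_transferred_blasts), int(n_frozen_blasts), int(n_retrieved)
    if r < 1:
        raise ValueError("n_retrieved must be >= 1")
    if t < 0 or f < 0:
        raise ValueError("blastocyst counts must be non-negative")
    if t + f > r:
        raise ValueError(f"usable blastocysts ({t}+{f}) exceed oocytes retrieved ({r})")
    return (t + f) / r


def _with_amh_band(r: pd.DataFrame) -> pd.DataFrame:
    out = r.copy()
    out["amh_band"] = derive_amh_bands(out["amh_ng_ml"])
    return out


def make_day_table(tables: RegistryTables) -> pd.DataFrame:
    """Stage-1 table: one row per cycle with a realized day label, outcome ``day5``."""
    r = _with_amh_band(tables.retrievals)
    r = r[r["transfer_day_label"].isin(["day3", "day5"])].reset_index(drop=True)
    r["day5"] = (r["transfer_day_label"] == "day5").astype(int)
    return r[["patient_id", "cycle_index", *MODEL_COVARIATES, "day5"]]


def make_yield_table(tables: RegistryTables) -> pd.DataFrame:
    """Stage-2 yield table: day-5 cycles with (usable, trials) counts.

    Usable blastocysts are those transferred from the cycle plus those
    frozen; freeze-all cycles (no transfer) therefore keep their outcome.
    """
    r = _with_amh_band(tables.retrievals)
    r = r[r["transfer_day_label"] == "day5"].reset_index(drop=True)
    t = tables.transfers
    if len(t):
        per_cycle = (
            t[t["transfer_day_label"] == "day5"]
            .groupby(["patient_id", "retrieval_cycle_index"])["n_embryos_transferred"]
            .sum()
        )
        key = pd.MultiIndex.from_frame(r[["patient_id", "cycle_index"]])
        transferred = pd.Series(per_cycle.reindex(key).fillna(0).to_numpy(), index=r.index)
    else:
        transferred = pd.Series(0, index=r.index)
    frozen = r["n_blastocysts_frozen"].fillna(0)
    usable = (transferred + frozen).astype(int)
    bad = usable > r["n_oocytes_retrieved"]
    if bad.any():
        raise ValueError(f"{int(bad.sum())} day-5 cycles have usable blastocysts exceeding oocytes retrieved")
    out = r[["patient_id", "cycle_index", *MODEL_COVARIATES]].copy()
    out["n_usable_blastocysts"] = usable
    out["yield_proportion"] = usable / r["n_oocytes_retrieved"]
    return out


def build_patient_courses(tables: RegistryTables) -> pd.DataFrame:
    """Patient-level censored end point for the survival model.

    Per patient, day-5 transfers are walked in treatment order, accumulating
    blastocysts transferred; the walk stops at the first live birth
    (``event=1``) or at the end of the record (``event=0``, right-censored).
    Blastocysts transferred after the first live birth are not counted.
    Covariates are taken from the patient's first day-5 retrieval cycle.
    Patients with no day-5 transfer contribute no course.
    """
    t = tables.transfers
    r = _with_amh_band(tables.retrievals)
    if len(t) == 0:
        return pd.DataFrame(columns=["patient_id", "total_blastocysts_transferred", "event", *MODEL_COVARIATES])
    unknown = set(t["patient_id"]) - set(r["patient_id"])
    if unknown:
        raise ValueError(f"transfers reference unknown patients: {sorted(unknown)[:5]}")

    d5 = t[t["transfer_day_label"] == "day5"].sort_values(
        ["patient_id", "transfer_index"], kind="mergesort"
    )
    if len(d5) == 0:
        return pd.DataFrame(columns=["patient_id", "total_blastocysts_transferred", "event", *MODEL_COVARIATES])

    grp = d5.groupby("patient_id", sort=True)
    # cumulative blastocysts; stop at (and include) the first live birth
    birth_rank = grp["live_birth"].cumsum()
    before_or_at_first = (birth_rank < 1) | ((birth_rank == 1) & d5["live_birth"])
    counted = d5[before_or_at_first]
    g2 = counted.groupby("patient_id", sort=True)
    time = g2["n_embryos_transferred"].sum()
    event = g2["live_birth"].any()

    first_d5 = r[r["transfer_day_label"] == "day5"].sort_values(
        ["patient_id", "cycle_index"], kind="mergesort"
    ).groupby("patient_id", sort=True).first()
    cov = first_d5.reindex(time.index)[list(MODEL_COVARIATES)]
    # a day-5 transfer implies a day-5 retrieval; fall back to the first
    # retrieval of any kind if labels disagree (external data)
    missing = cov["age_group"].isna()
    if missing.any():
        any_first = r.sort_values(["patient_id", "cycle_index"], kind="mergesort").groupby(
            "patient_id", sort=True).first()
        cov.loc[missing] = any_first.reindex(cov.index[missing])[list(MODEL_COVARIATES)]

    out = cov.reset_index()
    out["total_blastocysts_transferred"] = time.to_numpy()
    out["event"] = event.to_numpy().astype(int)
    out = out[out["total_blastocysts_transferred"] >= 1].reset_index(drop=True)
    return out[["patient_id", "total_blastocysts_transferred", "event", *MODEL_COVARIATES]]
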