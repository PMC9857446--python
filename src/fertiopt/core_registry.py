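"""Domain types, validation and delimited-text I/O for the cycle registry.

The registry mirrors the structure of a national ART outcome reporting
system: one table of oocyte-retrieval cycles and one table of embryo
transfers, linked by an opaque patient identifier.  Both tables are plain
UTF-8 CSV with a header row; the column dictionary is documented in
``docs/column_dictionary.md`` and enforced here.

Tables are held as :class:`pandas.DataFrame` with fixed dtypes; the record
types described below are row schemas, not Python objects.

Retrievals columns
------------------
patient_id : str
    Opaque identifier.
cycle_index : int
    1 = first stimulation cycle, in treatment order.
cycle_year : int
    Calendar year the stimulation cycle started.
age_years : float
    Age at cycle start, study range 18-45.
age_group : str
    One of ``<32, 32-34, 35-37, 38-40, 41-42, >42`` (derivable from
    ``age_years``).
region : str
    Categorical clinic state/region label.
amh_ng_ml : float
    Latest anti-mullerian hormone, ng/mL; missing allowed (empty field).
dor : bool
    Diminished ovarian reserve diagnosis.
icsi : bool
    Intracytoplasmic sperm injection cycle.
n_oocytes_retrieved : int
    Non-negative count (>= 1 for eligible cycles).
donor_oocyte, gestational_carrier, pgt : bool
    Exclusion flags.
transfer_day_label : str
    ``day3``, ``day5`` (transfer or freeze on that day) or ``none``.
n_blastocysts_frozen : float (nullable int)
    Defined only for day5 cycles; missing otherwise.
bmi, gravidity, fsh_miu_ml : optional descriptive fields.

Transfers columns
-----------------
patient_id : str
retrieval_cycle_index : int
transfer_index : int
    Consecutive from 1 within each patient, in treatment order.
transfer_day_label : str  (``day3`` or ``day5``)
n_embryos_transferred : int  (positive)
live_birth : bool
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Ordered age strata; intervals are [18,32), [32,35), [35,38), [38,41),
#: [41,43), [43,45] so integer ages land in the conventionally labelled bins.
AGE_GROUPS: tuple[str, ...] = ("<32", "32-34", "35-37", "38-40", "41-42", ">42")
_AGE_EDGES = (18.0, 32.0, 35.0, 38.0, 41.0, 43.0, 45.0)

#: AMH bands; missingness is a first-class category (about a third of real
#: registry cycles have no AMH on record), so models never impute.
AMH_BANDS: tuple[str, ...] = ("unknown", "<1", "1-<4", ">=4")

DAY_LABELS: tuple[str, ...] = ("day3", "day5", "none")

RETRIEVAL_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "cycle_index",
    "cycle_year",
    "age_years",
    "age_group",
    "region",
    "amh_ng_ml",
    "dor",
    "icsi",
    "n_oocytes_retrieved",
    "donor_oocyte",
    "gestational_carrier",
    "pgt",
    "transfer_day_label",
    "n_blastocysts_frozen",
    "bmi",
    "gravidity",
    "fsh_miu_ml",
)

TRANSFER_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "retrieval_cycle_index",
    "transfer_index",
    "transfer_day_label",
    "n_embryos_transferred",
    "live_birth",
)

_BOOL_RETRIEVAL = ("dor", "icsi", "donor_oocyte", "gestational_carrier", "pgt")
_INT_RETRIEVAL = ("cycle_index", "cycle_year", "n_oocytes_retrieved")
_FLOAT_RETRIEVAL = ("age_years", "amh_ng_ml", "n_blastocysts_frozen", "bmi", "gravidity", "fsh_miu_ml")


class SchemaError(ValueError):
    """A table is missing a required column or violates an invariant."""


class RegistryParseError(ValueError):
    """A delimited file contains a value that cannot be parsed."""


def derive_age_group(age_years: float) -> str:
    """Map an age in years onto its stratum label.

    The map is total, piecewise constant and monotone on [18, 45]; ages
    outside the study range raise ``ValueError``.
    """
    a = float(age_years)
    if not (18.0 <= a <= 45.0):
        raise ValueError(f"age_years={age_years!r} outside the study range [18, 45]")
    idx = int(np.searchsorted(_AGE_EDGES[1:-1], a, side="right"))
    return AGE_GROUPS[idx]


def derive_amh_band(amh_ng_ml: float | None) -> str:
    """Band an AMH concentration; NaN/None map to ``unknown``."""
    if amh_ng_ml is None or (isinstance(amh_ng_ml, float) and np.isnan(amh_ng_ml)):
        return "unknown"
    v = float(amh_ng_ml)
    if v < 0:
        raise ValueError(f"amh_ng_ml={amh_ng_ml!r} is negative")
    if v < 1.0:
        return "<1"
    if v < 4.0:
        return "1-<4"
    return ">=4"


def derive_amh_bands(amh: pd.Series) -> pd.Series:
    """Vectorized :func:`derive_amh_band` over a float Series."""
    vals = amh.to_numpy(dtype=float)
    out = np.full(len(vals), "unknown", dtype=object)
    known = ~np.isnan(vals)
    out[known & (vals < 1.0)] = "<1"
    out[known & (vals >= 1.0) & (vals < 4.0)] = "1-<4"
    out[known & (vals >= 4.0)] = ">=4"
    return pd.Series(out, index=amh.index, name="amh_band")


@dataclass
class RegistryTables:
    """The two registry tables plus validation.

    Invariants checked by :meth:`validate`:

    * required columns present with parseable dtypes,
    * every transfer's ``patient_id`` appears in ``retrievals``,
    * ``age_group`` consistent with ``age_years``,
    * ``n_blastocysts_frozen <= n_oocytes_retrieved`` where defined,
    * ``transfer_index`` consecutive from 1 within each patient.
    """

    retrievals: pd.DataFrame
    transfers: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.transfers is None or (isinstance(self.transfers, pd.DataFrame) and self.transfers.empty and len(self.transfers.columns) == 0):
            self.transfers = pd.DataFrame({c: pd.Series(dtype=object) for c in TRANSFER_COLUMNS})
        self.validate()

    def validate(self) -> "RegistryTables":
        for col in RETRIEVAL_COLUMNS:
            if col not in self.retrievals.columns:
                raise SchemaError(f"retrievals table is missing required column {col!r}")
        for col in TRANSFER_COLUMNS:
            if col not in self.transfers.columns:
                raise SchemaError(f"transfers table is missing required column {col!r}")
        r, t = self.retrievals, self.transfers
        if len(r):
            bad_day = ~r["transfer_day_label"].isin(DAY_LABELS)
            if bad_day.any():
                raise SchemaError(
                    f"unknown transfer_day_label values: {sorted(r.loc[bad_day, 'transfer_day_label'].unique())}"
                )
            ages = r["age_years"].to_numpy(dtype=float)
            if np.any(ages < 18.0) or np.any(ages > 45.0):
                raise SchemaError("age_years outside the study range [18, 45]")
            idx = np.searchsorted(_AGE_EDGES[1:-1], ages, side="right")
            expected = np.asarray(AGE_GROUPS, dtype=object)[idx]
            if (expected != r["age_group"].to_numpy(dtype=object)).any():
                raise SchemaError("age_group inconsistent with age_years for some rows")
            frozen = r["n_blastocysts_frozen"]
            over = frozen.notna() & (frozen > r["n_oocytes_retrieved"])
            if over.any():
                raise SchemaError("n_blastocysts_frozen exceeds n_oocytes_retrieved for some rows")
            if (r["n_oocytes_retrieved"] < 0).any():
                raise SchemaError("negative n_oocytes_retrieved")
        if len(t):
            unknown = ~t["patient_id"].isin(set(r["patient_id"]))
            if unknown.any():
                raise SchemaError(
                    f"{int(unknown.sum())} transfer rows reference patient_ids absent from retrievals"
                )
            ts = t.sort_values(["patient_id", "transfer_index"], kind="mergesort")
            codes = pd.factorize(ts["patient_id"].to_numpy())[0]
            ti = ts["transfer_index"].to_numpy(dtype=np.int64)
            first_of_group = np.ones(len(ts), dtype=bool)
            first_of_group[1:] = codes[1:] != codes[:-1]
            if not (ti[first_of_group] == 1).all():
                raise SchemaError("transfer_index does not start at 1 for some patients")
            within = ~first_of_group
            if not (np.diff(ti)[within[1:]] == 1).all():
                raise SchemaError("transfer_index not consecutive within some patients")
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegistryTables):
            return NotImplemented
        return registry_tables_equal(self, other)


def registry_tables_equal(a: RegistryTables, b: RegistryTables) -> bool:
    """Value equality of two registries, tolerant of row order and index."""

    def _norm(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        return df.sort_values(keys).reset_index(drop=True)

    ra = _norm(a.retrievals[list(RETRIEVAL_COLUMNS)], ["patient_id", "cycle_index"])
    rb = _norm(b.retrievals[list(RETRIEVAL_COLUMNS)], ["patient_id", "cycle_index"])
    ta = _norm(a.transfers[list(TRANSFER_COLUMNS)], ["patient_id", "transfer_index"])
    tb = _norm(b.transfers[list(TRANSFER_COLUMNS)], ["patient_id", "transfer_index"])
    try:
        pd.testing.assert_frame_equal(ra, rb, check_dtype=False)
        pd.testing.assert_frame_equal(ta, tb, check_dtype=False)
    except AssertionError:
        return False
    return True


def _coerce_retrievals(df: pd.DataFrame, path: str) -> pd.DataFrame:
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    for col in _INT_RETRIEVAL:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.argmax(bad.isna().to_numpy())) + 2  # +2: header + 1-based
            raise RegistryParseError(f"{path}: non-numeric value in column {col!r} near line {row}") from exc
    for col in _FLOAT_RETRIEVAL:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in _BOOL_RETRIEVAL:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64).astype(bool)
    df["age_group"] = df["age_group"].astype(str)
    df["region"] = df["region"].astype(str)
    df["transfer_day_label"] = df["transfer_day_label"].astype(str)
    return df


def _coerce_transfers(df: pd.DataFrame, path: str) -> pd.DataFrame:
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    for col in ("retrieval_cycle_index", "transfer_index", "n_embryos_transferred"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise RegistryParseError(f"{path}: non-numeric value in column {col!r}") from exc
    df["live_birth"] = pd.to_numeric(df["live_birth"], errors="raise").astype(np.int64).astype(bool)
    df["transfer_day_label"] = df["transfer_day_label"].astype(str)
    return df


def read_registry(retrievals_path: str | Path, transfers_path: str | Path) -> RegistryTables:
    """Read and validate the two registry CSV files.

    Missing AMH is represented by an empty field in the file and NaN in
    memory — never by 0.
    """
    retrievals_path, transfers_path = Path(retrievals_path), Path(transfers_path)
    r = pd.read_csv(retrievals_path, dtype=object, keep_default_na=True)
    t = pd.read_csv(transfers_path, dtype=object, keep_default_na=True)
    for col in RETRIEVAL_COLUMNS:
        if col not in r.columns:
            raise SchemaError(f"{retrievals_path}: missing required column {col!r}")
    for col in TRANSFER_COLUMNS:
        if col not in t.columns:
            raise SchemaError(f"{transfers_path}: missing required column {col!r}")
    return RegistryTables(_coerce_retrievals(r, str(retrievals_path)), _coerce_transfers(t, str(transfers_path)))


def write_registry(tables: RegistryTables, retrievals_path: str | Path, transfers_path: str | Path) -> None:
    """Write both tables as CSV; missing values become empty fields."""
    tables.validate()
    r = tables.retrievals[list(RETRIEVAL_COLUMNS)].copy()
    for col in _BOOL_RETRIEVAL:
        r[col] = r[col].astype(int)
    t = tables.transfers[list(TRANSFER_COLUMNS)].copy()
    if len(t):
        t["live_birth"] = t["live_birth"].astype(int)
    r.to_csv(retrievals_path, index=False, float_format="%.6g")
    t.to_csv(transfers_path, index=False)
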