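"""Synthetic ART registry generator with retained ground truth.

The national registry this package targets is access-restricted, so model
development is exercised on simulated cohorts whose marginal behaviour is
calibrated to the published cohort characteristics: the share of day-5
transfer-or-freeze cycles, oocyte-count medians overall and by transfer day,
the usable-blastocyst yield distribution among day-5 cycles, and per-transfer
live-birth fractions by transfer day.

The generative cascade mirrors the modelling cascade it is meant to test:

* patient covariates: age stratum -> age, clinic region, AMH (log-normal,
  with missingness), diminished-ovarian-reserve diagnosis (logistic in age
  and AMH band), oocytes retrieved (truncated negative binomial), ICSI flag;
* a latent day-5 probability from true logistic coefficients beta*, realized
  as the cycle's transfer-day label;
* for day-5 cycles, a usable-blastocyst count that is beta-binomial in the
  retrieved-oocyte denominator with logit-linear mean gamma* (the wide
  published yield IQR implies overdispersion beyond binomial);
* sequential embryo transfers consuming the cycle's blastocysts (day 5) or
  cleavage-stage embryos (day 3), each a Bernoulli live birth with
  age-dependent odds, stopped by the first live birth, supply exhaustion,
  or per-cycle dropout (the source of right-censoring);
* an optional second stimulation cycle for patients who exhausted their
  supply without a live birth and did not drop out.

Clinic-region effects are mean-zero Gaussian offsets on each linear
predictor.  All randomness derives from one master seed via named
substreams keyed by (variable, cycle, transfer number), each drawn as a
single array, so the first k patients of any cohort are identical across
cohort sizes.

The realized true coefficients (reference-coded exactly as the fitting
modules code their design matrices) and per-cycle latent probabilities are
returned as :class:`GroundTruth` to support parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit, logit

from fertiopt.core_registry import (
    AGE_GROUPS,
    AMH_BANDS,
    RETRIEVAL_COLUMNS,
    TRANSFER_COLUMNS,
    RegistryTables,
    derive_amh_bands,
)

_AGE_BOUNDS = ((18.0, 32.0), (32.0, 35.0), (35.0, 38.0), (38.0, 41.0), (41.0, 43.0), (43.0, 45.0))

# substream identifiers (order is part of the reproducibility contract)
_V = {
    "age_group": 1,
    "age_within": 2,
    "region": 3,
    "amh": 4,
    "amh_missing": 5,
    "dor": 6,
    "icsi": 7,
    "year": 8,
    "donor": 9,
    "carrier": 10,
    "pgt": 11,
    "bmi": 12,
    "gravidity": 13,
    "fsh": 14,
    "fsh_missing": 15,
    "region_effects": 16,
    "oocytes": 20,
    "day5": 21,
    "yield_beta": 22,
    "blasts": 23,
    "day3_supply": 24,
    "retry": 25,
    "cancel": 26,
    "transfer_size": 30,
    "live_birth": 31,
    "dropout": 32,
}


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the shipped calibration.

    Age-group-indexed tuples follow the stratum order ``<32 .. >42``.
    AMH-band dictionaries are keyed by ``unknown, <1, 1-<4, >=4``.
    Logistic-scale coefficients are log-odds; ``*_age`` entries are offsets
    relative to the youngest stratum.
    """

    n_patients: int = 100_000
    seed: int = 2014

    # covariate marginals
    age_group_probs: tuple = (0.26295, 0.23468, 0.21877, 0.16561, 0.07233, 0.04566)
    region_count: int = 8
    amh_log_loc: tuple = (1.16, 0.96, 0.69, 0.34, 0.00, -0.36)  # ln ng/mL by age group
    amh_log_scale: float = 0.85
    amh_missing_prob: float = 0.35
    dor_intercept: float = -2.2
    dor_age: tuple = (0.0, 0.3, 0.7, 1.2, 1.7, 2.1)
    dor_amh: dict = field(default_factory=lambda: {"unknown": 0.0, "<1": 1.9, "1-<4": -0.5, ">=4": -2.0})
    icsi_prob: float = 0.735
    donor_prob: float = 0.015
    carrier_prob: float = 0.005
    pgt_prob: float = 0.08
    year_range: tuple = (2014, 2019)

    # oocytes retrieved: truncated (>=1) negative binomial, log mean
    ooc_intercept: float = 2.62
    ooc_age: tuple = (0.0, -0.05, -0.14, -0.30, -0.48, -0.65)
    ooc_amh: dict = field(default_factory=lambda: {"unknown": 0.0, "<1": -0.45, "1-<4": 0.10, ">=4": 0.35})
    ooc_dor: float = -0.50
    ooc_dispersion: float = 3.8  # negative-binomial size (shape)
    ooc_max: int = 60

    # cycles cancelled before fertilization or converted to oocyte banking:
    # no transfer and nothing frozen, label "none"; the real registry's
    # day-3/day-5 strata likewise cover only ~80% of retrieval cycles.
    # Drawn independently of the day-5 coin so the day-of-transfer logistic
    # stays exactly recoverable from the labelled cycles.
    cancel_intercept: float = 0.55
    cancel_per_oocyte: float = -0.25

    # true day-5 logistic coefficients beta*
    day5_intercept: float = 0.42
    day5_age: tuple = (0.0, -0.26, -0.44, -0.62, -0.74, -0.80)
    day5_amh: dict = field(default_factory=lambda: {"unknown": 0.0, "<1": -0.50, "1-<4": 0.20, ">=4": 0.50})
    day5_dor: float = -0.60
    day5_per_oocyte: float = 0.095
    region_scale_day5: float = 0.15

    # true usable-blastocyst yield coefficients gamma* (logit of the
    # beta-binomial mean) and intra-cycle correlation rho
    yield_intercept: float = -0.645
    yield_age: tuple = (0.0, -0.05, -0.12, -0.22, -0.35, -0.50)
    yield_amh: dict = field(default_factory=lambda: {"unknown": 0.0, "<1": -0.10, "1-<4": 0.02, ">=4": 0.08})
    yield_dor: float = -0.10
    yield_per_oocyte: float = -0.005
    yield_overdispersion: float = 0.06
    region_scale_yield: float = 0.08

    # transfer policy
    lb_day5_prob_age: tuple = (0.506, 0.466, 0.417, 0.342, 0.232, 0.131)  # per-transfer live-birth prob
    lb_day3_prob_age: tuple = (0.322, 0.292, 0.262, 0.223, 0.153, 0.094)
    region_scale_livebirth: float = 0.10
    two_blast_prob_age: tuple = (0.15, 0.18, 0.25, 0.35, 0.50, 0.60)  # P(2 blastocysts/transfer), day 5
    three_embryo_prob_age: tuple = (0.25, 0.28, 0.30, 0.35, 0.40, 0.45)  # P(3 embryos/transfer), day 3
    day3_embryo_rate: float = 0.35  # cleavage-embryo supply per retrieved oocyte
    dropout_prob: float = 0.15  # per failed transfer; drives right-censoring
    retry_prob: float = 0.55  # second stimulation cycle after exhaustion w/o birth
    max_transfers: int = 12

    # ICSI maturity adjustment carried through to the recommendation rule
    maturity_fraction: float = 0.70

    def validate(self) -> "SimulationConfig":
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        p = np.asarray(self.age_group_probs, dtype=float)
        if len(p) != 6 or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("age_group_probs must be 6 non-negative values summing to 1")
        for name in ("amh_log_scale", "ooc_dispersion", "yield_overdispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("amh_missing_prob", "icsi_prob", "dropout_prob", "retry_prob",
                     "donor_prob", "carrier_prob", "pgt_prob", "day3_embryo_rate",
                     "maturity_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("lb_day5_prob_age", "lb_day3_prob_age", "two_blast_prob_age", "three_embryo_prob_age"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != 6 or ((arr <= 0) | (arr >= 1)).any():
                raise ValueError(f"{name} must be 6 probabilities in (0, 1)")
        if self.region_count < 2:
            raise ValueError("region_count must be >= 2")
        if not self.yield_overdispersion < 1.0:
            raise ValueError("yield_overdispersion (intra-cycle correlation) must be < 1")
        return self

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        fields = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown simulation-config keys: {sorted(unknown)}")
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d).validate()


def default_config(n_patients: int = 100_000, seed: int = 2014) -> SimulationConfig:
    """The shipped calibration (see the methods note for its provenance)."""
    return SimulationConfig(n_patients=n_patients, seed=seed).validate()


@dataclass
class GroundTruth:
    """Realized generator truth for recovery tests.

    ``day5_coefs`` / ``yield_coefs`` are the true coefficients expressed in
    the same reference coding the fitting modules use (youngest age group,
    first region, AMH ``unknown`` and no-DOR as references), including the
    realized region contrasts, so each can be compared term by term with a
    fitted coefficient vector.  ``latents`` carries one row per retrieval
    cycle with the true day-5 probability and, for day-5 cycles, the true
    expected yield proportion.
    """

    day5_coefs: pd.Series
    yield_coefs: pd.Series
    yield_overdispersion: float
    lb_day5_prob_age: tuple
    lb_day3_prob_age: tuple
    dropout_prob: float
    maturity_fraction: float
    region_effects: pd.DataFrame  # columns: region, day5, yield, live_birth
    latents: pd.DataFrame  # patient_id, cycle_index, p_day5_true, yield_p_true

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "day5_coefs": {k: float(v) for k, v in self.day5_coefs.items()},
            "yield_coefs": {k: float(v) for k, v in self.yield_coefs.items()},
            "yield_overdispersion": float(self.yield_overdispersion),
            "lb_day5_prob_age": list(map(float, self.lb_day5_prob_age)),
            "lb_day3_prob_age": list(map(float, self.lb_day3_prob_age)),
            "dropout_prob": float(self.dropout_prob),
            "maturity_fraction": float(self.maturity_fraction),
        }
        (directory / "ground_truth.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
        self.region_effects.to_csv(directory / "region_effects.csv", index=False)
        self.latents.to_csv(directory / "latents.csv", index=False, float_format="%.6g")


def _reference_coded(intercept: float, age: tuple, amh: dict, dor: float,
                     per_oocyte: float, region_u: np.ndarray, region_labels: list[str]) -> pd.Series:
    coefs = {"intercept": intercept + region_u[0]}
    for g, b in zip(AGE_GROUPS[1:], age[1:]):
        coefs[f"age_group[{g}]"] = b
    for r, lab in enumerate(region_labels[1:], start=1):
        coefs[f"region[{lab}]"] = region_u[r] - region_u[0]
    for band in AMH_BANDS[1:]:
        coefs[f"amh_band[{band}]"] = amh[band] - amh["unknown"]
    coefs["intercept"] += amh["unknown"]
    coefs["dor"] = dor
    coefs["n_oocytes_retrieved"] = per_oocyte
    return pd.Series(coefs, dtype=float)


def _truncated_nb(mean: np.ndarray, size: float, u: np.ndarray, upper: int) -> np.ndarray:
    """Inverse-CDF sample of NB(mean, size) truncated to >= 1, capped at upper."""
    prob = size / (size + mean)
    p0 = prob**size
    uu = p0 + (1.0 - p0) * u
    x = stats.nbinom.ppf(np.clip(uu, None, 1.0 - 1e-12), size, prob).astype(np.int64)
    return np.clip(x, 1, upper)


def _band_coef(bands: np.ndarray, table: dict) -> np.ndarray:
    lut = np.array([table[b] for b in AMH_BANDS], dtype=float)
    mapping = {b: i for i, b in enumerate(AMH_BANDS)}
    idx = np.fromiter((mapping[b] for b in bands), dtype=np.int64, count=len(bands))
    return lut[idx]


def _simulate_transfers(cfg: SimulationConfig, seed: int, cycle: int, is_day5: np.ndarray,
                        supply: np.ndarray, age_idx: np.ndarray, lb_region: np.ndarray,
                        active0: np.ndarray):
    """Sequential transfers for one stimulation cycle, vectorized over patients.

    Returns (rows, n_transferred, birth, dropped) where ``rows`` is a list of
    (patient_positions, day5_flag, n_embryos, live_birth) tuples, one per
    transfer round.
    """
    n = len(supply)
    lb5 = np.asarray(cfg.lb_day5_prob_age, dtype=float)[age_idx]
    lb3 = np.asarray(cfg.lb_day3_prob_age, dtype=float)[age_idx]
    p_lb = expit(np.where(is_day5, logit(lb5), logit(lb3)) + lb_region)
    p_two = np.asarray(cfg.two_blast_prob_age, dtype=float)[age_idx]
    p_three = np.asarray(cfg.three_embryo_prob_age, dtype=float)[age_idx]

    remaining = supply.copy()
    active = active0 & (remaining > 0)
    birth = np.zeros(n, dtype=bool)
    dropped = np.zeros(n, dtype=bool)
    n_transferred = np.zeros(n, dtype=np.int64)
    rows = []
    for t in range(cfg.max_transfers):
        if not active.any():
            break
        u_size = _rng(seed, _V["transfer_size"], cycle, t).uniform(size=n)
        u_lb = _rng(seed, _V["live_birth"], cycle, t).uniform(size=n)
        u_drop = _rng(seed, _V["dropout"], cycle, t).uniform(size=n)
        want = np.where(is_day5, 1 + (u_size < p_two), 2 + (u_size < p_three))
        take = np.minimum(want, remaining)
        lb = u_lb < p_lb
        idx = np.flatnonzero(active)
        rows.append((idx, is_day5[idx], take[idx].astype(np.int64), lb[idx]))
        n_transferred[active] += take[active]
        remaining[active] -= take[active]
        birth |= active & lb
        drop_now = active & ~lb & (u_drop < cfg.dropout_prob)
        dropped |= drop_now
        active = active & ~lb & ~drop_now & (remaining > 0)
    return rows, n_transferred, birth, dropped


def _simulate_cycle(cfg: SimulationConfig, seed: int, cycle: int, n: int,
                    age_idx: np.ndarray, amh_band: np.ndarray, dor: np.ndarray,
                    region_idx: np.ndarray, u_day5: np.ndarray, u_yield: np.ndarray,
                    lb_region: np.ndarray, active0: np.ndarray):
    """One stimulation cycle (oocytes -> day label -> blastocysts -> transfers)."""
    # oocytes retrieved: truncated negative binomial
    eta = (cfg.ooc_intercept + np.asarray(cfg.ooc_age)[age_idx]
           + _band_coef(amh_band, cfg.ooc_amh) + cfg.ooc_dor * dor)
    mu = np.exp(eta)
    u = _rng(seed, _V["oocytes"], cycle).uniform(size=n)
    oocytes = _truncated_nb(mu, cfg.ooc_dispersion, u, cfg.ooc_max)

    # latent day-5 probability and realized label
    lp5 = (cfg.day5_intercept + np.asarray(cfg.day5_age)[age_idx]
           + _band_coef(amh_band, cfg.day5_amh) + cfg.day5_dor * dor
           + cfg.day5_per_oocyte * oocytes + u_day5[region_idx])
    p_day5 = expit(lp5)
    is_day5 = _rng(seed, _V["day5"], cycle).uniform(size=n) < p_day5

    # cancellation / oocyte banking: no fertilization attempt, label "none"
    p_cancel = expit(cfg.cancel_intercept + cfg.cancel_per_oocyte * oocytes)
    cancelled = _rng(seed, _V["cancel"], cycle).uniform(size=n) < p_cancel

    # usable blastocysts (day-5 cycles): beta-binomial in the oocyte denominator
    lpy = (cfg.yield_intercept + np.asarray(cfg.yield_age)[age_idx]
           + _band_coef(amh_band, cfg.yield_amh) + cfg.yield_dor * dor
           + cfg.yield_per_oocyte * oocytes + u_yield[region_idx])
    p_yield = expit(lpy)
    rho = cfg.yield_overdispersion
    a = p_yield * (1.0 - rho) / rho
    b = (1.0 - p_yield) * (1.0 - rho) / rho
    fertilized = ~cancelled
    p_cycle = _rng(seed, _V["yield_beta"], cycle).beta(a, b)
    blasts = _rng(seed, _V["blasts"], cycle).binomial(oocytes, p_cycle)
    blasts = np.where(is_day5 & fertilized, blasts, 0)

    # day-3 cleavage-embryo supply (at least one, so the transfer happened)
    supply3 = _rng(seed, _V["day3_supply"], cycle).binomial(oocytes, cfg.day3_embryo_rate)
    supply3 = np.maximum(supply3, 1)
    supply = np.where(is_day5, blasts, np.where(fertilized, supply3, 0))

    rows, n_transferred, birth, dropped = _simulate_transfers(
        cfg, seed, cycle, is_day5, supply, age_idx, lb_region, active0 & fertilized)
    label = np.where(cancelled, "none", np.where(is_day5, "day5", "day3")).astype(object)
    frozen = np.where(is_day5 & fertilized, blasts - n_transferred, np.nan)
    return {
        "oocytes": oocytes, "p_day5": p_day5, "is_day5": is_day5, "label": label,
        "p_yield": p_yield, "blasts": blasts, "frozen": frozen,
        "rows": rows, "n_transferred": n_transferred, "birth": birth, "dropped": dropped,
    }


def simulate_cohort(config: SimulationConfig) -> tuple[RegistryTables, GroundTruth]:
    """Simulate a registry cohort; fully reproducible given ``config.seed``.

    Returns the registry tables together with the realized :class:`GroundTruth`.
    """
    cfg = config.validate()
    n = cfg.n_patients
    seed = cfg.seed

    # ---- patient covariates (shared across stimulation cycles) ----
    cum = np.cumsum(np.asarray(cfg.age_group_probs, dtype=float))
    cum = cum / cum[-1]
    age_idx = np.searchsorted(cum, _rng(seed, _V["age_group"]).uniform(size=n), side="right")
    lo = np.array([b[0] for b in _AGE_BOUNDS])[age_idx]
    hi = np.array([b[1] for b in _AGE_BOUNDS])[age_idx]
    age_years = np.round(lo + (hi - lo) * _rng(seed, _V["age_within"]).uniform(size=n), 1)
    # rounding must not push an age into the next half-open band
    age_years = np.clip(age_years, lo, np.round(hi - 0.1, 1))

    region_idx = _rng(seed, _V["region"]).integers(0, cfg.region_count, size=n)
    region_labels = [f"R{r:02d}" for r in range(cfg.region_count)]

    amh_true = np.exp(np.asarray(cfg.amh_log_loc)[age_idx]
                      + cfg.amh_log_scale * _rng(seed, _V["amh"]).standard_normal(n))
    amh_true = np.round(amh_true, 2)
    missing = _rng(seed, _V["amh_missing"]).uniform(size=n) < cfg.amh_missing_prob
    amh = np.where(missing, np.nan, amh_true)
    amh_band = derive_amh_bands(pd.Series(amh)).to_numpy(dtype=object)

    lp_dor = cfg.dor_intercept + np.asarray(cfg.dor_age)[age_idx] + _band_coef(amh_band, cfg.dor_amh)
    dor = _rng(seed, _V["dor"]).uniform(size=n) < expit(lp_dor)

    icsi = _rng(seed, _V["icsi"]).uniform(size=n) < cfg.icsi_prob
    year = _rng(seed, _V["year"]).integers(cfg.year_range[0], cfg.year_range[1] + 1, size=n)
    donor = _rng(seed, _V["donor"]).uniform(size=n) < cfg.donor_prob
    carrier = _rng(seed, _V["carrier"]).uniform(size=n) < cfg.carrier_prob
    pgt = _rng(seed, _V["pgt"]).uniform(size=n) < cfg.pgt_prob

    # descriptive noise fields (no causal role)
    bmi = np.round(np.exp(3.22 + 0.20 * _rng(seed, _V["bmi"]).standard_normal(n)), 1)
    gravidity = _rng(seed, _V["gravidity"]).poisson(0.95, size=n).astype(float)
    fsh = np.round(np.exp(1.95 + 0.35 * _rng(seed, _V["fsh"]).standard_normal(n)), 1)
    fsh[_rng(seed, _V["fsh_missing"]).uniform(size=n) < 0.30] = np.nan

    # mean-zero region effects per linear predictor
    re_rng = _rng(seed, _V["region_effects"])
    u_day5 = re_rng.standard_normal(cfg.region_count) * cfg.region_scale_day5
    u_yield = re_rng.standard_normal(cfg.region_count) * cfg.region_scale_yield
    u_lb = re_rng.standard_normal(cfg.region_count) * cfg.region_scale_livebirth
    for u in (u_day5, u_yield, u_lb):
        u -= u.mean()
    lb_region = u_lb[region_idx]

    # ---- stimulation cycle 1 for everyone ----
    all_active = np.ones(n, dtype=bool)
    c1 = _simulate_cycle(cfg, seed, 1, n, age_idx, amh_band, dor, region_idx,
                         u_day5, u_yield, lb_region, all_active)

    # ---- optional stimulation cycle 2: exhausted supply, no birth, no dropout ----
    eligible_retry = ~c1["birth"] & ~c1["dropped"]
    retry = eligible_retry & (_rng(seed, _V["retry"]).uniform(size=n) < cfg.retry_prob)
    c2 = _simulate_cycle(cfg, seed, 2, n, age_idx, amh_band, dor, region_idx,
                         u_day5, u_yield, lb_region, retry)

    patient_ids = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    age_group = np.asarray(AGE_GROUPS, dtype=object)[age_idx]
    region = np.asarray(region_labels, dtype=object)[region_idx]

    def _retrieval_frame(c, cycle_index: int, mask: np.ndarray, yr: np.ndarray) -> pd.DataFrame:
        m = mask
        return pd.DataFrame({
            "patient_id": patient_ids[m],
            "cycle_index": cycle_index,
            "cycle_year": yr[m],
            "age_years": age_years[m],
            "age_group": age_group[m],
            "region": region[m],
            "amh_ng_ml": amh[m],
            "dor": dor[m],
            "icsi": icsi[m],
            "n_oocytes_retrieved": c["oocytes"][m],
            "donor_oocyte": donor[m],
            "gestational_carrier": carrier[m],
            "pgt": pgt[m],
            "transfer_day_label": c["label"][m],
            "n_blastocysts_frozen": c["frozen"][m].astype(float),
            "bmi": bmi[m],
            "gravidity": gravidity[m],
            "fsh_miu_ml": fsh[m],
        })

    year2 = np.minimum(year + 1, cfg.year_range[1] + 1)
    retrievals = pd.concat(
        [_retrieval_frame(c1, 1, all_active, year), _retrieval_frame(c2, 2, retry, year2)],
        ignore_index=True,
    ).sort_values(["patient_id", "cycle_index"], kind="mergesort").reset_index(drop=True)

    # ---- long-form transfers with consecutive per-patient transfer_index ----
    parts = []
    for cycle_index, c in ((1, c1), (2, c2)):
        for t, (idx, d5, size, lb) in enumerate(c["rows"], start=1):
            parts.append(pd.DataFrame({
                "patient_id": patient_ids[idx],
                "retrieval_cycle_index": cycle_index,
                "_round": t,
                "transfer_day_label": np.where(d5, "day5", "day3"),
                "n_embryos_transferred": size,
                "live_birth": lb,
            }))
    if parts:
        transfers = pd.concat(parts, ignore_index=True)
        transfers = transfers.sort_values(
            ["patient_id", "retrieval_cycle_index", "_round"], kind="mergesort"
        ).reset_index(drop=True)
        transfers["transfer_index"] = transfers.groupby("patient_id").cumcount() + 1
        transfers = transfers.drop(columns="_round")[list(TRANSFER_COLUMNS)]
    else:
        transfers = pd.DataFrame({c: pd.Series(dtype=object) for c in TRANSFER_COLUMNS})

    tables = RegistryTables(retrievals[list(RETRIEVAL_COLUMNS)], transfers)

    latents = pd.concat([
        pd.DataFrame({
            "patient_id": patient_ids, "cycle_index": 1,
            "p_day5_true": c1["p_day5"],
            "yield_p_true": np.where(c1["label"] == "day5", c1["p_yield"], np.nan),
        }),
        pd.DataFrame({
            "patient_id": patient_ids[retry], "cycle_index": 2,
            "p_day5_true": c2["p_day5"][retry],
            "yield_p_true": np.where(c2["label"][retry] == "day5", c2["p_yield"][retry], np.nan),
        }),
    ], ignore_index=True).sort_values(["patient_id", "cycle_index"], kind="mergesort").reset_index(drop=True)

    truth = GroundTruth(
        day5_coefs=_reference_coded(cfg.day5_intercept, cfg.day5_age, cfg.day5_amh,
                                    cfg.day5_dor, cfg.day5_per_oocyte, u_day5, region_labels),
        yield_coefs=_reference_coded(cfg.yield_intercept, cfg.yield_age, cfg.yield_amh,
                                     cfg.yield_dor, cfg.yield_per_oocyte, u_yield, region_labels),
        yield_overdispersion=cfg.yield_overdispersion,
        lb_day5_prob_age=cfg.lb_day5_prob_age,
        lb_day3_prob_age=cfg.lb_day3_prob_age,
        dropout_prob=cfg.dropout_prob,
        maturity_fraction=cfg.maturity_fraction,
        region_effects=pd.DataFrame({"region": region_labels, "day5": u_day5,
                                     "yield": u_yield, "live_birth": u_lb}),
        latents=latents,
    )
    return tables, truth
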