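"""Combine the three model outputs into a recommended oocyte number.

The rule: if the predicted day-5 probability falls below the threshold the
cycle is treated as a poor-prognosis day-3 cycle and all retrieved oocytes
are exposed to sperm.  Otherwise the expected number of blastocysts needed
for one live birth, B, is divided by the expected usable-blastocyst
proportion p, multiplied by the oocyte maturity fraction m (0.70 for ICSI
cycles, since only mature oocytes are injected) and by the number of
desired children k, and rounded up:

    N = ceil((B / p) * m * k)

If N meets or exceeds the number of oocytes retrieved, all are exposed.
The recommendation can therefore never exceed the retrieved count.

Worked example: B = 4 blastocysts needed at a 40% usable-blastocyst rate in
a conventional-insemination cycle gives ceil(4 / 0.40) = 10 oocytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from fertiopt.core_registry import derive_amh_bands
from fertiopt.day_of_transfer_model import DayModelFit
from fertiopt.blastocyst_yield_model import YieldModelFit, predict_yield
from fertiopt.blastocysts_for_livebirth_model import AFTModelFit, predict_median_blastocysts
from fertiopt.day_of_transfer_model import predict_day5_probability

DEFAULT_MATURITY_FRACTION = 0.70

REASONS = ("predicted_day3", "ratio_ge_retrieved", "ratio_lt_retrieved")


@dataclass(frozen=True)
class Recommendation:
    """One cycle's recommendation with its audit trail."""

    predicted_day: str
    p_day5: float
    yield_p: float | None
    blastocysts_needed_B: float | None
    raw_ratio: float | None
    maturity_factor: float
    desired_children: int
    recommended_n: int
    expose_all: bool
    reason: str


@dataclass
class FittedModelSet:
    """The three fitted sub-models plus shared metadata."""

    day_model: DayModelFit
    yield_model: YieldModelFit
    aft_model: AFTModelFit
    maturity_fraction: float = DEFAULT_MATURITY_FRACTION

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.day_model.to_yaml(directory / "day_model.yaml")
        self.yield_model.to_yaml(directory / "yield_model.yaml")
        self.aft_model.to_yaml(directory / "aft_model.yaml")

    @classmethod
    def load(cls, directory: str | Path,
             maturity_fraction: float = DEFAULT_MATURITY_FRACTION) -> "FittedModelSet":
        directory = Path(directory)
        return cls(
            day_model=DayModelFit.from_yaml(directory / "day_model.yaml"),
            yield_model=YieldModelFit.from_yaml(directory / "yield_model.yaml"),
            aft_model=AFTModelFit.from_yaml(directory / "aft_model.yaml"),
            maturity_fraction=maturity_fraction,
        )


def recommend(p_day5: float, yield_p: float | None, B: float | None, icsi: bool,
              n_retrieved: int, threshold: float = 0.75, desired_children: int = 1,
              maturity_fraction: float = DEFAULT_MATURITY_FRACTION) -> Recommendation:
    """Apply the ceiling-of-ratio rule to one cycle's predictions.

    ``yield_p`` and ``B`` may be ``None`` when ``p_day5`` is below the
    threshold (they are not needed on the day-3 branch).  The desired-children
    multiplier scales the pre-ceiling ratio.
    """
    if not (0.0 <= p_day5 <= 1.0):
        raise ValueError(f"p_day5={p_day5} is not a probability")
    if n_retrieved < 1:
        raise ValueError("n_retrieved must be >= 1")
    if desired_children < 1:
        raise ValueError("desired_children must be >= 1")
    m = maturity_fraction if icsi else 1.0

    if p_day5 < threshold:
        return Recommendation(
            predicted_day="day3", p_day5=float(p_day5), yield_p=None,
            blastocysts_needed_B=None, raw_ratio=None, maturity_factor=m,
            desired_children=int(desired_children), recommended_n=int(n_retrieved),
            expose_all=True, reason="predicted_day3",
        )

    if yield_p is None or B is None:
        raise ValueError("yield_p and B are required for a predicted day-5 cycle")
    if not (0.0 < yield_p <= 1.0):
        raise ValueError(f"yield_p={yield_p} must lie in (0, 1]")
    if B <= 0:
        raise ValueError(f"B={B} must be positive")

    raw_ratio = B / yield_p
    n = math.ceil(raw_ratio * m * desired_children)
    if n >= n_retrieved:
        recommended, expose_all, reason = int(n_retrieved), True, "ratio_ge_retrieved"
    else:
        recommended, expose_all, reason = int(n), False, "ratio_lt_retrieved"
    return Recommendation(
        predicted_day="day5", p_day5=float(p_day5), yield_p=float(yield_p),
        blastocysts_needed_B=float(B), raw_ratio=float(raw_ratio), maturity_factor=m,
        desired_children=int(desired_children), recommended_n=max(recommended, 1),
        expose_all=expose_all, reason=reason,
    )


def _covariate_frame(cycles: pd.DataFrame) -> pd.DataFrame:
    df = cycles.copy()
    if "amh_band" not in df.columns:
        df["amh_band"] = derive_amh_bands(df["amh_ng_ml"])
    return df


def recommend_for_cycle(fits: FittedModelSet, cycle: pd.Series | pd.DataFrame,
                        threshold: float | None = None, desired_children: int = 1) -> Recommendation:
    """Wire the three fitted models into :func:`recommend` for one cycle row."""
    if isinstance(cycle, pd.Series):
        cycle = cycle.to_frame().T
    out = recommend_batch(fits, cycle, threshold=threshold, desired_children=desired_children)
    row = out.iloc[0]
    return Recommendation(
        predicted_day=row["predicted_day"], p_day5=float(row["p_day5"]),
        yield_p=None if pd.isna(row["yield_p"]) else float(row["yield_p"]),
        blastocysts_needed_B=None if pd.isna(row["blastocysts_needed_B"]) else float(row["blastocysts_needed_B"]),
        raw_ratio=None if pd.isna(row["raw_ratio"]) else float(row["raw_ratio"]),
        maturity_factor=float(row["maturity_factor"]),
        desired_children=int(row["desired_children"]),
        recommended_n=int(row["recommended_n"]),
        expose_all=bool(row["expose_all"]), reason=row["reason"],
    )


def recommend_batch(fits: FittedModelSet, cycles: pd.DataFrame,
                    threshold: float | None = None, desired_children: int = 1) -> pd.DataFrame:
    """Vectorized recommendations for a table of retrieval cycles.

    ``cycles`` needs the shared covariate columns (or ``amh_ng_ml`` from
    which the band is derived) plus ``icsi``; the order of rows does not
    affect any individual recommendation.
    """
    tau = fits.day_model.threshold if threshold is None else float(threshold)
    df = _covariate_frame(cycles)
    p5 = predict_day5_probability(fits.day_model, df).to_numpy()
    yp = predict_yield(fits.yield_model, df).to_numpy()
    B = predict_median_blastocysts(fits.aft_model, df).to_numpy()
    icsi = df["icsi"].astype(bool).to_numpy()
    n_ret = df["n_oocytes_retrieved"].astype(int).to_numpy()
    m = np.where(icsi, fits.maturity_fraction, 1.0)

    is_day5 = p5 >= tau
    raw_ratio = np.where(is_day5, B / yp, np.nan)
    n = np.ceil(raw_ratio * m * desired_children)
    fewer = is_day5 & (n < n_ret)
    recommended = np.where(fewer, np.maximum(n, 1), n_ret).astype(int)
    reason = np.where(~is_day5, "predicted_day3",
                      np.where(fewer, "ratio_lt_retrieved", "ratio_ge_retrieved"))
    out = pd.DataFrame({
        "predicted_day": np.where(is_day5, "day5", "day3"),
        "p_day5": p5,
        "yield_p": np.where(is_day5, yp, np.nan),
        "blastocysts_needed_B": np.where(is_day5, B, np.nan),
        "raw_ratio": raw_ratio,
        "maturity_factor": m,
        "desired_children": int(desired_children),
        "recommended_n": recommended,
        "expose_all": ~fewer,
        "reason": reason,
    }, index=cycles.index)
    return out
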