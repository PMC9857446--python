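"""Stage 1: logistic classification of day-5 vs day-3 transfer.

A maximum-likelihood logistic regression of the day-5 indicator on the
shared covariate set, combined with a fixed probability threshold (default
0.75): cycles with predicted day-5 probability below the threshold are
treated as poor-prognosis day-3 cycles for which all retrieved oocytes
should be exposed to sperm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy.special import expit

from fertiopt.design import CovariateLevels, design_matrix

DEFAULT_THRESHOLD = 0.75


class FitError(RuntimeError):
    """Model fitting failed (degenerate outcome, separation or non-convergence)."""


@dataclass
class DayModelFit:
    """Fitted stage-1 classifier."""

    coefficients: pd.Series
    standard_errors: pd.Series
    levels: CovariateLevels
    threshold: float
    n_obs: int
    log_likelihood: float
    converged: bool

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "model": "day_of_transfer_logistic",
            "threshold": float(self.threshold),
            "n_obs": int(self.n_obs),
            "log_likelihood": float(self.log_likelihood),
            "converged": bool(self.converged),
            "levels": self.levels.to_dict(),
            "coefficients": [
                {"name": k, "estimate": float(self.coefficients[k]),
                 "std_error": float(self.standard_errors[k])}
                for k in self.coefficients.index
            ],
        }, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DayModelFit":
        d = yaml.safe_load(Path(path).read_text())
        names = [c["name"] for c in d["coefficients"]]
        return cls(
            coefficients=pd.Series({c["name"]: c["estimate"] for c in d["coefficients"]}, index=names),
            standard_errors=pd.Series({c["name"]: c["std_error"] for c in d["coefficients"]}, index=names),
            levels=CovariateLevels.from_dict(d["levels"]),
            threshold=float(d["threshold"]),
            n_obs=int(d["n_obs"]),
            log_likelihood=float(d["log_likelihood"]),
            converged=bool(d["converged"]),
        )


def fit_day_model(day_table: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> DayModelFit:
    """Fit the logistic day-of-transfer model on a stage-1 training table.

    ``day_table`` needs the shared covariate columns plus a binary ``day5``
    outcome (see :func:`fertiopt.cohort_prep.make_day_table`).  Both outcome
    classes must be present and there must be at least ten observations per
    parameter.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    y = day_table["day5"].astype(int)
    if y.nunique() < 2:
        raise FitError("both day-3 and day-5 outcomes must be present in training data")
    levels = CovariateLevels.from_frame(day_table)
    X = design_matrix(day_table, levels)
    if len(day_table) < 10 * X.shape[1]:
        raise FitError(f"need >= {10 * X.shape[1]} observations for {X.shape[1]} parameters, "
                       f"got {len(day_table)}")
    model = sm.GLM(y.to_numpy(), X.to_numpy(), family=sm.families.Binomial())
    try:
        res = model.fit()
    except Exception as exc:  # perfect separation surfaces as a numerical failure
        raise FitError(f"logistic fit failed: {exc}") from exc
    params = pd.Series(res.params, index=X.columns)
    if not np.isfinite(params).all() or np.abs(params).max() > 50:
        raise FitError("non-finite or diverging coefficients (possible separation)")
    return DayModelFit(
        coefficients=params,
        standard_errors=pd.Series(res.bse, index=X.columns),
        levels=levels,
        threshold=float(threshold),
        n_obs=int(len(day_table)),
        log_likelihood=float(res.llf),
        converged=bool(res.converged),
    )


def predict_day5_probability(fit: DayModelFit, covariates: pd.DataFrame) -> pd.Series:
    """Predicted probability of a day-5 transfer for each covariate row."""
    X = design_matrix(covariates, fit.levels)
    lp = X.to_numpy() @ fit.coefficients.to_numpy()
    return pd.Series(expit(lp), index=covariates.index, name="p_day5")


def classify_day(probability, threshold: float = DEFAULT_THRESHOLD):
    """Threshold a day-5 probability: ``>= threshold`` classifies as day 5."""
    p = np.asarray(probability, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    out = np.where(p >= threshold, "day5", "day3")
    return out.item() if np.isscalar(probability) or p.ndim == 0 else out


def operating_characteristics(fit: DayModelFit, day_table: pd.DataFrame,
                              thresholds) -> pd.DataFrame:
    """Sensitivity/specificity/day-5 classification rate per threshold.

    Sensitivity is the fraction of true day-5 cycles classified day 5;
    specificity the fraction of true day-3 cycles classified day 3.
    """
    if len(day_table) == 0:
        raise ValueError("labelled data must be non-empty")
    p = predict_day5_probability(fit, day_table).to_numpy()
    y = day_table["day5"].astype(bool).to_numpy()
    rows = []
    for tau in np.atleast_1d(np.asarray(thresholds, dtype=float)):
        pred5 = p >= tau
        sens = pred5[y].mean() if y.any() else np.nan
        spec = (~pred5[~y]).mean() if (~y).any() else np.nan
        rows.append({"threshold": float(tau), "sensitivity": float(sens),
                     "specificity": float(spec), "day5_rate": float(pred5.mean())})
    return pd.DataFrame(rows)
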