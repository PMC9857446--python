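"""Stage 2, end point 1: usable-blastocyst yield among day-5 cycles.

The outcome is the count of usable blastocysts (transferred + frozen) out
of the retrieved-oocyte denominator.  Published yield distributions are far
wider than binomial sampling alone allows, so the default family is a
quasi-binomial logit GLM: binomial mean structure with sandwich
(heteroscedasticity-robust) standard errors, plus a Pearson-chi-square
dispersion estimate reported as a diagnostic.  A plain binomial fit is
available for comparison; the two share coefficients and differ only in
their standard errors.
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
from fertiopt.day_of_transfer_model import FitError

FAMILIES = ("quasi-binomial", "binomial")


@dataclass
class YieldModelFit:
    """Fitted stage-2 proportion model (logit link)."""

    coefficients: pd.Series
    standard_errors: pd.Series
    levels: CovariateLevels
    family: str
    dispersion: float  # Pearson-based; 1.0 under pure binomial sampling
    n_obs: int
    converged: bool

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "model": "blastocyst_yield_glm",
            "family": self.family,
            "dispersion": float(self.dispersion),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "levels": self.levels.to_dict(),
            "coefficients": [
                {"name": k, "estimate": float(self.coefficients[k]),
                 "std_error": float(self.standard_errors[k])}
                for k in self.coefficients.index
            ],
        }, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "YieldModelFit":
        d = yaml.safe_load(Path(path).read_text())
        names = [c["name"] for c in d["coefficients"]]
        return cls(
            coefficients=pd.Series({c["name"]: c["estimate"] for c in d["coefficients"]}, index=names),
            standard_errors=pd.Series({c["name"]: c["std_error"] for c in d["coefficients"]}, index=names),
            levels=CovariateLevels.from_dict(d["levels"]),
            family=d["family"],
            dispersion=float(d["dispersion"]),
            n_obs=int(d["n_obs"]),
            converged=bool(d["converged"]),
        )


def fit_yield_model(yield_table: pd.DataFrame, family: str = "quasi-binomial") -> YieldModelFit:
    """Fit the yield GLM on a stage-2 training table.

    ``yield_table`` needs the shared covariates plus ``n_usable_blastocysts``
    and ``n_oocytes_retrieved`` (see
    :func:`fertiopt.cohort_prep.make_yield_table`).  The outcome enters as
    (successes, failures) counts, so cycles with yield exactly 0 or 1 are
    retained, and the fit is implicitly weighted by the number of oocytes.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    if len(yield_table) == 0:
        raise FitError("no day-5 cycles with a defined yield outcome")
    succ = yield_table["n_usable_blastocysts"].to_numpy(dtype=float)
    trials = yield_table["n_oocytes_retrieved"].to_numpy(dtype=float)
    if (succ > trials).any() or (succ < 0).any():
        raise ValueError("usable blastocysts must lie in [0, oocytes retrieved]")
    if succ.sum() == 0 or (trials - succ).sum() == 0:
        raise FitError("degenerate outcome: all-zero or all-one yields")
    levels = CovariateLevels.from_frame(yield_table)
    X = design_matrix(yield_table, levels)
    endog = np.column_stack([succ, trials - succ])
    model = sm.GLM(endog, X.to_numpy(), family=sm.families.Binomial())
    try:
        # the overdispersion in blastocyst counts is cycle-level (beta-binomial
        # like), i.e. grows with the trial count, so a constant Pearson scale
        # understates coefficient uncertainty; a sandwich covariance does not
        res = model.fit(cov_type="HC1") if family == "quasi-binomial" else model.fit()
    except Exception as exc:
        raise FitError(f"yield GLM failed: {exc}") from exc
    params = pd.Series(res.params, index=X.columns)
    if not np.isfinite(params).all():
        raise FitError("non-finite coefficients in yield GLM")
    pearson_scale = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else np.nan
    return YieldModelFit(
        coefficients=params,
        standard_errors=pd.Series(res.bse, index=X.columns),
        levels=levels,
        family=family,
        dispersion=pearson_scale,
        n_obs=int(len(yield_table)),
        converged=bool(getattr(res, "converged", True)),
    )


def predict_yield(fit: YieldModelFit, covariates: pd.DataFrame) -> pd.Series:
    """Predicted usable-blastocyst proportion, strictly inside (0, 1)."""
    X = design_matrix(covariates, fit.levels)
    lp = X.to_numpy() @ fit.coefficients.to_numpy()
    return pd.Series(expit(lp), index=covariates.index, name="yield_p")
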