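"""Stage 2, end point 2: blastocysts transferred until the first live birth.

The per-patient outcome is the cumulative number of blastocysts transferred
across treatment cycles until the first live birth; patients whose record
ends without a live birth are right-censored.  A parametric accelerated
failure time (AFT) model treats that count as a continuous positive "time":
covariates rescale the time axis, and the patient-specific prediction is
the median of the fitted time distribution.

Three families are supported — Weibull, log-normal and log-logistic — and
by default the family is chosen by lowest AIC on the training data.  The
conditional medians have closed forms:

* log-normal:    median = exp(mu),            mu = x'eta
* Weibull:       median = lambda (ln 2)^(1/k), lambda = exp(x'eta), shape k
* log-logistic:  median = alpha,              alpha = exp(x'eta)

Fitting is delegated to lifelines; medians and survival functions are
evaluated from the fitted parameters in-package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from lifelines import LogLogisticAFTFitter, LogNormalAFTFitter, WeibullAFTFitter
from scipy.stats import norm

from fertiopt.design import CovariateLevels, design_matrix
from fertiopt.day_of_transfer_model import FitError

logger = logging.getLogger(__name__)

FAMILIES = ("weibull", "lognormal", "loglogistic")

_FITTERS = {
    "weibull": (WeibullAFTFitter, "lambda_", "rho_"),
    "lognormal": (LogNormalAFTFitter, "mu_", "sigma_"),
    "loglogistic": (LogLogisticAFTFitter, "alpha_", "beta_"),
}


@dataclass
class AFTModelFit:
    """Fitted AFT model.

    ``coefficients`` act on the location (log-time for Weibull/log-logistic
    via ``exp``, directly for log-normal ``mu``); ``scale`` is the family's
    ancillary parameter (Weibull shape k, log-normal sigma, log-logistic
    shape beta), constant across covariates.
    """

    family: str
    coefficients: pd.Series
    standard_errors: pd.Series
    scale: float
    levels: CovariateLevels
    n_obs: int
    n_events: int
    aic: float
    aic_by_family: dict

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "model": "blastocysts_for_livebirth_aft",
            "family": self.family,
            "scale": float(self.scale),
            "n_obs": int(self.n_obs),
            "n_events": int(self.n_events),
            "aic": float(self.aic),
            "aic_by_family": {k: float(v) for k, v in self.aic_by_family.items()},
            "levels": self.levels.to_dict(),
            "coefficients": [
                {"name": k, "estimate": float(self.coefficients[k]),
                 "std_error": float(self.standard_errors[k])}
                for k in self.coefficients.index
            ],
        }, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AFTModelFit":
        d = yaml.safe_load(Path(path).read_text())
        names = [c["name"] for c in d["coefficients"]]
        return cls(
            family=d["family"],
            coefficients=pd.Series({c["name"]: c["estimate"] for c in d["coefficients"]}, index=names),
            standard_errors=pd.Series({c["name"]: c["std_error"] for c in d["coefficients"]}, index=names),
            scale=float(d["scale"]),
            levels=CovariateLevels.from_dict(d["levels"]),
            n_obs=int(d["n_obs"]),
            n_events=int(d["n_events"]),
            aic=float(d["aic"]),
            aic_by_family={k: float(v) for k, v in d.get("aic_by_family", {}).items()},
        )


def _fit_one(family: str, frame: pd.DataFrame):
    fitter_cls, loc_name, anc_name = _FITTERS[family]
    fitter = fitter_cls(fit_intercept=True)
    try:
        fitter.fit(frame, duration_col="_duration", event_col="_event")
    except Exception as exc:
        raise FitError(f"{family} AFT fit failed: {exc}") from exc
    params = fitter.params_
    if not np.isfinite(params.to_numpy()).all():
        raise FitError(f"{family} AFT fit produced non-finite parameters")
    loc = params[loc_name].rename(index={"Intercept": "intercept"})
    se = fitter.standard_errors_[loc_name].rename(index={"Intercept": "intercept"})
    scale = float(np.exp(params[(anc_name, "Intercept")]))
    return fitter, loc, se, scale


def fit_aft_model(courses: pd.DataFrame, family: str = "auto") -> AFTModelFit:
    """Fit the censored blastocyst-count AFT model on patient courses.

    ``courses`` needs the shared covariates plus
    ``total_blastocysts_transferred`` (>= 1) and ``event`` (see
    :func:`fertiopt.cohort_prep.build_patient_courses`).  ``family`` may be
    one of ``weibull | lognormal | loglogistic`` or ``auto`` (lowest AIC).
    """
    if family != "auto" and family not in FAMILIES:
        raise ValueError(f"family must be 'auto' or one of {FAMILIES}")
    if len(courses) == 0:
        raise FitError("no patient courses to fit")
    events = courses["event"].astype(int)
    if events.sum() == 0:
        raise FitError("all courses are censored; at least one live birth is required")
    durations = courses["total_blastocysts_transferred"].astype(float)
    if (durations < 1).any():
        raise ValueError("course times must be >= 1 blastocyst")
    levels = CovariateLevels.from_frame(courses)
    X = design_matrix(courses, levels).drop(columns="intercept")
    frame = X.copy()
    frame["_duration"] = durations.to_numpy()
    frame["_event"] = events.to_numpy()

    candidates = FAMILIES if family == "auto" else (family,)
    fits, aics = {}, {}
    for fam in candidates:
        fits[fam] = _fit_one(fam, frame)
        aics[fam] = float(fits[fam][0].AIC_)
    chosen = min(aics, key=aics.get)
    if family == "auto":
        logger.info("AFT family selected by AIC: %s (AICs: %s)", chosen, aics)
    _, loc, se, scale = fits[chosen]
    order = ["intercept"] + [c for c in X.columns]
    return AFTModelFit(
        family=chosen,
        coefficients=loc.reindex(order),
        standard_errors=se.reindex(order),
        scale=scale,
        levels=levels,
        n_obs=int(len(courses)),
        n_events=int(events.sum()),
        aic=aics[chosen],
        aic_by_family=aics,
    )


def _location(fit: AFTModelFit, covariates: pd.DataFrame) -> np.ndarray:
    X = design_matrix(covariates, fit.levels)
    return X.to_numpy() @ fit.coefficients.reindex(X.columns).to_numpy()


def predict_median_blastocysts(fit: AFTModelFit, covariates: pd.DataFrame) -> pd.Series:
    """Median blastocysts needed for one live birth at each covariate profile."""
    lp = _location(fit, covariates)
    if fit.family == "lognormal":
        med = np.exp(lp)
    elif fit.family == "weibull":
        med = np.exp(lp) * np.log(2.0) ** (1.0 / fit.scale)
    elif fit.family == "loglogistic":
        med = np.exp(lp)
    else:  # pragma: no cover - guarded at construction
        raise ValueError(f"unknown family {fit.family!r}")
    return pd.Series(med, index=covariates.index, name="blastocysts_needed")


def survival_function(fit: AFTModelFit, covariates: pd.DataFrame, t) -> np.ndarray:
    """S(t | x) of the fitted family, for the numerical-inversion cross-check."""
    t = np.asarray(t, dtype=float)
    lp = _location(fit, covariates)
    if fit.family == "lognormal":
        return norm.sf((np.log(t) - lp) / fit.scale)
    if fit.family == "weibull":
        return np.exp(-((t / np.exp(lp)) ** fit.scale))
    if fit.family == "loglogistic":
        return 1.0 / (1.0 + (t / np.exp(lp)) ** fit.scale)
    raise ValueError(f"unknown family {fit.family!r}")
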