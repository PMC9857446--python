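import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from fertiopt import fit_aft_model, predict_median_blastocysts
from fertiopt.blastocysts_for_livebirth_model import (
    FAMILIES,
    AFTModelFit,
    survival_function,
)
from fertiopt.cohort_prep import build_patient_courses
from fertiopt.day_of_transfer_model import FitError

from test_day_model import cov_frame


def lognormal_courses(n=4000, seed=8):
    """Synthetic right-censored courses with known log-normal truth."""
    rng = np.random.default_rng(seed)
    dor = rng.random(n) < 0.4
    ooc = rng.integers(5, 25, n)
    truth = {"intercept": 1.6, "dor": 0.4, "n_oocytes_retrieved": 0.03, "sigma": 0.5}
    mu = truth["intercept"] + truth["dor"] * dor + truth["n_oocytes_retrieved"] * ooc
    t_event = np.exp(mu + truth["sigma"] * rng.standard_normal(n))
    t_censor = np.exp(rng.normal(2.6, 0.7, n))
    obs = np.minimum(t_event, t_censor)
    event = t_event <= t_censor
    keep = obs >= 1
    df = cov_frame(int(keep.sum()), dor=dor[keep], n_oocytes_retrieved=ooc[keep])
    df["total_blastocysts_transferred"] = obs[keep]
    df["event"] = event[keep].astype(int)
    return df, truth


def test_lognormal_parameter_recovery():
    courses, truth = lognormal_courses()
    fit = fit_aft_model(courses, family="lognormal")
    for term in ("intercept", "dor", "n_oocytes_retrieved"):
        z = (fit.coefficients[term] - truth[term]) / fit.standard_errors[term]
        assert abs(z) < 3, f"{term}: z={z:.2f}"
    assert fit.scale == pytest.approx(truth["sigma"], rel=0.1)


def test_auto_selects_true_family_by_aic():
    courses, _ = lognormal_courses()
    fit = fit_aft_model(courses, family="auto")
    assert fit.family == "lognormal"
    assert set(fit.aic_by_family) == set(FAMILIES)
    assert fit.aic == min(fit.aic_by_family.values())


def test_ignoring_censoring_shrinks_the_median():
    courses, _ = lognormal_courses()
    proper = fit_aft_model(courses, family="lognormal")
    naive = fit_aft_model(courses.assign(event=1), family="lognormal")
    probe = cov_frame(1, n_oocytes_retrieved=15)
    assert (predict_median_blastocysts(naive, probe).iloc[0]
            < predict_median_blastocysts(proper, probe).iloc[0])


@pytest.mark.parametrize("family", FAMILIES)
def test_closed_form_median_matches_survival_inversion(family, eligible):
    courses = build_patient_courses(eligible).head(4000)
    fit = fit_aft_model(courses, family=family)
    probe = courses.drop_duplicates("age_group").head(6)
    med = predict_median_blastocysts(fit, probe).to_numpy()
    for i in range(len(probe)):
        row = probe.iloc[[i]]
        inverted = brentq(
            lambda t: survival_function(fit, row, t)[0] - 0.5, 1e-9, 1e6,
            xtol=1e-12,
        )
        assert abs(med[i] - inverted) < 1e-6


def test_error_paths():
    courses, _ = lognormal_courses(n=300)
    with pytest.raises(ValueError, match="family"):
        fit_aft_model(courses, family="gamma")
    with pytest.raises(FitError, match="no patient courses"):
        fit_aft_model(courses.iloc[:0])
    with pytest.raises(FitError, match="censored"):
        fit_aft_model(courses.assign(event=0))
    with pytest.raises(ValueError, match=">= 1"):
        fit_aft_model(courses.assign(total_blastocysts_transferred=0.5))


def test_yaml_roundtrip(tmp_path):
    courses, _ = lognormal_courses(n=1500)
    fit = fit_aft_model(courses, family="weibull")
    fit.to_yaml(tmp_path / "aft.yaml")
    back = AFTModelFit.from_yaml(tmp_path / "aft.yaml")
    pd.testing.assert_series_equal(back.coefficients, fit.coefficients,
                                   check_names=False)
    assert back.family == fit.family
    assert back.scale == pytest.approx(fit.scale)
    probe = cov_frame(3, n_oocytes_retrieved=[5, 10, 20])
    assert np.allclose(predict_median_blastocysts(back, probe),
                       predict_median_blastocysts(fit, probe))
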