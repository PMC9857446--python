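"""Test-set evaluation: age-group summary tables and oocyte savings.

Mirrors the structure of the published summaries: per age group, the share
of cycles recommended to expose all vs fewer than all retrieved oocytes,
the median (IQR) recommendation among the "fewer" cycles, and the total
number of oocytes spared fertilization.  The published count grid of
recommendations by age group ships with the package so its derived
percentages can be recomputed exactly.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from fertiopt.core_registry import AGE_GROUPS
from fertiopt.day_of_transfer_model import predict_day5_probability
from fertiopt.blastocyst_yield_model import predict_yield
from fertiopt.blastocysts_for_livebirth_model import predict_median_blastocysts


def _quantiles(x: pd.Series) -> tuple[float, float, float]:
    """Median and IQR with linear-interpolation quantiles."""
    if len(x) == 0:
        return (np.nan, np.nan, np.nan)
    q1, med, q3 = np.quantile(np.asarray(x, dtype=float), [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def summarize_by_age(recommendations: pd.DataFrame, cycles: pd.DataFrame) -> pd.DataFrame:
    """Per-age-group recommendation summary.

    ``recommendations`` is the output of
    :func:`fertiopt.recommendation_engine.recommend_batch`, index-aligned
    with ``cycles``.  Percentages are row-normalized within each age group;
    the median (IQR) of the recommended count is computed only over cycles
    recommended fewer than all oocytes, and flagged undefined for empty
    groups.
    """
    df = recommendations.join(cycles[["age_group"]], how="inner")
    rows = []
    for g in AGE_GROUPS:
        sub = df[df["age_group"] == g]
        n_all = int(sub["expose_all"].sum())
        n_fewer = int((~sub["expose_all"]).sum())
        total = n_all + n_fewer
        med, q1, q3 = _quantiles(sub.loc[~sub["expose_all"], "recommended_n"])
        rows.append({
            "age_group": g,
            "expose_all_n": n_all,
            "expose_all_pct": round(100.0 * n_all / total, 1) if total else 0.0,
            "fewer_n": n_fewer,
            "fewer_pct": round(100.0 * n_fewer / total, 1) if total else 0.0,
            "recommended_median": med,
            "recommended_q1": q1,
            "recommended_q3": q3,
            "median_defined": n_fewer > 0,
        })
    return pd.DataFrame(rows)


def oocytes_saved(recommendations: pd.DataFrame, cycles: pd.DataFrame) -> int:
    """Total oocytes spared fertilization under the recommendations.

    Sums ``n_oocytes_retrieved - recommended_n`` over cycles recommended
    fewer than all oocytes; expose-all cycles contribute zero.
    """
    df = recommendations.join(cycles[["n_oocytes_retrieved"]], how="inner")
    fewer = df[df["reason"] == "ratio_lt_retrieved"]
    return int((fewer["n_oocytes_retrieved"] - fewer["recommended_n"]).sum())


def load_published_counts() -> pd.DataFrame:
    """The published 6x2 grid of recommendation counts by age group."""
    with resources.files("fertiopt.data").joinpath("published_recommendation_counts.csv").open() as fh:
        return pd.read_csv(fh)


def aggregate_printed_table2(counts: pd.DataFrame | None = None) -> dict:
    """Derived proportions from a recommendation count grid.

    ``counts`` needs columns ``age_group, expose_all_n, fewer_n`` (defaults
    to the published grid).  Returns the percentage of cycles recommended
    fewer than all oocytes overall and within the under-38 strata, rounded
    to one decimal.
    """
    if counts is None:
        counts = load_published_counts()
    c = counts.set_index("age_group")
    if (c[["expose_all_n", "fewer_n"]] < 0).any().any():
        raise ValueError("counts must be non-negative")
    under38 = c.loc[list(AGE_GROUPS[:3])]
    total = c["expose_all_n"].sum() + c["fewer_n"].sum()
    total38 = under38["expose_all_n"].sum() + under38["fewer_n"].sum()
    return {
        "fewer_pct_overall": round(100.0 * c["fewer_n"].sum() / total, 1),
        "fewer_pct_under_38": round(100.0 * under38["fewer_n"].sum() / total38, 1),
        "fewer_n_overall": int(c["fewer_n"].sum()),
    }


def prediction_summaries(fits, test_cycles: pd.DataFrame) -> pd.DataFrame:
    """Per-age-group medians/IQRs of the three model predictions.

    One row per age stratum with the day-5 classification rate and the
    median (IQR) of the predicted yield proportion and predicted blastocyst
    need among cycles classified day 5.  On simulated cohorts these are
    qualitative gradients, not numeric matches to any published cohort.
    """
    from fertiopt.recommendation_engine import _covariate_frame

    df = _covariate_frame(test_cycles)
    p5 = predict_day5_probability(fits.day_model, df)
    yp = predict_yield(fits.yield_model, df)
    B = predict_median_blastocysts(fits.aft_model, df)
    is5 = p5 >= fits.day_model.threshold
    rows = []
    for g in AGE_GROUPS:
        m = df["age_group"] == g
        m5 = m & is5
        p_med, p_q1, p_q3 = _quantiles(yp[m5])
        b_med, b_q1, b_q3 = _quantiles(B[m5])
        rows.append({
            "age_group": g,
            "n_cycles": int(m.sum()),
            "day5_classification_rate": float(is5[m].mean()) if m.any() else np.nan,
            "yield_p_median": p_med, "yield_p_q1": p_q1, "yield_p_q3": p_q3,
            "blastocysts_needed_median": b_med, "blastocysts_needed_q1": b_q1,
            "blastocysts_needed_q3": b_q3,
        })
    return pd.DataFrame(rows)
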