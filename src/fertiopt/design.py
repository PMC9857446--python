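"""Reference-coded design matrices shared by the three models.

All three models use the same covariate set: female age group, clinic
region, AMH band, diminished-ovarian-reserve diagnosis, and the number of
oocytes retrieved (linear continuous term).  Categorical covariates are
reference-coded against the youngest age group, the first region level (in
sorted order), the ``unknown`` AMH band, and no DOR.  Term names are
``intercept``, ``age_group[<level>]``, ``region[<level>]``,
``amh_band[<level>]``, ``dor``, ``n_oocytes_retrieved``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fertiopt.core_registry import AGE_GROUPS, AMH_BANDS


class UnseenLevelError(ValueError):
    """A prediction covariate level was not present in the training data."""


@dataclass(frozen=True)
class CovariateLevels:
    """Categorical levels fixed at fit time (first level is the reference)."""

    age_groups: tuple
    regions: tuple
    amh_bands: tuple

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CovariateLevels":
        """Levels observed in the training data, in canonical order.

        Restricting to observed levels keeps the design matrix full rank;
        predicting at a level absent from training raises
        :class:`UnseenLevelError` rather than silently extrapolating.
        """
        ages = tuple(g for g in AGE_GROUPS if g in set(df["age_group"]))
        bands = tuple(b for b in AMH_BANDS if b in set(df["amh_band"]))
        regions = tuple(sorted(df["region"].unique()))
        return cls(age_groups=ages, regions=regions, amh_bands=bands)

    def to_dict(self) -> dict:
        return {"age_groups": list(self.age_groups), "regions": list(self.regions),
                "amh_bands": list(self.amh_bands)}

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateLevels":
        return cls(tuple(d["age_groups"]), tuple(d["regions"]), tuple(d["amh_bands"]))


def term_names(levels: CovariateLevels) -> list[str]:
    names = ["intercept"]
    names += [f"age_group[{g}]" for g in levels.age_groups[1:]]
    names += [f"region[{r}]" for r in levels.regions[1:]]
    names += [f"amh_band[{b}]" for b in levels.amh_bands[1:]]
    names += ["dor", "n_oocytes_retrieved"]
    return names


def _dummies(values: pd.Series, what: str, cats: tuple, prefix: str) -> pd.DataFrame:
    unseen = set(values.unique()) - set(cats)
    if unseen:
        raise UnseenLevelError(f"unseen {what} level(s): {sorted(unseen)}")
    codes = pd.Categorical(values, categories=list(cats))
    dm = pd.get_dummies(codes, drop_first=True, dtype=float)
    dm.columns = [f"{prefix}[{c}]" for c in dm.columns]
    dm.index = values.index
    return dm


def design_matrix(df: pd.DataFrame, levels: CovariateLevels) -> pd.DataFrame:
    """Build the reference-coded design matrix (with intercept column)."""
    parts = [
        pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index),
        _dummies(df["age_group"], "age_group", levels.age_groups, "age_group"),
        _dummies(df["region"], "region", levels.regions, "region"),
        _dummies(df["amh_band"], "amh_band", levels.amh_bands, "amh_band"),
        pd.DataFrame({
            "dor": df["dor"].astype(float),
            "n_oocytes_retrieved": df["n_oocytes_retrieved"].astype(float),
        }, index=df.index),
    ]
    X = pd.concat(parts, axis=1)
    return X[term_names(levels)]
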