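"""Per-strain post-MI remodeling traits from echocardiography and survival logs.

Two derived traits quantify left-ventricular systolic dysfunction after
myocardial infarction:

* ``LVD``  — percent LV dilation, ``vol_after / vol_before * 100 - 100``
  using the diastolic LV volume before and one month after MI;
* ``dEF``  — percent EF reduction, ``(EF_before - EF_after) / EF_after * 100``.

A third trait scores susceptibility to myocardial rupture as the fraction of
animals surviving the day 3-5 rupture window. Only animals whose infarct
exceeds 30% of the LV enter the analysis; strains whose dEF and LVD z-scores
disagree are flagged as discordant and excluded from dilation/heart-failure
analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_lvd",
    "compute_delta_ef",
    "apply_inclusion_filters",
    "rupture_survival",
    "concordance_flag",
    "strain_trait_table",
    "ConcordanceRule",
]


def compute_lvd(lv_vol_d_before, lv_vol_d_after):
    """Percent LV dilation: ``after / before * 100 - 100``; positive = dilation."""
    before = np.asarray(lv_vol_d_before, dtype=float)
    after = np.asarray(lv_vol_d_after, dtype=float)
    if np.any(before <= 0) or np.any(after <= 0):
        raise ValueError("LV volumes must be positive")
    out = after / before * 100.0 - 100.0
    return out.item() if out.ndim == 0 else out


def compute_delta_ef(ef_before, ef_after):
    """Percent EF reduction: ``(before - after) / after * 100``; positive = loss."""
    before = np.asarray(ef_before, dtype=float)
    after = np.asarray(ef_after, dtype=float)
    if np.any(after <= 0):
        raise ValueError("post-MI EF must be positive")
    out = (before - after) / after * 100.0
    return out.item() if out.ndim == 0 else out


def apply_inclusion_filters(
    records: pd.DataFrame,
    survival: pd.DataFrame | None = None,
    mi_size_threshold: float = 30.0,
):
    """Drop animals with infarcts of <= ``mi_size_threshold`` percent of the LV.

    ``MI_size`` is read from each animal's post-MI row. Animals whose infarct
    is below ~40% of the LV are additionally reported (comparability warning)
    but only the >30% rule removes animals. Returns
    ``(records, survival, removed_per_strain)`` with both tables restricted to
    retained animals.
    """
    if not (0 < mi_size_threshold < 100):
        raise ValueError("mi_size_threshold must be in (0, 100)")
    post = records[records["timepoint"] == "after"]
    sizes = post.set_index("animal_id")["MI_size"]
    if sizes.isna().all():
        raise ValueError(
            "MI_size missing for all animals: " + ", ".join(sizes.index.astype(str))
        )
    keep = sizes[sizes > mi_size_threshold].index
    small = sizes[(sizes > mi_size_threshold) & (sizes < 40.0)]
    if len(small):
        warnings.warn(
            f"{len(small)} retained animals have MI size below the ~40% "
            "comparability screen", stacklevel=2,
        )
    removed = (
        post[~post["animal_id"].isin(keep)].groupby("strain_id")["animal_id"].nunique()
    )
    records_f = records[records["animal_id"].isin(keep)].copy()
    survival_f = None
    if survival is not None:
        survival_f = survival[survival["animal_id"].isin(keep)].copy()
    return records_f, survival_f, removed


def rupture_survival(
    survival: pd.DataFrame, window: tuple[int, int] = (3, 5)
) -> pd.Series:
    """Per-strain fraction of animals not dying of rupture in the day window.

    Deaths outside the window, deaths from other causes, and surviving
    animals all count as surviving the rupture window.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("window start must be <= end")
    counts = survival.groupby("strain_id")["animal_id"].nunique()
    if (counts == 0).any() or survival.empty:
        raise ValueError("zero included animals for at least one strain")
    in_window = (
        (survival["cause"] == "rupture")
        & survival["death_day"].between(lo, hi)
    )
    deaths = survival[in_window].groupby("strain_id")["animal_id"].nunique()
    frac = 1.0 - deaths.reindex(counts.index, fill_value=0) / counts
    return frac.rename("rupture_survival")


@dataclass
class ConcordanceRule:
    """Discordance rule: opposite-sign z-scores with both |z| above the gate."""

    z_gate: float = 0.5


def concordance_flag(
    trait_table: pd.DataFrame, rule: ConcordanceRule | None = None
) -> pd.Series:
    """Flag strains whose dEF and LVD strain-level z-scores disagree.

    Returns a boolean Series (True = concordant). Strains flagged discordant
    are excluded from dilation/heart-failure analyses downstream.
    """
    rule = rule or ConcordanceRule()
    if len(trait_table) < 3:
        raise ValueError("need at least 3 strains")
    z = {}
    for col in ("delta_EF", "LVD"):
        x = trait_table[col].astype(float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance in {col}")
        z[col] = (x - x.mean()) / sd
    discordant = (
        (np.sign(z["delta_EF"]) != np.sign(z["LVD"]))
        & (z["delta_EF"].abs() > rule.z_gate)
        & (z["LVD"].abs() > rule.z_gate)
    )
    return (~discordant).rename("concordant")


def strain_trait_table(
    records: pd.DataFrame,
    survival: pd.DataFrame | None = None,
    rule: ConcordanceRule | None = None,
) -> pd.DataFrame:
    """Derive the per-strain trait table from per-animal records.

    Computes per-animal dEF and LVD from the before/after rows, averages
    within strain (mean and SD reported), attaches the rupture-survival
    fraction when a survival log is given, and flags concordance when at
    least 3 strains are present.
    """
    wide = records.pivot_table(
        index=["strain_id", "animal_id"],
        columns="timepoint",
        values=["EF", "LV_vol_d"],
        aggfunc="first",
    )
    d_ef = compute_delta_ef(wide[("EF", "before")], wide[("EF", "after")])
    lvd = compute_lvd(wide[("LV_vol_d", "before")], wide[("LV_vol_d", "after")])
    per_animal = pd.DataFrame(
        {"delta_EF": d_ef, "LVD": lvd}, index=wide.index
    ).reset_index()
    grouped = per_animal.groupby("strain_id")
    table = grouped.agg(
        delta_EF=("delta_EF", "mean"),
        delta_EF_sd=("delta_EF", "std"),
        LVD=("LVD", "mean"),
        LVD_sd=("LVD", "std"),
        n_animals=("animal_id", "nunique"),
    )
    if survival is not None and len(survival):
        table = table.join(rupture_survival(survival), how="left")
    if len(table) >= 3:
        table["concordant"] = concordance_flag(table, rule)
    return table
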