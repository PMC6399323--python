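"""Expression-trait correlation on the GeneNetwork "2Z + 8" scale.

Log2-normalized transcript intensities are standardized per transcript to
Z-scores rescaled to mean 8 and SD 2 (one transformed unit = half an SD;
on this scale one unit corresponds to a twofold expression difference),
filtered at a mean expression > 7, and correlated transcript-by-transcript
against per-strain remodeling traits. Top correlates per trait (|r| above a
cutoff, ranked by |r|) are intersected across traits. A ddCT utility covers
relative qPCR quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "transform_2z8",
    "filter_expressed",
    "correlate_trait",
    "top_correlates",
    "TopCorrelates",
    "ddct",
]


def transform_2z8(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript Z-score rescaled to mean 8, SD 2 (sample SD, n-1).

    Constant transcripts are excluded with a warning (their z-score is
    undefined); excluded ids are recorded in ``result.attrs['excluded']``.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 strains")
    sd = matrix.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant transcripts excluded", stacklevel=2
        )
    kept = matrix.loc[~constant]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)
    out = 2.0 * z + 8.0
    out.attrs["transform"] = "2Z+8"
    out.attrs["excluded"] = list(matrix.index[constant])
    return out


def filter_expressed(matrix: pd.DataFrame, threshold: float = 7.0) -> pd.DataFrame:
    """Keep transcripts whose mean transformed value exceeds the threshold (strict)."""
    keep = matrix.mean(axis=1) > threshold
    if not keep.any():
        warnings.warn("no transcripts pass the expression filter", stacklevel=2)
    return matrix.loc[keep]


def correlate_trait(
    matrix: pd.DataFrame,
    trait: pd.Series,
    method: str = "pearson",
    trait_name: str | None = None,
) -> pd.DataFrame:
    """Correlate every transcript with a per-strain trait.

    Strains are aligned by intersection (at least 3 required). Returns a
    DataFrame with columns ``transcript, r, p, n, rank, trait`` ranked by
    |r| descending, ties broken by transcript id. P-values use the exact
    null t-transform ``t = r sqrt((n-2)/(1-r^2))`` with n-2 df.
    """
    shared = [s for s in matrix.columns if s in trait.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared strains")
    y = trait.loc[shared].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant trait")
    X = matrix[shared].to_numpy(dtype=float)
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    n = len(shared)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc @ yc / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0
    res = pd.DataFrame(
        {"transcript": matrix.index, "r": r, "p": p, "n": n}
    ).dropna(subset=["r"])
    # rank by |r| descending, ties broken by transcript id
    res = res.iloc[
        np.lexsort((res["transcript"].to_numpy(), -res["r"].abs().to_numpy()))
    ]
    res["rank"] = np.arange(1, len(res) + 1)
    res["trait"] = trait_name or getattr(trait, "name", None) or "trait"
    return res.reset_index(drop=True)


@dataclass
class TopCorrelates:
    """Per-trait top-correlate sets and their intersection."""

    sets: dict[str, set]
    intersection: set

    @property
    def counts(self) -> dict[str, int]:
        out = {k: len(v) for k, v in self.sets.items()}
        out["intersection"] = len(self.intersection)
        return out


def top_correlates(
    results: dict[str, pd.DataFrame],
    n_top: int = 500,
    r_min: float = 0.60,
) -> TopCorrelates:
    """Top ``n_top`` transcripts per trait with |r| >= ``r_min``, intersected."""
    sets = {}
    for trait, res in results.items():
        passing = res[res["r"].abs() >= r_min].nsmallest(n_top, "rank")
        sets[trait] = set(passing["transcript"])
    inter = set.intersection(*sets.values()) if sets else set()
    return TopCorrelates(sets=sets, intersection=inter)


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative quantity by the ddCT method: ``2**-ddCT``.

    ``ddCT = (CT_target,sample - CT_ref,sample) -
    (CT_target,calibrator - CT_ref,calibrator)``; one cycle equals a twofold
    change.
    """
    vals = [ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator]
    if not np.all(np.isfinite(vals)):
        raise ValueError("all CT values must be finite")
    ddct_val = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-ddct_val))
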