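"""Kinship-adjusted genome scans of strain traits on founder haplotype dosages.

The model at each locus is a linear mixed model

    y = X_locus b + g + e,   g ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

where X_locus holds the eight founder dosage columns (they sum to one per
locus, so the intercept lies in their span) and K is a strain kinship matrix
built from the dosages themselves. Variance components are estimated once by
maximum likelihood under the null (intercept-only) model and reused at every
locus; after rotating by the eigenvectors of K the locus fits
reduce to weighted least squares and the LOD is the Gaussian ML likelihood
ratio, LOD = (n/2) log10(RSS0/RSS1), which is non-negative by nesting and
invariant to affine transformation of the trait.

Genome-wide significance thresholds come from trait permutations (null
variance components re-estimated per permutation); support intervals are
two-LOD drops padded by 10 kb; founder effects at a peak are GLS
coefficients re-expressed as centered eight-vectors with Wald tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .haplotype import DosageSet

__all__ = [
    "KinshipMatrix",
    "QTLScan",
    "Thresholds",
    "SupportInterval",
    "FounderEffects",
    "kinship_matrix",
    "scan",
    "permutation_thresholds",
    "support_interval",
    "founder_effects",
    "prioritize_snps",
]


@dataclass
class KinshipMatrix:
    """Strain-by-strain genetic similarity (PSD, mean diagonal = 1)."""

    values: np.ndarray
    strain_ids: list[str]
    method: str = "dosage-inner-product"

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        self.values = K


@dataclass
class QTLScan:
    """Per-locus LOD scores and centered founder coefficients."""

    chrom: np.ndarray
    pos: np.ndarray
    lod: np.ndarray
    coef: np.ndarray  # (n_loci, 8), centered to mean 0
    trait: str
    n_strains: int
    h2_null: float

    def peak_index(self) -> int:
        return int(np.argmax(self.lod))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos, "lod": self.lod})
        for k in range(8):
            df[f"coef_f{k}"] = self.coef[:, k]
        return df


@dataclass
class Thresholds:
    """Genome-wide LOD cutoffs from the permutation null of max LOD."""

    cutoffs: dict[float, float]
    n_perm: int
    seed: int
    max_lods: np.ndarray = field(repr=False, default=None)

    def __getitem__(self, alpha: float) -> float:
        return self.cutoffs[alpha]


@dataclass
class SupportInterval:
    """Two-LOD-drop support interval with 10 kb padding."""

    chrom: str
    peak_pos: int
    start: int
    end: int
    peak_lod: float
    whole_chromosome: bool = False

    def __post_init__(self) -> None:
        if not (self.start <= self.peak_pos <= self.end):
            raise ValueError("interval must contain the peak")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class FounderEffects:
    """Centered founder coefficients at a locus with Wald tests."""

    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    df: int

    def implicated(self) -> int:
        """Founder index with the largest absolute effect."""
        return int(np.argmax(np.abs(self.coef)))


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def kinship_matrix(
    dset: DosageSet, exclude_chromosome: str | None = None
) -> KinshipMatrix:
    """Mean dosage inner product across loci, rescaled to mean diagonal 1.

    ``K[a, b] = mean_l <d_la, d_lb>`` over founder-dosage vectors, a Gram
    average and hence positive semi-definite. ``exclude_chromosome`` gives the
    leave-one-chromosome-out variant used to avoid proximal contamination.
    """
    if dset.n_loci == 0 or dset.n_strains < 2:
        raise ValueError("need dosages for at least 2 strains and 1 locus")
    use = np.ones(dset.n_loci, dtype=bool)
    if exclude_chromosome is not None:
        use &= dset.chrom != exclude_chromosome
        if not use.any():
            raise ValueError("no loci left after chromosome exclusion")
    D = dset.dosages[use]
    K = np.einsum("lak,lbk->ab", D, D) / use.sum()
    K /= np.mean(np.diag(K))
    method = "dosage-inner-product" + (
        f"-loco-{exclude_chromosome}" if exclude_chromosome else ""
    )
    return KinshipMatrix(K, list(dset.strain_ids), method)


# ---------------------------------------------------------------------------
# mixed-model machinery
# ---------------------------------------------------------------------------

class _ScanEngine:
    """Eigen-rotated workspace shared by scans and permutations."""

    def __init__(self, dset: DosageSet, K: KinshipMatrix):
        if list(K.strain_ids) != list(dset.strain_ids):
            raise ValueError("kinship and dosages must index the same strains")
        self.n = dset.n_strains
        evals, U = np.linalg.eigh(K.values)
        self.evals = np.clip(evals, 0.0, None)
        self.U = U
        # rotated design per locus and rotated intercept
        self.Xr = np.einsum("nm,lnk->lmk", U, dset.dosages)
        self.x0r = U.T @ np.ones(self.n)
        self.dset = dset

    def rotate(self, y: np.ndarray) -> np.ndarray:
        return self.U.T @ y

    def null_fit(self, z: np.ndarray, fix_h2: float | None = None):
        """ML fit of h2 (genetic variance fraction) under the intercept model."""
        n = self.n

        def neg_ll(h2):
            lam = h2 * self.evals + (1 - h2)
            w = 1.0 / lam
            xw = self.x0r * w
            beta = (xw @ z) / (xw @ self.x0r)
            resid = z - beta * self.x0r
            rss = resid @ (w * resid)
            return 0.5 * (n * np.log(rss / n) + np.log(lam).sum())

        if fix_h2 is not None:
            h2 = float(fix_h2)
        else:
            res = optimize.minimize_scalar(
                neg_ll, bounds=(0.0, 1.0 - 1e-6), method="bounded"
            )
            h2 = float(res.x)
        lam = h2 * self.evals + (1 - h2)
        w = 1.0 / lam
        xw = self.x0r * w
        beta = (xw @ z) / (xw @ self.x0r)
        resid = z - beta * self.x0r
        rss0 = float(resid @ (w * resid))
        return h2, w, rss0

    def locus_fits(self, z: np.ndarray, w: np.ndarray):
        """Batched weighted LS of z on every locus design; returns (rss1, beta)."""
        zw = z * w
        G = np.einsum("lnk,n,lnm->lkm", self.Xr, w, self.Xr)
        b = np.einsum("lnk,n->lk", self.Xr, zw)
        beta = np.einsum("lkm,lm->lk", np.linalg.pinv(G, rcond=1e-10), b)
        rss1 = (z * zw).sum() - np.einsum("lk,lk->l", b, beta)
        return np.clip(rss1, 1e-300, None), beta

    def scan_once(self, y: np.ndarray, fix_h2: float | None = None):
        z = self.rotate(np.asarray(y, dtype=float))
        h2, w, rss0 = self.null_fit(z, fix_h2)
        rss1, beta = self.locus_fits(z, w)
        lod = 0.5 * self.n * np.log10(np.clip(rss0 / rss1, 1.0, None))
        return lod, beta, h2, w, rss0


def _align_trait(trait, dset: DosageSet) -> np.ndarray:
    if isinstance(trait, pd.Series):
        missing = [s for s in dset.strain_ids if s not in trait.index]
        if missing:
            raise ValueError(f"trait missing strains: {missing[:5]}")
        y = trait.loc[dset.strain_ids].to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
        if y.size != dset.n_strains:
            raise ValueError("trait length must match strain count")
    if np.ptp(y) == 0:
        raise ValueError("constant trait")
    return y


def scan(
    trait,
    dset: DosageSet,
    K: KinshipMatrix,
    trait_name: str = "trait",
    fix_h2: float | None = None,
    founder_mask: np.ndarray | None = None,
) -> QTLScan:
    """Genome scan: LOD and centered founder coefficients at every locus.

    ``trait`` is a strain-indexed Series or an array aligned with
    ``dset.strain_ids``; needs at least 10 strains. ``fix_h2`` pins the
    genetic variance fraction (0 reduces the model to ordinary regression).
    ``founder_mask`` (length 8, True = keep) zeroes out excluded founders'
    dosage columns before fitting (e.g. a founder absent from the cohort).
    """
    if dset.n_strains < 10:
        raise ValueError("need at least 10 strains")
    y = _align_trait(trait, dset)
    if founder_mask is not None:
        dset = DosageSet(
            dset.chrom, dset.pos,
            dset.dosages * np.asarray(founder_mask, dtype=float)[None, None, :],
            dset.strain_ids,
        )
    eng = _ScanEngine(dset, K)
    lod, beta, h2, _, _ = eng.scan_once(y, fix_h2)
    coef = beta - beta.mean(axis=1, keepdims=True)
    return QTLScan(
        chrom=dset.chrom, pos=dset.pos, lod=lod, coef=coef,
        trait=trait_name, n_strains=dset.n_strains, h2_null=h2,
    )


def permutation_thresholds(
    trait,
    dset: DosageSet,
    K: KinshipMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    alphas: tuple[float, ...] = (0.05, 0.10, 0.63),
    fix_h2: float | None = None,
) -> Thresholds:
    """Genome-wide LOD thresholds from permutations of the trait vector.

    Each permutation shuffles trait values across strains, re-estimates the
    null variance components, and re-runs the full scan; the threshold at
    level alpha is the ``ceil((1-alpha)*(n_perm+1))``-th order statistic of
    the max-LOD null sample (capped at the maximum), the convention that
    makes the permutation test exactly level alpha: an exchangeable new
    scan exceeds the threshold with probability
    ``floor(alpha*(n_perm+1))/(n_perm+1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    for a in alphas:
        if a < 1.0 / n_perm:
            raise ValueError(f"alpha={a} unresolvable with {n_perm} permutations")
    y = _align_trait(trait, dset)
    eng = _ScanEngine(dset, K)
    rng = np.random.default_rng(seed)
    max_lods = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        lod, _, _, _, _ = eng.scan_once(yp, fix_h2)
        max_lods[i] = lod.max()
    srt = np.sort(max_lods)
    cutoffs = {}
    for a in alphas:
        k = int(np.ceil((1 - a) * (n_perm + 1)))
        cutoffs[a] = float(srt[min(k, n_perm) - 1])
    return Thresholds(cutoffs=cutoffs, n_perm=n_perm, seed=seed, max_lods=max_lods)


def support_interval(
    qscan: QTLScan,
    peak_index: int | None = None,
    drop: float = 2.0,
    pad: int = 10_000,
    chrom_length: int | None = None,
) -> SupportInterval:
    """Two-LOD-drop interval around a peak, padded by ``pad`` bp.

    Walks outward from the peak to the first loci whose LOD falls ``drop``
    below the peak; the interval spans those loci's positions extended by the
    pad (clipped to the chromosome's scanned range, or to ``chrom_length``).
    A peak that never drops on one side extends to the chromosome end and is
    flagged ``whole_chromosome`` if neither side drops.
    """
    i = qscan.peak_index() if peak_index is None else int(peak_index)
    chrom = qscan.chrom[i]
    on = np.flatnonzero(qscan.chrom == chrom)
    pos = qscan.pos[on]
    lod = qscan.lod[on]
    j = int(np.flatnonzero(on == i)[0])
    target = lod[j] - drop
    lo = j
    while lo > 0 and lod[lo] > target:
        lo -= 1
    hi = j
    while hi < lod.size - 1 and lod[hi] > target:
        hi += 1
    dropped_left = lod[lo] <= target
    dropped_right = lod[hi] <= target
    start = int(pos[lo]) - pad
    end = int(pos[hi]) + pad
    lo_bound = 0
    hi_bound = chrom_length if chrom_length is not None else int(pos[-1]) + pad
    start = max(start, lo_bound)
    end = min(end, hi_bound)
    whole = not (dropped_left or dropped_right)
    if whole:
        warnings.warn("LOD never drops below peak - drop: interval spans the "
                      "whole chromosome", stacklevel=2)
    return SupportInterval(
        chrom=str(chrom), peak_pos=int(qscan.pos[i]), start=start, end=end,
        peak_lod=float(qscan.lod[i]), whole_chromosome=whole,
    )


def founder_effects(
    trait,
    dset: DosageSet,
    K: KinshipMatrix,
    locus_index: int,
    fix_h2: float | None = None,
) -> FounderEffects:
    """GLS founder coefficients at one locus, centered, with Wald p-values.

    Standard errors come from the GLS covariance of the eight dosage
    coefficients propagated through the centering contrast; p-values are
    two-sided t-tests on n - rank degrees of freedom. Collinear dosage
    columns are handled by the pseudo-inverse (minimum-norm coefficients).
    """
    y = _align_trait(trait, dset)
    eng = _ScanEngine(dset, K)
    z = eng.rotate(y)
    _, w, _ = eng.null_fit(z, fix_h2)
    X = eng.Xr[locus_index]
    G = X.T @ (w[:, None] * X)
    Ginv = np.linalg.pinv(G, rcond=1e-10)
    rank = int(np.linalg.matrix_rank(G, tol=1e-8))
    if rank < 8:
        warnings.warn("collinear founder dosages at locus: pseudo-inverse "
                      "(minimum-norm) coefficients reported", stacklevel=2)
    beta = Ginv @ (X.T @ (w * z))
    resid = z - X @ beta
    dof = eng.n - rank
    sigma2 = float(resid @ (w * resid)) / dof
    C = np.eye(8) - np.full((8, 8), 1 / 8)
    cov = sigma2 * (C @ Ginv @ C.T)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    coef = C @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / se, 0.0)
    p = 2 * stats.t.sf(np.abs(tstat), df=dof)
    return FounderEffects(coef=coef, se=se, p=p, df=dof)


# ---------------------------------------------------------------------------
# candidate variants
# ---------------------------------------------------------------------------

_SEVERE = {"missense", "splice_donor", "splice_acceptor", "splice_region",
           "stop_gained", "frameshift"}


def prioritize_snps(
    interval: SupportInterval,
    variants: pd.DataFrame,
    implicated_founders: list[int],
    founder_allele_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Rank candidate variants inside a QTL support interval.

    ``variants`` needs columns ``snp_id, chrom, pos, consequence, sift`` plus
    eight per-founder alternate-allele indicator columns (default
    ``founder_0..founder_7``). Variants are filtered to the interval, kept if
    every implicated founder carries the alternate allele, and ranked by
    (1) allele private to the implicated founders, (2) consequence severity
    (missense/splice and worse first), (3) SIFT < 0.05 deleterious flag,
    breaking remaining ties by ascending SIFT then position.
    """
    if not implicated_founders:
        raise ValueError("implicated founder set must be non-empty")
    cols = founder_allele_cols or [f"founder_{k}" for k in range(8)]
    v = variants[
        (variants["chrom"] == interval.chrom)
        & variants["pos"].between(interval.start, interval.end)
    ].copy()
    if v.empty:
        return v.assign(private=[], severe=[], deleterious=[], tier=[], rank=[])
    carrier = v[cols].to_numpy(dtype=bool)
    imp = np.zeros(8, dtype=bool)
    imp[list(implicated_founders)] = True
    carried_by_all = carrier[:, imp].all(axis=1)
    v = v[carried_by_all].copy()
    carrier = carrier[carried_by_all]
    v["private"] = ~carrier[:, ~imp].any(axis=1)
    v["severe"] = v["consequence"].isin(_SEVERE)
    v["deleterious"] = v["sift"] < 0.05
    v["tier"] = np.where(v["private"], 1, 2)
    v = v.sort_values(
        by=["tier", "severe", "deleterious", "sift", "pos"],
        ascending=[True, False, False, True, True],
        kind="mergesort",
    )
    v["rank"] = np.arange(1, len(v) + 1)
    return v.reset_index(drop=True)
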