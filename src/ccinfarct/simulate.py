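"""Synthetic Collaborative Cross cohorts with known ground truth.

Generates every input the analysis pipeline consumes: an eight-founder SNP
panel, recombinant-inbred strain genomes as founder mosaics, per-animal
echocardiography records driven by a planted founder-effect QTL, paired
polarized/brightfield scar images with von Mises fiber orientations, and
transcript-by-strain expression matrices with planted trait correlates.

All generators are deterministic given a seed. Strains are fully inbred
(one haplotype per strain); mosaics are drawn directly as Poisson-breakpoint
founder tilings rather than simulating the breeding funnel, which is
sufficient to exercise haplotype inference and mapping.

Angle convention for fiber truth and rendering: axial angles in degrees in
[0, 180), measured from the image x-axis (columns) toward the y-axis (rows).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FOUNDER_NAMES",
    "FounderPanel",
    "MosaicGenome",
    "QTLSpec",
    "FiberTruth",
    "BaselineParams",
    "simulate_founders",
    "simulate_cc_strain",
    "simulate_cc_panel",
    "simulate_cohort_traits",
    "simulate_survival",
    "simulate_scar_image_pair",
    "simulate_expression",
]

#: Labels of the eight Collaborative Cross founder strains.
FOUNDER_NAMES = ("AJ", "B6", "129S1", "NOD", "NZO", "CAST", "PWK", "WSB")


@dataclass
class FounderPanel:
    """Eight founder haplotypes over a set of biallelic SNPs.

    ``snp_positions[chrom]`` holds strictly increasing bp positions,
    ``founder_alleles[chrom]`` an ``(n_snps, 8)`` array of 0/1 alleles.
    """

    founder_ids: tuple[str, ...]
    chromosomes: list[tuple[str, int]]
    snp_positions: dict[str, np.ndarray]
    founder_alleles: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.founder_ids) != 8:
            raise ValueError("a Collaborative Cross panel has exactly 8 founders")
        for chrom, _length in self.chromosomes:
            pos = np.asarray(self.snp_positions[chrom])
            alle = np.asarray(self.founder_alleles[chrom])
            if pos.ndim != 1 or np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions must be strictly increasing")
            if alle.shape != (pos.size, 8):
                raise ValueError(f"{chrom}: allele matrix must be (n_snps, 8)")
            if not np.isin(alle, (0, 1)).all():
                raise ValueError(f"{chrom}: alleles must be 0/1")

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def n_snps(self) -> int:
        return sum(self.snp_positions[c].size for c in self.chrom_names)

    def chrom_length(self, chrom: str) -> int:
        for c, length in self.chromosomes:
            if c == chrom:
                return length
        raise KeyError(chrom)


@dataclass
class MosaicGenome:
    """A fully inbred strain genome as a tiling of founder segments.

    Segments are half-open ``(chrom, start, end, founder_index)`` intervals
    covering each chromosome without gaps or overlaps. ``genotypes[chrom]``
    are the strain's calls at the panel SNPs (0/1, -1 for missing) after
    optional error injection.
    """

    strain_id: str
    segments: list[tuple[str, int, int, int]]
    genotypes: dict[str, np.ndarray]

    def validate_tiling(self, panel: FounderPanel) -> None:
        """Assert that segments tile each chromosome exactly."""
        for chrom, length in panel.chromosomes:
            segs = sorted(s for s in self.segments if s[0] == chrom)
            if not segs:
                raise AssertionError(f"{self.strain_id}: no segments on {chrom}")
            if segs[0][1] != 0 or segs[-1][2] != length:
                raise AssertionError(f"{self.strain_id}: {chrom} not fully covered")
            for (_, _, e0, _), (_, s1, _, _) in zip(segs, segs[1:]):
                if e0 != s1:
                    raise AssertionError(f"{self.strain_id}: gap/overlap on {chrom}")

    def founder_at(self, chrom: str, position: int) -> int:
        """Founder index donating the haplotype at a bp position."""
        for c, start, end, f in self.segments:
            if c == chrom and start <= position < end:
                return f
        raise ValueError(f"position {chrom}:{position} outside genome")

    def true_founder_per_snp(self, panel: FounderPanel, chrom: str) -> np.ndarray:
        """Ground-truth founder index at every panel SNP on a chromosome."""
        pos = panel.snp_positions[chrom]
        out = np.empty(pos.size, dtype=np.int64)
        for c, start, end, f in self.segments:
            if c == chrom:
                out[(pos >= start) & (pos < end)] = f
        return out


@dataclass
class QTLSpec:
    """A planted additive QTL: locus, centered 8-founder effects, heritability.

    ``h2`` is the fraction of strain-mean trait variance explained by the
    locus; the effect vector is centered to mean zero on construction.
    """

    chromosome: str
    position: int
    founder_effects: np.ndarray
    h2: float

    def __post_init__(self) -> None:
        eff = np.asarray(self.founder_effects, dtype=float)
        if eff.shape != (8,):
            raise ValueError("founder_effects must have length 8")
        if not (0 <= self.h2 < 1):
            raise ValueError("h2 must lie in [0, 1)")
        self.founder_effects = eff - eff.mean()


@dataclass
class FiberTruth:
    """Ground truth for one scar image pair.

    mu:    true mean axial fiber angle, degrees in [0, 180)
    kappa: von Mises concentration applied on doubled angles (axial);
           0 = uniform orientations
    fiber_density: expected fibers per 100x100 px patch
    pixel_size: microns per pixel
    fiber_length_px: rendered fiber length in pixels
    """

    mu: float
    kappa: float
    fiber_density: float = 40.0
    pixel_size: float = 1.7
    fiber_length_px: int = 24

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        self.mu = float(self.mu) % 180.0


# ---------------------------------------------------------------------------
# founder panel & mosaics
# ---------------------------------------------------------------------------

def simulate_founders(
    n_snps_per_chrom: int,
    n_chroms: int = 2,
    maf_distribution=None,
    seed: int = 0,
    chrom_length: int = 100_000_000,
    founder_ids: tuple[str, ...] = FOUNDER_NAMES,
) -> FounderPanel:
    """Draw an eight-founder biallelic SNP panel.

    ``maf_distribution`` may be a scalar minor-allele frequency, or a callable
    ``f(rng, size) -> array`` of per-SNP frequencies; the default draws MAFs
    uniformly on [0.1, 0.5]. Each founder carries the alternate allele
    independently with the SNP's MAF.
    """
    if n_snps_per_chrom < 2 or n_chroms < 1:
        raise ValueError("need at least 2 SNPs per chromosome and 1 chromosome")
    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i + 1}", chrom_length) for i in range(n_chroms)]
    positions: dict[str, np.ndarray] = {}
    alleles: dict[str, np.ndarray] = {}
    for chrom, length in chromosomes:
        # sorted draw with an arange offset guarantees strict increase
        base = np.sort(
            (rng.random(n_snps_per_chrom) * (length - n_snps_per_chrom - 1))
        ).astype(np.int64)
        positions[chrom] = base + np.arange(n_snps_per_chrom) + 1
        if maf_distribution is None:
            maf = rng.uniform(0.1, 0.5, size=n_snps_per_chrom)
        elif callable(maf_distribution):
            maf = np.asarray(maf_distribution(rng, n_snps_per_chrom), dtype=float)
        else:
            maf = np.full(n_snps_per_chrom, float(maf_distribution))
        alleles[chrom] = (rng.random((n_snps_per_chrom, 8)) < maf[:, None]).astype(
            np.int8
        )
    return FounderPanel(tuple(founder_ids), chromosomes, positions, alleles)


def simulate_cc_strain(
    panel: FounderPanel,
    expected_breakpoints_per_chrom: float = 3.0,
    genotype_error_rate: float = 0.0,
    seed: int = 0,
    strain_id: str = "CC001",
    missing_rate: float = 0.0,
) -> MosaicGenome:
    """Draw one recombinant-inbred genome as a founder mosaic.

    Breakpoint counts per chromosome are Poisson with the stated mean,
    breakpoint positions uniform, founder identities i.i.d. uniform over the
    eight founders. Genotypes are copied from the donor founder, then flipped
    independently at ``genotype_error_rate`` and masked to missing (-1) at
    ``missing_rate``.
    """
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    if expected_breakpoints_per_chrom < 0:
        raise ValueError("expected breakpoints must be >= 0")
    if not (0 <= genotype_error_rate < 0.5):
        raise ValueError("genotype_error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    segments: list[tuple[str, int, int, int]] = []
    genotypes: dict[str, np.ndarray] = {}
    for chrom, length in panel.chromosomes:
        n_bp = rng.poisson(expected_breakpoints_per_chrom)
        cuts = np.sort(rng.integers(1, length, size=n_bp))
        bounds = np.concatenate(([0], cuts, [length]))
        founders = rng.integers(0, 8, size=bounds.size - 1)
        pos = panel.snp_positions[chrom]
        calls = np.empty(pos.size, dtype=np.int8)
        for start, end, f in zip(bounds[:-1], bounds[1:], founders):
            segments.append((chrom, int(start), int(end), int(f)))
            sel = (pos >= start) & (pos < end)
            calls[sel] = panel.founder_alleles[chrom][sel, f]
        if genotype_error_rate > 0:
            flip = rng.random(pos.size) < genotype_error_rate
            calls[flip] = 1 - calls[flip]
        if missing_rate > 0:
            calls[rng.random(pos.size) < missing_rate] = -1
        genotypes[chrom] = calls
    return MosaicGenome(strain_id, segments, genotypes)


def simulate_cc_panel(
    panel: FounderPanel,
    n_strains: int,
    expected_breakpoints_per_chrom: float = 3.0,
    genotype_error_rate: float = 0.0,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> list[MosaicGenome]:
    """Draw a cohort of recombinant-inbred genomes (one sub-seed per strain)."""
    ss = np.random.SeedSequence(seed).spawn(n_strains)
    return [
        simulate_cc_strain(
            panel,
            expected_breakpoints_per_chrom,
            genotype_error_rate,
            seed=child,
            strain_id=f"CC{i + 1:03d}",
            missing_rate=missing_rate,
        )
        for i, child in enumerate(ss)
    ]


# ---------------------------------------------------------------------------
# echo traits
# ---------------------------------------------------------------------------

@dataclass
class BaselineParams:
    """Population parameters of the simulated echo traits.

    Strain means of the derived traits (dEF, LVD, both in percent) are drawn
    with the stated SDs; the planted QTL replaces a fraction ``h2`` of that
    strain-level variance. ``animal_sd`` is the per-animal SD of the derived
    traits around the strain mean, in percent; it is deliberately exposed
    rather than fixed, since animal-level echo variance is cohort-specific.
    """

    delta_ef_mean: float = 40.0
    delta_ef_sd: float = 18.0
    lvd_mean: float = 40.0
    lvd_sd: float = 22.0
    animal_sd: float = 5.0
    ef_before_mean: float = 60.0
    ef_before_sd: float = 4.0
    lv_vol_before_mean: float = 55.0
    lv_vol_before_sd: float = 6.0
    mi_size_mean: float = 42.0
    mi_size_sd: float = 4.0
    sv_mean: float = 32.0
    sv_sd: float = 4.0
    lv_mass_mean: float = 95.0
    lv_mass_sd: float = 12.0
    bwt_mean: float = 27.0
    bwt_sd: float = 3.0
    heart_rate_mean: float = 430.0
    heart_rate_sd: float = 25.0


def _genetic_values(genomes: list[MosaicGenome], qtl: QTLSpec) -> np.ndarray:
    """Raw additive genetic value per strain at the planted locus."""
    return np.array(
        [qtl.founder_effects[g.founder_at(qtl.chromosome, qtl.position)] for g in genomes]
    )


def simulate_cohort_traits(
    genomes: list[MosaicGenome],
    qtl: QTLSpec | None,
    n_animals_per_strain: int = 5,
    baseline: BaselineParams | None = None,
    seed: int = 0,
    panel: FounderPanel | None = None,
):
    """Simulate per-animal echocardiography records for a strain cohort.

    A single strain-level value drives both derived traits: the planted
    genetic component is rescaled so that its variance is ``h2`` of the total
    strain-mean variance of each trait, strain noise supplies the remainder,
    and per-animal noise (``baseline.animal_sd``) is added on the derived
    trait scale. Pre/post-MI EF and diastolic volumes are then constructed by
    exact inversion of the dEF and LVD definitions, so the trait formulas
    recover the planted per-animal values exactly.

    Returns ``(records, truth)`` where ``records`` is a long-format DataFrame
    (one row per animal and timepoint) and ``truth`` maps trait name to the
    planted per-strain values.
    """
    if n_animals_per_strain < 1:
        raise ValueError("n_animals_per_strain must be >= 1")
    if qtl is not None and panel is not None:
        pos = panel.snp_positions.get(qtl.chromosome)
        if pos is None or not (0 <= qtl.position < panel.chrom_length(qtl.chromosome)):
            raise ValueError("QTL position outside panel")
    bp = baseline or BaselineParams()
    rng = np.random.default_rng(seed)
    n = len(genomes)

    if qtl is None:
        g = np.zeros(n)
        h2 = 0.0
    else:
        g = _genetic_values(genomes, qtl)
        g = g - g.mean()
        h2 = qtl.h2
        sd_g = g.std()
        if sd_g == 0 and h2 > 0:
            raise ValueError("planted QTL is monomorphic in this cohort")
    # shared standardized strain driver: genetic part + strain noise
    if h2 > 0:
        z = math.sqrt(h2) * g / g.std() + math.sqrt(1 - h2) * rng.standard_normal(n)
    else:
        z = rng.standard_normal(n)

    strain_def = bp.delta_ef_mean + bp.delta_ef_sd * z
    strain_lvd = bp.lvd_mean + bp.lvd_sd * z
    truth = {
        "delta_EF": pd.Series(strain_def, index=[g_.strain_id for g_ in genomes]),
        "LVD": pd.Series(strain_lvd, index=[g_.strain_id for g_ in genomes]),
        "strain_z": pd.Series(z, index=[g_.strain_id for g_ in genomes]),
    }

    rows = []
    for i, genome in enumerate(genomes):
        for a in range(n_animals_per_strain):
            animal = f"{genome.strain_id}_a{a + 1}"
            d = strain_def[i] + bp.animal_sd * rng.standard_normal()
            l = strain_lvd[i] + bp.animal_sd * rng.standard_normal()
            d = max(d, -80.0)  # keep EF_after physiologic
            l = max(l, -80.0)
            ef_before = np.clip(rng.normal(bp.ef_before_mean, bp.ef_before_sd), 25, 85)
            vol_before = max(rng.normal(bp.lv_vol_before_mean, bp.lv_vol_before_sd), 15)
            ef_after = ef_before / (1 + d / 100.0)
            vol_after = vol_before * (1 + l / 100.0)
            common = dict(
                strain_id=genome.strain_id,
                animal_id=animal,
                SV=max(rng.normal(bp.sv_mean, bp.sv_sd), 5),
                LV_mass=max(rng.normal(bp.lv_mass_mean, bp.lv_mass_sd), 40),
                BWt=max(rng.normal(bp.bwt_mean, bp.bwt_sd), 12),
                heart_rate=rng.normal(bp.heart_rate_mean, bp.heart_rate_sd),
            )
            rows.append(
                dict(common, timepoint="before", EF=ef_before, LV_vol_d=vol_before,
                     MI_size=np.nan)
            )
            rows.append(
                dict(common, timepoint="after", EF=ef_after, LV_vol_d=vol_after,
                     MI_size=np.clip(rng.normal(bp.mi_size_mean, bp.mi_size_sd), 5, 70))
            )
    records = pd.DataFrame(rows)
    return records, truth


def simulate_survival(
    strain_values: pd.Series,
    n_animals_per_strain: int = 8,
    seed: int = 0,
    base_rate: float = 0.30,
    slope: float = 0.25,
    window: tuple[int, int] = (3, 5),
) -> pd.DataFrame:
    """Simulate a rupture-death log from standardized strain values.

    Per-strain rupture probability is ``clip(base_rate + slope*z, 0.02, 0.98)``;
    rupture deaths occur uniformly on the day window, all other animals
    survive to censoring.
    """
    rng = np.random.default_rng(seed)
    z = (strain_values - strain_values.mean()) / strain_values.std(ddof=0)
    rows = []
    for strain, zi in z.items():
        p = float(np.clip(base_rate + slope * zi, 0.02, 0.98))
        for a in range(n_animals_per_strain):
            if rng.random() < p:
                day = int(rng.integers(window[0], window[1] + 1))
                rows.append(dict(strain_id=strain, animal_id=f"{strain}_s{a+1}",
                                 death_day=day, cause="rupture"))
            else:
                rows.append(dict(strain_id=strain, animal_id=f"{strain}_s{a+1}",
                                 death_day=np.nan, cause="alive"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scar images
# ---------------------------------------------------------------------------

def sample_axial_angles(truth: FiberTruth, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw axial fiber angles (degrees, [0,180)) from the doubled-angle von Mises."""
    if truth.kappa == 0:
        return rng.uniform(0.0, 180.0, size=n)
    doubled = rng.vonmises(math.radians(2 * truth.mu), truth.kappa, size=n)
    return (np.degrees(doubled) / 2.0) % 180.0


def simulate_scar_image_pair(
    truth: FiberTruth,
    image_shape: tuple[int, int] = (256, 256),
    noise_sd: float = 0.02,
    seed: int = 0,
):
    """Render a polarized/brightfield image pair of straight collagen fibers.

    Fibers are straight segments with a Gaussian cross-section profile
    (anti-alias-free analytic rendering) and axial angles drawn from the
    doubled-angle von Mises(2*mu, kappa); the polarized channel shows fibers
    bright on dark, the blue-filtered brightfield channel shows them dark on
    bright, and both carry additive Gaussian noise. Returns
    ``(polarized, brightfield, angles)`` with float images in roughly [0, 1].
    """
    h, w = image_shape
    if h < 64 or w < 64:
        raise ValueError("image must be at least 64x64")
    rng = np.random.default_rng(seed)
    n_fibers = int(round(truth.fiber_density * h * w / 1e4))
    angles = sample_axial_angles(truth, n_fibers, rng)
    canvas = np.zeros((h, w), dtype=float)
    half = truth.fiber_length_px / 2.0
    profile_sd = 0.8  # px, fiber cross-section width
    for theta in angles:
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        dy = math.sin(math.radians(theta)) * half
        dx = math.cos(math.radians(theta)) * half
        y0, x0, y1, x1 = cy - dy, cx - dx, cy + dy, cx + dx
        rmin = max(int(min(y0, y1)) - 3, 0)
        rmax = min(int(max(y0, y1)) + 4, h)
        cmin = max(int(min(x0, x1)) - 3, 0)
        cmax = min(int(max(x0, x1)) + 4, w)
        if rmin >= rmax or cmin >= cmax:
            continue
        yy, xx = np.mgrid[rmin:rmax, cmin:cmax].astype(float)
        vy, vx = y1 - y0, x1 - x0
        t = np.clip(((yy - y0) * vy + (xx - x0) * vx) / (vy * vy + vx * vx), 0, 1)
        d2 = (yy - (y0 + t * vy)) ** 2 + (xx - (x0 + t * vx)) ** 2
        canvas[rmin:rmax, cmin:cmax] += np.exp(-d2 / (2 * profile_sd**2))
    canvas = np.clip(canvas, 0, 1)
    polarized = np.clip(0.9 * canvas + rng.normal(0, noise_sd, (h, w)), 0, None)
    brightfield = np.clip(1.0 - 0.9 * canvas + rng.normal(0, noise_sd, (h, w)), 0, None)
    return polarized, brightfield, angles


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    n_transcripts: int,
    strain_traits: pd.Series,
    n_correlated: int,
    target_r: float = 0.9,
    noise_sd: float = 1.0,
    seed: int = 0,
    base_mean: float = 10.0,
):
    """Simulate a transcripts x strains log-intensity matrix.

    The first ``n_correlated`` transcripts are ``a*trait_z + noise`` with the
    loading ``a`` calibrated so the expected sample correlation with the trait
    is ``target_r``; the remainder are independent noise. Returns
    ``(matrix, correlated_ids)``.
    """
    if not (0 <= n_correlated <= n_transcripts):
        raise ValueError("n_correlated out of range")
    if abs(target_r) > 1:
        raise ValueError("|target_r| must be <= 1")
    sd_t = strain_traits.std(ddof=0)
    if sd_t == 0:
        raise ValueError("constant trait vector")
    rng = np.random.default_rng(seed)
    z = ((strain_traits - strain_traits.mean()) / sd_t).to_numpy()
    n_strains = z.size
    ids = [f"tx{i + 1:06d}" for i in range(n_transcripts)]
    mat = np.empty((n_transcripts, n_strains))
    if n_correlated:
        if abs(target_r) == 1:
            signal = np.sign(target_r) * z[None, :].repeat(n_correlated, axis=0)
        else:
            a = noise_sd * target_r / math.sqrt(1 - target_r**2)
            signal = a * z[None, :] + rng.normal(
                0, noise_sd, (n_correlated, n_strains)
            )
        scale = signal.std(axis=1, ddof=0)
        scale[scale == 0] = 1.0
        mat[:n_correlated] = base_mean + signal / scale[:, None]
    mat[n_correlated:] = base_mean + rng.normal(
        0, 1.0, (n_transcripts - n_correlated, n_strains)
    )
    np.clip(mat, 0.01, None, out=mat)
    df = pd.DataFrame(mat, index=ids, columns=strain_traits.index)
    return df, ids[:n_correlated]
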