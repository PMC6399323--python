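# Methods

This note documents the models, parameter choices, and numerical decisions
behind `ccinfarct`, and what the synthetic-data tests do and do not
demonstrate about real cohorts.

## Synthetic cohorts

The generator produces every input the pipeline consumes, with ground truth
retained for recovery tests.

**Founder panel and mosaics.** Eight founder haplotypes are drawn per SNP as
independent Bernoulli alleles with per-SNP minor-allele frequencies uniform
on [0.1, 0.5] by default (configurable, including degenerate values). Strain
genomes are founder tilings drawn directly: breakpoint counts per chromosome
are Poisson (default mean 3), positions uniform, founder identities i.i.d.
uniform. The breeding funnel is *not* simulated generation by generation;
the Poisson tiling reproduces the mosaic structure the inference machinery
must handle, differing from a true funnel only in the segment-length
distribution. Strains are fully inbred — one haplotype per strain — so all
genotypes are homozygous. Genotyping error is a symmetric allele flip
(default 0); missing calls are a separate configurable rate.

**Echo traits.** A single standardized strain value z (planted genetic
component scaled to a fraction h² of the strain-mean variance, plus strain
noise) drives both ΔEF and LVD, matching the phenotype definition in which
heart failure requires the two traits to agree. Per-animal values add
Gaussian noise (default SD 5 percentage points — deliberately config-exposed
because animal-level echo variance is cohort-specific) and are inverted
exactly into EF and volume pairs:
`EF_after = EF_before / (1 + ΔEF/100)`, `V_after = V_before (1 + LVD/100)`.
With zero animal noise the trait formulas therefore recover the planted
strain values exactly, a tested invariant. Default population parameters
(ΔEF mean 40, SD 18; LVD mean 40, SD 22; EF_before ≈ 60%; diastolic volume
≈ 55 µl; MI size ≈ 42 ± 4% of LV; heart rate ≈ 430 bpm) are realistic for a
mouse permanent-ligation model with large infarcts. Rupture-death logs are
generated by a separate helper mapping the standardized strain value to a
rupture probability `clip(0.30 + 0.25 z, 0.02, 0.98)` with deaths uniform on
days 3–5.

**Scar images.** Fibers are straight segments (default length 24 px) with a
Gaussian cross-section (SD 0.8 px) rendered analytically — anti-aliased
polyline rasterization was rejected because its intensity modulation along
the segment biases structure-tensor orientations by several degrees. Axial
angles are sampled by drawing from von Mises(2µ, κ) on the doubled circle
and halving, keeping the MVL–κ relationship analytic; κ = 0 means uniform
orientations. The polarized channel is fibers-bright, the brightfield
channel fibers-dark, with additive Gaussian noise.

**Expression.** Correlated transcripts are `a·z_trait + noise` with loading
`a = σ_noise · r/√(1−r²)` so the expected sample correlation is the target;
remaining transcripts are independent normals around a log-intensity
baseline of 10.

What the generator does *not* emulate: linkage disequilibrium beyond the
mosaic model, funnel-specific segment lengths, microarray probe effects,
image artifacts (uneven illumination, stain variability, channel
misregistration), or surgical-mortality mechanisms. Passing tests therefore
demonstrate correctness of the estimators under their stated models, not
robustness to those real-data complications.

## Trait derivation

Strain traits are means over included animals (SD reported alongside). The
inclusion rule is strict: infarct > 30% of LV; retained animals below the
~40% comparability screen only trigger a warning. The rupture trait is the
fraction of included animals not dying of rupture within days 3–5; deaths
outside the window or from other causes count as surviving the window. The
concordance rule — the criterion for excluding strains whose ΔEF and LVD
disagree — is necessarily a package decision (no published criterion
exists): a strain is discordant when the two traits' strain-level z-scores
have opposite signs and both exceed |z| > 0.5. Both the gate and the rule
object are configurable, and flags are always reported rather than silently
dropped. The rupture trait value used for mapping is the plain survival
fraction (no transform).

## Scar fiber analysis

Wall thickness is `(last − first tissue section) × 7 µm`; midwall sections
are those at relative depth within [0.40, 0.60] of the tissue span
(inclusive; at least 5 tissue sections required). Both channels are min–max
rescaled to [0, 1] before subtraction (raw cross-modality subtraction is
meaningless without normalization) and negatives clamped to zero. Area
fraction thresholding defaults to Otsu with an absolute-threshold fallback
(warned) for constant images.

Orientations are estimated per non-overlapping subwindow (default 16 px)
from the 2×2 structure tensor of Scharr-filtered gradients; the fiber angle
is perpendicular to the dominant gradient orientation
`0.5·atan2(2J_xy, J_xx − J_yy)`, the weight is the tensor trace, and
subwindows below a gradient-energy floor (default 1e-3) are invalid. Scharr
filters were chosen over central differences after measuring a ~4°
orientation bias toward the diagonals with the latter on synthetic fiber
fields; with Scharr the planted mean angle is recovered within 0.5°.
Angle convention everywhere: axial, degrees in [0, 180), 0° along the image
x-axis (the circumferential direction), increasing toward the y-axis.

Circular summaries double the angles, average the (optionally
weight-normalized) unit vectors, and report half the resultant's angle. The
group alignment test builds the group vector as the *unweighted* mean of the
per-sample vectors (MVLᵢ, θᵢ), projects each sample as
vᵢ = MVLᵢ·cos(2θᵢ − 2θ_m), and applies a two-sided one-sample t-test; zero
variance in v is reported as degenerate with an undefined p-value rather
than ±∞.

## Haplotype HMM

State space: the 8 founders (haploid — strains are inbred homozygotes; no
heterozygous states). Emissions: 1−ε on an allele match, ε on a mismatch
(default ε = 0.002), constant for missing calls. Transitions over a gap of
d bp: stay with e^{−γd}, leave mass split equally over the 7 other founders;
γ defaults to 1e-7 per bp, roughly matching a few switches per 100 Mb
chromosome. Both parameters are exposed — the published tooling for this
inference does not print its values, so these defaults are this package's
decisions. Informative SNPs require all founders called and both alleles
present among founders. Forward–backward runs in scaled linear arithmetic
(numerically safe here because per-SNP likelihood ratios are bounded by
(1−ε)/ε); the reported MAP path is the Viterbi path in log space. Posteriors
are validated against exhaustive path enumeration on small instances.
Downstream mapping uses the posterior probabilities as dosages, not the MAP
path — the standard choice for mixed-model mapping, and the one that
propagates uncertainty.

## Mixed-model QTL scan

Kinship is the mean inner product of founder-dosage vectors across loci,
rescaled to mean diagonal 1 (a Gram average, hence PSD); a
leave-one-chromosome-out variant is available. Variance components are
estimated once under the null by maximum likelihood — profiling the genetic
fraction h² over the eigendecomposition of K — and reused at every locus.
ML (not REML) is used so the likelihood-ratio nesting holds and LOD ≥ 0
everywhere. The alternative design at each locus is the eight dosage
columns with no explicit intercept: the columns sum to one, so the
intercept lies in their span, making the fit equivalent to the
drop-one-column-plus-intercept parameterization while keeping the centered
effect re-expression trivial. Rank-deficient loci (a founder absent from
the cohort) are fitted by pseudo-inverse with a warning. Per-locus fits are
batched over loci via normal equations for speed; exact per-locus behavior
is cross-checked against OLS log-likelihoods when K = I and h² = 0.

Permutations shuffle the raw trait across strains and re-estimate the null
variance components each time (simple and conservative; a kinship-aware
rotation scheme would be the natural alternative). The threshold at level α
is the ⌈(1−α)(n_perm+1)⌉-th order statistic of the max-LOD sample (capped
at the maximum) — the convention under which a new exchangeable scan
exceeds the threshold with probability ⌊α(n_perm+1)⌋/(n_perm+1), i.e. the
test is exactly level α. The simpler ⌈(1−α)·n_perm⌉ convention was measured
to have exact level 11/201 ≈ 0.055 at α = 0.05 with 200 permutations and
was replaced for that reason.

Support intervals walk outward from the peak to the first loci at
LOD ≤ peak − 2, pad by 10 kb, and clip to the chromosome; a peak that never
drops on either side spans the chromosome and is flagged. Founder effects
at a locus are GLS coefficients centered by C = I − 11ᵀ/8, with standard
errors from the propagated GLS covariance and two-sided Wald t-tests on
n − rank degrees of freedom (a Wald test is a package decision; the
likelihood-based alternative is not implemented). Candidate variants inside
an interval are kept if all implicated founders carry the alternate allele
and ranked by (1) allele private to the implicated founders, (2) severe
consequence (missense/splice and worse), (3) SIFT < 0.05, with ascending
SIFT and position as tie-breaks; SIFT scores are consumed as annotation,
never computed.

## Expression correlation

The scale transform is `2·(x − mean)/SD + 8` per transcript with the sample
(n−1) SD — the SD convention is stated explicitly because the upstream
database convention is not documented. Constant transcripts are excluded
with a warning. The expression filter keeps transcripts with mean
transformed value strictly above 7. Correlation is Pearson by default
(Spearman by rank transform), with p-values from the exact null t-transform
on n−2 degrees of freedom; results are ranked by |r| descending with
transcript-id tie-breaks. Upstream array normalization (robust spline) is
out of scope: inputs are assumed log2-normalized intensities.

## Problem sizes in the validation suite

The acceptance-style checks run at desk scale by design: threshold
calibration uses 50 strains × 200 loci with 200 permutations × 200 null
replicates; planted-QTL recovery uses 100 strains × ~200 loci × 50
replicates; HMM oracles enumerate 8⁵ paths; image recovery uses 256×256
renders. These sizes give the Monte Carlo checks 2σ-scale resolution (e.g.
±0.03 on a 0.05 type-I rate) while keeping the full suite in minutes.

## Known limitations

* The Poisson-tiling genome model understates long-range founder
  correlations of a real funnel pedigree; kinship estimated from it is
  correspondingly mild.
* Null variance components reused across loci (EMMA-style) slightly
  misestimate LOD at very strong loci; exact per-locus ML is not
  implemented (only the h²-pinned oracle path).
* The scan supports no covariates beyond the absorbed intercept and no
  epistasis; X-chromosome dosage is not special-cased.
* Image analysis assumes co-registered channel pairs and uniform
  illumination; there is no stain deconvolution or tiling of whole slides.
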