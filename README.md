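# ccinfarct

Analysis pipeline for post-myocardial-infarction (MI) outcome variation
across Collaborative Cross (CC) mouse strains, built for geneticists and
cardiovascular biologists mapping the genetic basis of heart-attack outcomes
in multi-parental recombinant inbred panels.

After coronary ligation, strains diverge in survival (myocardial rupture on
days 3–5), left-ventricular remodeling, and infarct scar structure. The
package derives the remodeling traits from echocardiography, quantifies scar
collagen from paired polarized/brightfield histology, reconstructs each
strain's eight-founder haplotype mosaic from SNP genotypes, scans the genome
for quantitative trait loci (QTL) with a kinship-adjusted mixed model, and
correlates cardiac transcript expression with the traits. A synthetic-cohort
generator with known ground truth exercises the whole pipeline.

## The models in brief

**Remodeling traits.** Per animal, with pre/post-MI ejection fraction EF and
diastolic LV volume V:

    LVD = V_after / V_before × 100 − 100          (percent dilation)
    ΔEF = (EF_before − EF_after) / EF_after × 100 (percent EF reduction)

Only animals with infarcts > 30% of the LV are analyzed; rupture
susceptibility is the per-strain fraction surviving the day 3–5 window.

**Scar fiber statistics.** Collagen is isolated by subtracting the
blue-filtered brightfield channel from the circularly polarized channel;
axial fiber orientations θᵢ ∈ [0°, 180°) are estimated per subwindow from
the image structure tensor. Because orientations are axial, angles are
doubled before averaging: the mean vector Σ wᵢ e^{2iθᵢ} / Σ wᵢ gives the
mean angle θ_m and mean vector length MVL ∈ [0, 1] (0 = random,
1 = perfectly aligned). Group alignment is tested by a one-sample t-test on
vᵢ = MVLᵢ · cos(2θᵢ − 2θ_m).

**Haplotype reconstruction.** An 8-state hidden Markov model over
informative SNPs (homozygous in all founders, both alleles represented)
with emission error ε and distance-dependent transitions
(stay probability e^{−γd} over d bp) yields posterior founder probabilities
by forward–backward; these posteriors are the dosages used for mapping.

**QTL scan.** At each locus, y = X·b + g + e with g ~ N(0, σ²_g K) for a
dosage-derived kinship K; variance components are fit once under the null
by maximum likelihood, and LOD = (n/2)·log₁₀(RSS₀/RSS₁) in the whitened
space. Genome-wide thresholds at P ≤ 0.05 / < 0.10 / < 0.63 come from trait
permutations; support intervals are two-LOD drops padded by 10 kb; founder
effects are centered GLS coefficients with Wald tests, feeding candidate-SNP
prioritization by founder of origin, consequence, and SIFT score.

**Expression correlation.** Transcripts are rescaled to Z-scores with mean 8
and SD 2, filtered at mean > 7, correlated with strain traits (Pearson by
default), and top correlates (|r| ≥ 0.60, top 500) are intersected across
traits. A ΔΔCT utility covers relative qPCR quantification.

## Worked example

Simulate 60 CC-like strains with a QTL on chr1 where the PWK haplotype
raises post-MI EF loss (h² = 0.5), then map it end to end:

```python
import numpy as np
from ccinfarct import simulate, haplotype, qtl, traits

panel = simulate.simulate_founders(n_snps_per_chrom=100, n_chroms=2, seed=42)
genomes = simulate.simulate_cc_panel(panel, n_strains=60, seed=43)
qtl_spec = simulate.QTLSpec(
    chromosome="chr1",
    position=int(panel.snp_positions["chr1"][55]),
    founder_effects=np.array([0, 0, 0, 0, 0, 0, 6.0, 0]),  # PWK effect
    h2=0.5,
)
records, _ = simulate.simulate_cohort_traits(
    genomes, qtl_spec, n_animals_per_strain=5, seed=44, panel=panel
)
table = traits.strain_trait_table(records)

probs = haplotype.infer_cohort(genomes, panel)
dosages = haplotype.stack_dosages(probs)
K = qtl.kinship_matrix(dosages)
scan = qtl.scan(table["delta_EF"], dosages, K, trait_name="delta_EF")
thresholds = qtl.permutation_thresholds(
    table["delta_EF"], dosages, K, n_perm=200, seed=45
)
peak = scan.peak_index()
interval = qtl.support_interval(scan)
effects = qtl.founder_effects(table["delta_EF"], dosages, K, peak)

print(f"peak: {scan.chrom[peak]}:{scan.pos[peak]}  LOD = {scan.lod[peak]:.1f}")
print(f"thresholds: P<=0.05 at LOD {thresholds[0.05]:.2f}, "
      f"P<0.63 at {thresholds[0.63]:.2f}")
print(f"support interval: {interval.start:,}-{interval.end:,} bp")
print(f"implicated founder: {simulate.FOUNDER_NAMES[effects.implicated()]}")
```

Output:

```
peak: chr1:55703215  LOD = 12.1
thresholds: P<=0.05 at LOD 6.54, P<0.63 at 3.38
support interval: 46,945,584-56,533,612 bp
implicated founder: PWK
```

The scan peaks one SNP away from the planted locus (55,458,478 bp, inside
the support interval), clears the genome-wide P ≤ 0.05 permutation
threshold, and correctly implicates the PWK founder (centered effect +64.1
trait units, Wald p = 5.4e-11).

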