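"""Mixed-model scan: kinship, LOD oracle, permutations, intervals, candidates."""

import numpy as np
import pandas as pd
import pytest

from ccinfarct import haplotype, qtl, simulate
from ccinfarct.haplotype import DosageSet
from ccinfarct.qtl import (
    QTLScan,
    SupportInterval,
    founder_effects,
    kinship_matrix,
    permutation_thresholds,
    prioritize_snps,
    scan,
    support_interval,
)


@pytest.fixture(scope="module")
def kinship(small_dosages):
    return kinship_matrix(small_dosages)


@pytest.fixture(scope="module")
def null_trait(small_dosages):
    rng = np.random.default_rng(55)
    return pd.Series(rng.standard_normal(small_dosages.n_strains),
                     index=small_dosages.strain_ids)


class TestKinship:
    def test_self_similarity_maximal(self, kinship):
        K = kinship.values
        assert np.all(np.diag(K) >= K.max(axis=1) - 1e-9)
        assert np.mean(np.diag(K)) == pytest.approx(1.0)

    def test_positive_semidefinite(self, kinship):
        assert np.linalg.eigvalsh(kinship.values).min() >= -1e-8

    def test_disjoint_mosaics_near_zero(self):
        # two strains with certain, non-overlapping founder assignments
        L = 50
        d = np.zeros((L, 2, 8))
        d[:, 0, 0] = 1.0
        d[:, 1, 5] = 1.0
        dset = DosageSet(np.full(L, "chr1", dtype=object),
                         np.arange(L) * 1000 + 1, d, ["a", "b"])
        K = kinship_matrix(dset).values
        assert K[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_loco_excludes_chromosome(self, small_dosages):
        K_all = kinship_matrix(small_dosages)
        K_loco = kinship_matrix(small_dosages, exclude_chromosome="chr1")
        assert "loco" in K_loco.method
        assert not np.allclose(K_all.values, K_loco.values)


class TestScan:
    def test_lod_nonnegative(self, small_dosages, kinship, null_trait):
        sc = scan(null_trait, small_dosages, kinship)
        assert np.all(sc.lod >= 0)
        assert np.all(np.isfinite(sc.coef))

    def test_affine_invariance(self, small_dosages, kinship, null_trait):
        sc1 = scan(null_trait, small_dosages, kinship)
        sc2 = scan(2.0 * null_trait + 3.0, small_dosages, kinship)
        np.testing.assert_allclose(sc1.lod, sc2.lod, atol=1e-6)

    def test_coefficients_centered(self, small_dosages, kinship, null_trait):
        sc = scan(null_trait, small_dosages, kinship)
        np.testing.assert_allclose(sc.coef.mean(axis=1), 0.0, atol=1e-9)

    def test_matches_ols_likelihood_ratio_oracle(self, small_dosages):
        """With K=I and h2 pinned to 0 the LOD must equal the ordinary
        regression LRT computed independently from OLS log-likelihoods."""
        import statsmodels.api as sm

        n = small_dosages.n_strains
        K = qtl.KinshipMatrix(np.eye(n), list(small_dosages.strain_ids), "identity")
        rng = np.random.default_rng(66)
        y = rng.standard_normal(n)
        sc = scan(y, small_dosages, K, fix_h2=0.0)
        for j in [0, 7, 33, small_dosages.n_loci - 1]:
            X = small_dosages.dosages[j]
            ll_alt = sm.OLS(y, X).fit().llf
            ll_null = sm.OLS(y, np.ones((n, 1))).fit().llf
            lod_oracle = (ll_alt - ll_null) / np.log(10)
            assert sc.lod[j] == pytest.approx(lod_oracle, abs=1e-6)

    def test_constant_trait_rejected(self, small_dosages, kinship):
        with pytest.raises(ValueError):
            scan(np.ones(small_dosages.n_strains), small_dosages, kinship)

    def test_power_increases_with_h2(self, small_panel, small_cohort):
        probs = haplotype.infer_cohort(small_cohort, small_panel)
        dset = haplotype.stack_dosages(probs)
        K = kinship_matrix(dset)
        pos = int(small_panel.snp_positions["chr1"][40])
        eff = np.array([0, 0, 0, 6.0, 0, 0, 0, 0])
        peaks = []
        for h2 in (0.1, 0.3, 0.5):
            lods = []
            for rep in range(8):
                qspec = simulate.QTLSpec("chr1", pos, eff, h2)
                _, truth = simulate.simulate_cohort_traits(
                    small_cohort, qspec, 1, seed=700 + rep, panel=small_panel
                )
                sc = scan(truth["delta_EF"], dset, K)
                lods.append(sc.lod.max())
            peaks.append(np.mean(lods))
        assert peaks[0] < peaks[1] < peaks[2]


class TestPermutations:
    def test_threshold_ordering_and_determinism(self, small_dosages, kinship,
                                                null_trait):
        th1 = permutation_thresholds(null_trait, small_dosages, kinship,
                                     n_perm=100, seed=5)
        th2 = permutation_thresholds(null_trait, small_dosages, kinship,
                                     n_perm=100, seed=5)
        assert th1.cutoffs == th2.cutoffs
        assert th1[0.05] >= th1[0.10] >= th1[0.63]

    def test_small_vs_large_nperm_agree_at_suggestive_level(
        self, small_dosages, kinship, null_trait
    ):
        th_small = permutation_thresholds(null_trait, small_dosages, kinship,
                                          n_perm=100, seed=6)
        th_large = permutation_thresholds(null_trait, small_dosages, kinship,
                                          n_perm=400, seed=7)
        # binomial MC error on the 0.37 quantile of max-LOD
        spread = np.quantile(th_large.max_lods, [0.50, 0.76])
        assert spread[0] - 0.3 <= th_small[0.63] <= spread[1] + 0.3

    def test_unresolvable_alpha_rejected(self, small_dosages, kinship, null_trait):
        with pytest.raises(ValueError):
            permutation_thresholds(null_trait, small_dosages, kinship,
                                   n_perm=100, seed=1, alphas=(0.001,))


def _triangle_scan():
    pos = (np.arange(21) + 1) * 1000
    lod = 10.0 - np.abs(np.arange(21) - 10).astype(float)
    return QTLScan(
        chrom=np.full(21, "chr1", dtype=object), pos=pos, lod=lod,
        coef=np.zeros((21, 8)), trait="t", n_strains=30, h2_null=0.0,
    )


class TestSupportInterval:
    def test_triangular_curve_two_loci_out_plus_pad(self):
        sc = _triangle_scan()
        si = support_interval(sc, drop=2.0, pad=10_000)
        # peak at index 10 (pos 11000); LOD drops by 2 at indices 8 and 12
        assert si.start == 9000 - 10_000 if 9000 - 10_000 > 0 else si.start == 0
        assert si.start == max(9000 - 10_000, 0)
        assert si.end == 13000 + 10_000
        assert si.contains("chr1", 11000)

    def test_pad_zero_gives_raw_boundaries(self):
        si = support_interval(_triangle_scan(), drop=2.0, pad=0)
        assert (si.start, si.end) == (9000, 13000)

    def test_flat_curve_whole_chromosome_warns(self):
        sc = _triangle_scan()
        sc.lod[:] = 5.0
        with pytest.warns(UserWarning):
            si = support_interval(sc, peak_index=10, drop=2.0, pad=0)
        assert si.whole_chromosome


class TestFounderEffects:
    def test_planted_founder_has_largest_effect(self, small_panel, small_cohort):
        probs = haplotype.infer_cohort(small_cohort, small_panel)
        dset = haplotype.stack_dosages(probs)
        K = kinship_matrix(dset)
        pos = int(small_panel.snp_positions["chr2"][40])
        qspec = simulate.QTLSpec("chr2", pos,
                                 np.array([0, 0, 0, 0, 0, 0, 8.0, 0]), 0.8)
        _, truth = simulate.simulate_cohort_traits(
            small_cohort, qspec, 1, seed=900, panel=small_panel
        )
        sc = scan(truth["delta_EF"], dset, K)
        fe = founder_effects(truth["delta_EF"], dset, K, sc.peak_index())
        assert fe.implicated() == 6
        assert fe.p[6] == fe.p.min()

    def test_founder_relabeling_permutes_coefficients(self, small_dosages,
                                                      kinship, null_trait):
        fe = founder_effects(null_trait, small_dosages, kinship, 10)
        perm = np.array([4, 2, 0, 7, 5, 1, 3, 6])
        dperm = DosageSet(small_dosages.chrom, small_dosages.pos,
                          small_dosages.dosages[:, :, perm],
                          small_dosages.strain_ids)
        fe_perm = founder_effects(null_trait, dperm, kinship, 10)
        np.testing.assert_allclose(fe_perm.coef, fe.coef[perm], atol=1e-8)


class TestPrioritizeSNPs:
    def _variants(self):
        rows = [
            # private to founder 6, deleterious missense inside interval
            dict(snp_id="rs1", chrom="chr1", pos=5000, consequence="missense",
                 sift=0.01),
            # shared with 3 other founders, missense
            dict(snp_id="rs2", chrom="chr1", pos=6000, consequence="missense",
                 sift=0.30),
            # outside interval
            dict(snp_id="rs3", chrom="chr1", pos=99_000, consequence="missense",
                 sift=0.01),
            # implicated founder does not carry
            dict(snp_id="rs4", chrom="chr1", pos=5500, consequence="missense",
                 sift=0.01),
            # private but synonymous
            dict(snp_id="rs5", chrom="chr1", pos=5200, consequence="synonymous",
                 sift=1.0),
        ]
        v = pd.DataFrame(rows)
        for k in range(8):
            v[f"founder_{k}"] = 0
        v.loc[v.snp_id.isin(["rs1", "rs2", "rs3", "rs5"]), "founder_6"] = 1
        for k in (0, 1, 2):
            v.loc[v.snp_id == "rs2", f"founder_{k}"] = 1
        v.loc[v.snp_id == "rs4", "founder_5"] = 1
        return v

    def test_tiers_and_filters(self):
        si = SupportInterval(chrom="chr1", peak_pos=5500, start=4000, end=8000,
                             peak_lod=9.0)
        ranked = prioritize_snps(si, self._variants(), [6])
        assert list(ranked["snp_id"]) == ["rs1", "rs5", "rs2"]
        assert ranked.loc[0, "tier"] == 1
        assert ranked.loc[2, "tier"] == 2  # shared allele retained, lower tier

    def test_empty_founder_set_rejected(self):
        si = SupportInterval(chrom="chr1", peak_pos=5500, start=4000, end=8000,
                             peak_lod=9.0)
        with pytest.raises(ValueError):
            prioritize_snps(si, self._variants(), [])
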