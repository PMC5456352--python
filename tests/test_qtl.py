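"""Map functions, interval mapping, permutation thresholds, cis/trans calls."""

import math

import numpy as np
import pandas as pd
import pytest

from riqtl import (
    classify_cis_trans,
    haldane_recombination,
    interval_map,
    permutation_thresholds,
    pseudomarker_probabilities,
    ri_expand,
    simulate_marker_map,
    simulate_ri_genotypes,
)
from riqtl.panel import GenotypeMatrix, MarkerMap
from riqtl.qtl import LRS_CAP, PermutationThresholds, QTLScan


def toy_map(positions_cM, chromosome="1", mb_per_cM=2.0):
    return MarkerMap(
        pd.DataFrame(
            {
                "chromosome": chromosome,
                "position_cM": positions_cM,
                "position_Mb": [p * mb_per_cM for p in positions_cM],
            },
            index=[f"m{i}" for i in range(1, len(positions_cM) + 1)],
        )
    )


def toy_genotypes(marker_map, columns):
    calls = pd.DataFrame(
        np.column_stack(columns),
        index=[f"S{i}" for i in range(1, len(columns[0]) + 1)],
        columns=marker_map.marker_ids,
    ).astype(float)
    return GenotypeMatrix(strains=list(calls.index), markers=marker_map, calls=calls)


class TestMapFunctions:
    def test_haldane_values(self):
        assert haldane_recombination(0.0) == 0.0
        assert np.isclose(haldane_recombination(50.0), (1 - math.exp(-1)) / 2)
        assert np.isclose(haldane_recombination(50.0), 0.31606, atol=1e-5)
        assert haldane_recombination(1e6) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            haldane_recombination(-1.0)

    def test_ri_expansion(self):
        assert ri_expand(0.0) == 0.0
        assert ri_expand(0.5) == pytest.approx(0.5)  # fixed point
        assert ri_expand(0.1) == pytest.approx(0.25)  # 0.4 / 1.6
        assert ri_expand(0.1, mating="self") == pytest.approx(0.2 / 1.2)
        with pytest.raises(ValueError):
            ri_expand(0.6)


class TestPseudomarkerProbabilities:
    def test_boundaries_and_symmetry(self):
        assert pseudomarker_probabilities(1, 1, 0.0, 0.0) == 1.0
        assert pseudomarker_probabilities(1, 1, 5.0, 5.0) > 0.5
        assert pseudomarker_probabilities(0, 1, 7.0, 7.0) == pytest.approx(0.5)
        assert pseudomarker_probabilities(None, None, 3.0, 3.0) == 0.5

    def test_single_flank_conditioning(self):
        R = ri_expand(haldane_recombination(10.0))
        assert pseudomarker_probabilities(1, None, 10.0, 0.0) == pytest.approx(1 - R)
        assert pseudomarker_probabilities(None, 0, 0.0, 10.0) == pytest.approx(R)

    def test_interior_point_matches_chain_enumeration(self):
        # brute-force enumeration over the unobserved middle state of the
        # two-step Markov chain with RI-expanded switch probabilities
        d1, d2 = 10.0, 10.0
        R1 = ri_expand(haldane_recombination(d1))
        R2 = ri_expand(haldane_recombination(d2))
        for left, right in [(1, 1), (0, 0), (1, 0), (0, 1)]:
            probs = {}
            for mid in (0, 1):
                p1 = (1 - R1) if mid == left else R1
                p2 = (1 - R2) if right == mid else R2
                probs[mid] = p1 * p2
            expected = probs[1] / (probs[0] + probs[1])
            got = pseudomarker_probabilities(left, right, d1, d2)
            assert got == pytest.approx(expected, abs=1e-12)


class TestIntervalMap:
    def test_constant_phenotype_gives_zero_profile(self):
        mm = toy_map([0.0, 20.0, 40.0])
        geno = simulate_ri_genotypes(mm, 10, seed=1)
        y = pd.Series(1.0, index=geno.strains)
        scan = interval_map(y, geno, step_cM=5.0)
        assert np.all(scan.lrs == 0.0)

    def test_hand_computed_lrs_at_marker(self):
        # two balanced genotype groups duplicated to 12 strains:
        # RSS0 = 2 * 1.54, RSS1 = 2 * 0.04, LRS = 12 ln(38.5)
        mm = toy_map([0.0, 50.0])
        g1 = [0, 0, 0, 1, 1, 1] * 2
        g2 = [0, 1] * 6
        geno = toy_genotypes(mm, [g1, g2])
        y = pd.Series([1.0, 1.1, 0.9, 2.0, 2.1, 1.9] * 2, index=geno.strains)
        scan = interval_map(y, geno, step_cM=50.0)
        at_m1 = scan.lrs[scan.loci.index.get_loc("m1")]
        assert at_m1 == pytest.approx(12 * math.log(1.54 / 0.04), abs=1e-9)

    def test_matches_ols_oracle_at_genotyped_markers(self):
        import statsmodels.api as sm

        mm = simulate_marker_map(2, 6, 60.0, seed=5)
        geno = simulate_ri_genotypes(mm, 25, seed=6)
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=25), index=geno.strains)
        scan = interval_map(y, geno, step_cM=1.0)
        rss0 = float(((y - y.mean()) ** 2).sum())
        for marker in mm.marker_ids:
            x = geno.calls[marker].to_numpy()
            fit = sm.OLS(y.to_numpy(), sm.add_constant(x)).fit()
            expected = 25 * math.log(rss0 / fit.ssr)
            got = scan.lrs[scan.loci.index.get_loc(marker)]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_affine_phenotype_invariance(self):
        mm = simulate_marker_map(2, 5, 60.0, seed=8)
        geno = simulate_ri_genotypes(mm, 20, seed=9)
        rng = np.random.default_rng(10)
        y = pd.Series(rng.normal(size=20), index=geno.strains)
        s1 = interval_map(y, geno, step_cM=2.0)
        s2 = interval_map(3.0 * y - 7.0, geno, step_cM=2.0)
        assert np.allclose(s1.lrs, s2.lrs, atol=1e-8)

    def test_perfect_fit_hits_cap(self):
        mm = toy_map([0.0, 30.0])
        geno = simulate_ri_genotypes(mm, 12, seed=11)
        y = geno.calls["m1"].astype(float)
        scan = interval_map(y, geno, step_cM=30.0)
        assert scan.lrs.max() == LRS_CAP

    def test_composite_mapping_absorbs_cofactor_qtl(self):
        mm = simulate_marker_map(2, 6, 60.0, seed=12)
        geno = simulate_ri_genotypes(mm, 40, seed=13)
        m_a = "m1_3"  # planted QTL, used as cofactor
        m_b = "m2_4"  # second planted QTL
        rng = np.random.default_rng(14)
        y = (
            geno.calls[m_a].astype(float)
            + 0.8 * geno.calls[m_b].astype(float)
            + rng.normal(0, 0.2, size=40)
        )
        scan = interval_map(y, geno, step_cM=2.0, cofactors=[m_a])
        at_cof = scan.lrs[scan.loci.index.get_loc(m_a)]
        assert at_cof < 1e-6  # cofactor column is collinear with the null model
        assert str(scan.peak["chromosome"]) == "2"

    def test_too_few_strains_rejected(self):
        mm = toy_map([0.0, 10.0])
        geno = simulate_ri_genotypes(mm, 6, seed=15)
        y = pd.Series(np.arange(6.0), index=geno.strains)
        with pytest.raises(ValueError, match="at least 8"):
            interval_map(y, geno)

    def test_unknown_cofactor_rejected(self):
        mm = toy_map([0.0, 10.0])
        geno = simulate_ri_genotypes(mm, 10, seed=16)
        y = pd.Series(np.arange(10.0), index=geno.strains)
        with pytest.raises(ValueError, match="cofactor"):
            interval_map(y, geno, cofactors=["nope"])


class TestPermutationThresholds:
    def test_deterministic_given_seed(self):
        mm = simulate_marker_map(2, 5, 60.0, seed=17)
        geno = simulate_ri_genotypes(mm, 20, seed=18)
        y = pd.Series(np.random.default_rng(19).normal(size=20), index=geno.strains)
        t1 = permutation_thresholds(y, geno, n_perm=200, seed=42)
        t2 = permutation_thresholds(y, geno, n_perm=200, seed=42)
        assert np.array_equal(t1.max_lrs_null, t2.max_lrs_null)
        assert t1.suggestive_lrs <= t1.significant_lrs

    def test_single_marker_threshold_near_chi2(self):
        # one locus, large n: the LRS null is asymptotically chi-square(1),
        # so the 95th percentile should sit near 3.84
        mm = toy_map([0.0])
        rng = np.random.default_rng(20)
        calls = pd.DataFrame(
            {"m1": rng.integers(0, 2, size=100).astype(float)},
            index=[f"S{i}" for i in range(100)],
        )
        geno = GenotypeMatrix(strains=list(calls.index), markers=mm, calls=calls)
        y = pd.Series(rng.normal(size=100), index=calls.index)
        t = permutation_thresholds(y, geno, n_perm=2000, seed=21)
        assert t.significant_lrs == pytest.approx(3.84, abs=0.5)

    def test_bigger_genome_raises_threshold(self):
        mm_small = simulate_marker_map(1, 10, 80.0, seed=22)
        mm_big = simulate_marker_map(20, 10, 80.0, seed=22)
        diffs = []
        for rep in range(20):
            geno_s = simulate_ri_genotypes(mm_small, 30, seed=100 + rep)
            geno_b = simulate_ri_genotypes(mm_big, 30, seed=100 + rep)
            y = pd.Series(
                np.random.default_rng(200 + rep).normal(size=30), index=geno_s.strains
            )
            ts = permutation_thresholds(y, geno_s, n_perm=300, step_cM=2.0, seed=rep)
            tb = permutation_thresholds(y, geno_b, n_perm=300, step_cM=2.0, seed=rep)
            diffs.append(tb.significant_lrs - ts.significant_lrs)
        assert np.mean(diffs) > 0

    def test_too_few_permutations_rejected(self):
        mm = toy_map([0.0, 10.0])
        geno = simulate_ri_genotypes(mm, 10, seed=23)
        y = pd.Series(np.arange(10.0), index=geno.strains)
        with pytest.raises(ValueError, match="100"):
            permutation_thresholds(y, geno, n_perm=50)


class TestCisTransCall:
    @staticmethod
    def scan_with_peak(chromosome, mb, lrs):
        loci = pd.DataFrame(
            {
                "chromosome": [chromosome, "1"],
                "position_cM": [10.0, 20.0],
                "position_Mb": [mb, 40.0],
                "is_pseudomarker": [False, False],
            },
            index=["peak", "other"],
        )
        return QTLScan(gene="Cd14", loci=loci, lrs=np.array([lrs, 0.1]))

    @staticmethod
    def thresholds(significant=16.0):
        null = np.full(100, significant - 5.0)
        null[-5:] = significant  # 95th percentile lands at `significant`
        return PermutationThresholds(n_perm=100, max_lrs_null=null)

    def test_significant_peak_near_gene_is_cis(self):
        scan = self.scan_with_peak("18", 36.5, 18.2)
        call = classify_cis_trans(scan, self.thresholds(), "18", 36.88)
        assert call.call == "cis"

    def test_significant_peak_elsewhere_is_trans(self):
        scan = self.scan_with_peak("4", 36.5, 18.2)
        call = classify_cis_trans(scan, self.thresholds(), "1", 40.0)
        assert call.call == "trans"

    def test_no_significant_peak_is_none(self):
        scan = self.scan_with_peak("18", 36.5, 5.0)
        call = classify_cis_trans(scan, self.thresholds(), "18", 36.88)
        assert call.call == "none"

    def test_unknown_chromosome_rejected(self):
        scan = self.scan_with_peak("18", 36.5, 18.2)
        with pytest.raises(ValueError, match="chromosome"):
            classify_cis_trans(scan, self.thresholds(), "chrX", 36.88)
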