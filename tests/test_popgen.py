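"""Allele frequencies, F_ST, HWE, permutation panmixia test, PCA,
paired-locus correlation, linkage screen and Fisher's combined test."""

import numpy as np
import pandas as pd
import pytest

from rsta import hybsim, popgen
from rsta.popgen import (allele_frequencies, benjamini_hochberg,
                         fishers_combined, fst_locus, fst_table, hwe_test,
                         individual_heterozygosity, ld_screen, mean_fst,
                         paired_fst_correlation, pca_individuals,
                         permute_panmixia, top_fst_subset)

from conftest import (brute_force_allele_freq, brute_force_bh,
                      brute_force_fisher, brute_force_fst)


def _matrix(rows, pops=("pop1",) * 3):
    inds = [f"i{j}" for j in range(len(pops))]
    geno = pd.DataFrame(rows, columns=inds,
                        index=[f"L{i}" for i in range(len(rows))])
    return geno, pd.Series(pops, index=inds)


class TestAlleleFrequencies:
    def test_three_genotypes_give_half(self):
        geno, pops = _matrix([["CC", "CU", "UU"]])
        out = allele_frequencies(geno, pops)
        assert out.loc["L0", "p_pop1"] == 0.5
        assert out.loc["L0", "n_called_pop1"] == 3

    def test_all_reference_gives_zero(self):
        geno, pops = _matrix([["CC", "CC", "CC"]])
        assert allele_frequencies(geno, pops).loc["L0", "p_pop1"] == 0.0

    def test_missing_pairwise_deleted(self):
        geno, pops = _matrix([["NA", "CU", "UU"]])
        out = allele_frequencies(geno, pops)
        assert out.loc["L0", "p_pop1"] == pytest.approx(3 / 4)
        assert out.loc["L0", "n_called_pop1"] == 2

    def test_matches_hand_count_oracle(self, genotype_matrix_small):
        geno, pops = genotype_matrix_small
        out = allele_frequencies(geno, pops)
        for pop in ("pop1", "pop2"):
            cols = pops.index[pops == pop]
            for locus in geno.index:
                expected = brute_force_allele_freq(
                    list(geno.loc[locus, cols]))
                assert out.loc[locus, f"p_{pop}"] == pytest.approx(expected)

    def test_invalid_code_rejected(self):
        geno, pops = _matrix([["CC", "XX", "UU"]])
        with pytest.raises(ValueError):
            allele_frequencies(geno, pops)


class TestFst:
    @pytest.mark.parametrize("p,expected", [
        ((0.5, 0.5), 0.0),
        ((1.0, 0.0), 1.0),
        ((0.8, 0.2), 0.36),  # H_T = 0.5, H_S = 0.32
    ])
    def test_formula_examples(self, p, expected):
        assert fst_locus(p) == pytest.approx(expected)

    def test_fixed_identical_populations_undefined(self):
        assert np.isnan(fst_locus((0.0, 0.0)))

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            fst_locus((0.5,))

    def test_table_matches_brute_force(self, genotype_matrix_small):
        geno, pops = genotype_matrix_small
        table = fst_table(geno, pops)
        freqs = allele_frequencies(geno, pops)
        for locus in geno.index:
            p = [freqs.loc[locus, "p_pop1"], freqs.loc[locus, "p_pop2"]]
            expected = brute_force_fst(p)
            got = table.loc[locus, "fst"]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)

    def test_low_call_rate_locus_excluded(self):
        rows = [["CC", "NA", "NA", "CU", "UU", "UU"]]
        geno, pops = _matrix(rows, pops=("pop1",) * 3 + ("pop2",) * 3)
        table = fst_table(geno, pops)
        assert not table.loc["L0", "usable"]

    def test_parameter_recovery_bias_corrected(self):
        """The corrected multilocus estimator recovers the simulated F_ST
        from genotype data of 20 individuals."""
        spec = hybsim.PopulationSpec(n_loci=3000, fraction_polymorphic=1.0,
                                     fraction_indel=0.0, fst_sim=0.05,
                                     seed=13)
        truth = hybsim.simulate_genotypes(spec)
        table = fst_table(truth.genotype_codes(), truth.populations,
                          corrected=True)
        assert mean_fst(table, weighted=True) == pytest.approx(0.05,
                                                               abs=0.01)


class TestHeterozygosity:
    def test_all_het_individual(self):
        geno, pops = _matrix([["CU", "CC", "CC"], ["CU", "CU", "UU"]])
        het, _ = individual_heterozygosity(geno, pops)
        assert het["i0"] == 1.0

    def test_all_missing_individual_nan(self):
        geno, pops = _matrix([["NA", "CC", "CU"], ["NA", "CU", "UU"]])
        het, _ = individual_heterozygosity(geno, pops)
        assert np.isnan(het["i0"])

    def test_population_difference_detected(self):
        """Higher heterozygosity in one population is picked up by the KS
        comparison at large locus count."""
        rng = np.random.default_rng(4)
        n_loci = 800
        qa, qb = 0.15, 0.5  # 2q(1-q): 0.255 vs 0.5
        a = rng.binomial(2, qa, size=(n_loci, 10))
        b = rng.binomial(2, qb, size=(n_loci, 10))
        codes = np.array(["CC", "CU", "UU"])
        geno = pd.DataFrame(np.hstack([codes[a], codes[b]]),
                            index=[f"L{i}" for i in range(n_loci)],
                            columns=[f"i{j}" for j in range(20)])
        pops = pd.Series(["pop1"] * 10 + ["pop2"] * 10, index=geno.columns)
        _, ks = individual_heterozygosity(geno, pops)
        assert ks["mean_b"] > ks["mean_a"]
        assert ks["pvalue"] < 0.01


class TestHWE:
    def test_exact_equilibrium(self):
        rows = [["CC"] * 25 + ["CU"] * 50 + ["UU"] * 25]
        geno, pops = _matrix(rows, pops=("pop1",) * 100)
        out = hwe_test(geno, pops)
        assert out["chi2"].iloc[0] == pytest.approx(0.0)
        assert out["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_no_heterozygotes_chi2_equals_n(self):
        rows = [["CC"] * 50 + ["UU"] * 50]
        geno, pops = _matrix(rows, pops=("pop1",) * 100)
        out = hwe_test(geno, pops)
        assert out["chi2"].iloc[0] == pytest.approx(100.0)
        assert out["pvalue"].iloc[0] < 1e-20

    def test_simulated_loci_in_equilibrium(self, genotype_matrix_small):
        """Binomially sampled genotypes stay in HWE after BH correction."""
        spec = hybsim.PopulationSpec(n_loci=300, fraction_polymorphic=1.0,
                                     fraction_indel=0.0, fst_sim=0.0,
                                     seed=21)
        truth = hybsim.simulate_genotypes(spec)
        out = hwe_test(truth.genotype_codes(), truth.populations)
        assert (out["pvalue_bh"] >= 0.05).all()


class TestMultipleTesting:
    def test_bh_worked_example(self):
        got = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_hand_procedure(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 37)
        assert np.allclose(benjamini_hochberg(p), brute_force_bh(list(p)))

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 50)
        adj = benjamini_hochberg(p)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_fisher_examples(self):
        x, p = fishers_combined([1.0, 1.0])
        assert x == 0.0 and p == 1.0
        _, p = fishers_combined([0.05])
        assert p == pytest.approx(0.05)
        x, p = fishers_combined([0.1, 0.1])
        assert x == pytest.approx(9.2103, abs=1e-3)
        assert p == pytest.approx(0.0563, abs=1e-3)

    def test_fisher_matches_closed_form(self):
        rng = np.random.default_rng(2)
        p = list(rng.uniform(0.001, 1, 7))
        x_ref, p_ref = brute_force_fisher(p)
        x, pv = fishers_combined(p)
        assert x == pytest.approx(x_ref)
        assert pv == pytest.approx(p_ref)

    def test_fisher_invalid_inputs(self):
        with pytest.raises(ValueError):
            fishers_combined([])
        with pytest.raises(ValueError):
            fishers_combined([0.0, 0.5])


class TestPermutation:
    def test_deterministic(self, genotype_matrix_small):
        geno, pops = genotype_matrix_small
        a = permute_panmixia(geno, pops, n_permutations=10, seed=3)
        b = permute_panmixia(geno, pops, n_permutations=10, seed=3)
        assert np.array_equal(a.permuted_means, b.permuted_means)

    def test_structured_data_exceeds_null(self):
        """With simulated F_ST 0.05 the observed mean outranks virtually
        every allele permutation."""
        spec = hybsim.PopulationSpec(n_loci=1000, fraction_polymorphic=1.0,
                                     fraction_indel=0.0, fst_sim=0.05,
                                     seed=29)
        truth = hybsim.simulate_genotypes(spec)
        s = permute_panmixia(truth.genotype_codes(), truth.populations,
                             n_permutations=500, seed=5)
        assert s.rank_of_observed_mean >= 0.99
        assert s.observed_mean > s.permuted_means.mean()

    def test_tail_counts_reported(self, genotype_matrix_small):
        geno, pops = genotype_matrix_small
        s = permute_panmixia(geno, pops, n_permutations=20, seed=1,
                             tail_cutoffs=(0.2, 0.4))
        assert set(s.observed_tail_counts) == {0.2, 0.4}
        assert s.permuted_tail_counts[0.2].shape == (20,)
        assert s.observed_tail_counts[0.4] <= s.observed_tail_counts[0.2]

    def test_individual_unit_mode(self, genotype_matrix_small):
        geno, pops = genotype_matrix_small
        s = permute_panmixia(geno, pops, n_permutations=10, seed=2,
                             unit="individual")
        assert s.n_permutations == 10


class TestTopFst:
    def test_single_outlier(self):
        fst = pd.Series([0.0] * 30 + [0.5],
                        index=[f"L{i}" for i in range(31)])
        top, threshold = top_fst_subset(fst)
        assert list(top) == ["L30"]
        assert threshold < 0.5

    def test_gaussian_tail_fraction(self):
        rng = np.random.default_rng(6)
        fst = pd.Series(rng.normal(0.1, 0.02, 20000))
        top, _ = top_fst_subset(fst)
        # mean + 2 sd cuts ~2.3% of a normal sample
        assert 0.015 < len(top) / len(fst) < 0.032


class TestPairedCorrelation:
    def test_identical_vectors(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 0.3, 50)
        out = paired_fst_correlation(
            pd.DataFrame({"fst_a": v, "fst_b": v}), n_permutations=200,
            seed=0)
        assert out["r"] == pytest.approx(1.0)
        assert out["pvalue"] < 0.01

    def test_independent_pairs_null(self):
        rng = np.random.default_rng(1)
        out = paired_fst_correlation(
            pd.DataFrame({"fst_a": rng.uniform(0, 0.3, 200),
                          "fst_b": rng.uniform(0, 0.3, 200)}),
            n_permutations=500, seed=0)
        assert abs(out["r"]) < 0.2
        assert out["pvalue"] > 0.01

    def test_duplicate_genes_collapsed(self):
        df = pd.DataFrame({"gene": ["g1", "g1", "g2", "g3", "g4"],
                           "fst_a": [0.1, 0.9, 0.2, 0.3, 0.4],
                           "fst_b": [0.1, 0.9, 0.2, 0.3, 0.4]})
        out = paired_fst_correlation(df, n_permutations=50, seed=0)
        assert out["n_pairs"] == 4


class TestLdScreen:
    def test_self_pair_perfectly_associated(self):
        rng = np.random.default_rng(0)
        codes = np.array(["CC", "CU", "UU"])
        col = codes[rng.integers(0, 3, 40)]
        geno = pd.DataFrame([col, col],
                            index=["a", "b"],
                            columns=[f"i{j}" for j in range(40)])
        out = ld_screen(geno, ["a", "b"], n_permutations=200, seed=1)
        assert out["pvalue"].iloc[0] <= 2 / 201

    def test_independent_loci_type_one_controlled(self):
        spec = hybsim.PopulationSpec(n_loci=12, fraction_polymorphic=1.0,
                                     fraction_indel=0.0, fst_sim=0.0,
                                     seed=17, n_per_population=20)
        truth = hybsim.simulate_genotypes(spec)
        out = ld_screen(truth.genotype_codes(), truth.locus_ids,
                        n_permutations=200, seed=2)
        tested = out[~out["skipped"]]
        assert (tested["pvalue_bh"] < 0.05).mean() <= 0.05

    def test_sparse_pair_skipped(self):
        geno = pd.DataFrame(
            {"i0": ["CC", "CC"], "i1": ["NA", "CU"], "i2": ["CU", "NA"],
             "i3": ["NA", "NA"], "i4": ["UU", "NA"], "i5": ["NA", "UU"]},
            index=["a", "b"])
        out = ld_screen(geno, ["a", "b"], n_permutations=10, seed=0)
        assert bool(out["skipped"].iloc[0])


class TestPCA:
    def test_duplicated_individuals_identical_coordinates(self):
        rng = np.random.default_rng(0)
        lr = pd.DataFrame(rng.normal(0, 1, (50, 6)),
                          index=[f"L{i}" for i in range(50)],
                          columns=[f"i{j}" for j in range(6)])
        lr["dup"] = lr["i0"]
        coords, _ = pca_individuals(lr)
        assert np.allclose(coords.loc["i0"], coords.loc["dup"], atol=1e-9)

    def test_locus_order_invariant_up_to_sign(self):
        rng = np.random.default_rng(1)
        lr = pd.DataFrame(rng.normal(0, 1, (40, 8)),
                          index=[f"L{i}" for i in range(40)],
                          columns=[f"i{j}" for j in range(8)])
        a, _ = pca_individuals(lr)
        b, _ = pca_individuals(lr.sample(frac=1, random_state=2))
        for col in a.columns:
            assert (np.allclose(a[col], b[col], atol=1e-8)
                    or np.allclose(a[col], -b[col], atol=1e-8))

    def test_structured_populations_separate(self):
        """Log ratios carrying a strong frequency difference separate the
        two populations on the leading components."""
        from sklearn.metrics import silhouette_score
        spec = hybsim.PopulationSpec(n_loci=400, fraction_polymorphic=1.0,
                                     fraction_indel=0.0, fst_sim=0.15,
                                     seed=19)
        truth = hybsim.simulate_genotypes(spec)
        rng = np.random.default_rng(3)
        lr = pd.DataFrame(
            -0.7 * truth.dosage + rng.normal(0, 0.1, truth.dosage.shape),
            index=truth.locus_ids, columns=truth.individual_ids)
        coords, _ = pca_individuals(lr)
        labels = truth.populations.reindex(coords.index)
        assert silhouette_score(coords.to_numpy()[:, :2], labels) > 0

    def test_subsets_partition_loci(self):
        rng = np.random.default_rng(5)
        fst = pd.Series(np.r_[rng.normal(0.05, 0.01, 97), [0.4, 0.5, 0.6]],
                        index=[f"L{i}" for i in range(100)])
        top, _ = top_fst_subset(fst)
        rest = fst.index.difference(top)
        assert len(top) + len(rest) == 100
        assert set(top) | set(rest) == set(fst.index)
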