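import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tas2rpop.diversity import (
    codon_pathway_differences,
    concatenate_class,
    dxy,
    empirical_percentile,
    nei_gojobori_sites,
    nucleotide_diversity,
    site_fst,
    syn_nonsyn_diversity,
)
from tas2rpop.errors import InputError
from tas2rpop.io import GeneAlignment

from _oracles import (
    BASES,
    dxy_bruteforce,
    ng_pathway_enumerate,
    ng_sites_enumerate,
    pi_bruteforce,
    pin_pis_bruteforce,
    random_alignment,
)


class TestNucleotideDiversity:
    def test_monomorphic_is_zero(self):
        pi, L, S = nucleotide_diversity(["ACGTAC"] * 5)
        assert (pi, L, S) == (0.0, 6, 0)

    def test_single_pair_single_difference(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        pi, L, S = nucleotide_diversity([a, b])
        assert (pi, L, S) == (0.01, 100, 1)

    def test_gap_and_n_columns_removed_first(self):
        pi, L, S = nucleotide_diversity(["AC-TA", "ACGTN", "ACGTA"])
        assert L == 3 and S == 0 and pi == 0.0

    def test_n_below_two_is_na(self):
        pi, L, S = nucleotide_diversity(["ACGT"])
        assert math.isnan(pi)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, L = int(rng.integers(2, 7)), int(rng.integers(4, 31))
        seqs = ["".join(rng.choice(list(BASES + "-N"), size=L, p=[0.23] * 4 + [0.04, 0.04]))
                for _ in range(n)]
        got = nucleotide_diversity(seqs)
        want = pi_bruteforce(seqs)
        if math.isnan(want[0]):
            assert math.isnan(got[0])
        else:
            assert got[0] == pytest.approx(want[0])
            assert got[1:] == want[1:]

    def test_invariant_under_relabeling(self, rng):
        seqs = random_alignment(rng, 5, 8)
        shuffled = list(seqs)
        rng.shuffle(shuffled)
        assert nucleotide_diversity(seqs) == nucleotide_diversity(shuffled)


class TestNeiGojobori:
    def test_phe_codon_site_counts(self):
        syn, nonsyn = nei_gojobori_sites("TTT")
        assert syn == pytest.approx(1 / 3)
        assert nonsyn == pytest.approx(8 / 3)

    def test_two_position_pathway_average(self):
        assert codon_pathway_differences("TTT", "GTA") == (0.5, 1.5)

    def test_identical_codons_no_differences(self):
        assert codon_pathway_differences("CTT", "CTT") == (0.0, 0.0)

    def test_bad_length_rejected(self):
        with pytest.raises(InputError):
            nei_gojobori_sites("TTTT")

    def test_all_sense_codons_match_enumeration(self):
        from Bio.Seq import Seq

        checked = 0
        for codon in map("".join, itertools.product(BASES, repeat=3)):
            if str(Seq(codon).translate()) == "*":
                # stop codons contribute no sites by construction
                assert nei_gojobori_sites(codon) == (0.0, 0.0)
                continue
            assert nei_gojobori_sites(codon) == pytest.approx(ng_sites_enumerate(codon))
            checked += 1
        assert checked == 61

    def test_all_two_position_pairs_match_enumeration(self):
        codons = [c for c in map("".join, itertools.product(BASES, repeat=3))]
        for ca in codons:
            for cb in codons:
                if sum(a != b for a, b in zip(ca, cb)) != 2:
                    continue
                assert codon_pathway_differences(ca, cb) == pytest.approx(
                    ng_pathway_enumerate(ca, cb)
                )


class TestSynNonsynDiversity:
    def test_fixed_population_is_zero_zero(self):
        seqs = ["ATGCTTACTTTTTAA"] * 4
        assert syn_nonsyn_diversity(seqs) == (0.0, 0.0)

    def test_single_synonymous_difference_separates_classes(self):
        a = "ATG" + "CTT" + "TTT" + "CAT" + "TAA"
        b = "ATG" + "CTT" + "TTC" + "CAT" + "TAA"
        pi_s, pi_n = syn_nonsyn_diversity([a, b])
        assert pi_n == 0.0 and pi_s > 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pair_and_pathway_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        seqs = random_alignment(rng, int(rng.integers(2, 6)), int(rng.integers(5, 11)))
        got = syn_nonsyn_diversity(seqs)
        want = pin_pis_bruteforce(seqs)
        assert got == pytest.approx(want, nan_ok=True)


class TestDxy:
    def test_identical_monomorphic_populations(self):
        assert dxy(["ACGT"] * 3, ["ACGT"] * 2) == 0.0

    def test_fixed_single_difference(self):
        a = ["A" * 100] * 3
        b = ["A" * 99 + "G"] * 4
        assert dxy(a, b) == pytest.approx(0.01)

    def test_empty_population_is_na(self):
        assert math.isnan(dxy([], ["ACGT"]))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_cross_pairs_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        L = int(rng.integers(4, 31))
        mk = lambda n: ["".join(rng.choice(list(BASES), size=L)) for _ in range(n)]
        a, b = mk(int(rng.integers(1, 6))), mk(int(rng.integers(1, 6)))
        assert dxy(a, b) == pytest.approx(dxy_bruteforce(a, b))


class TestSiteFst:
    def test_fixed_difference_is_exactly_one(self):
        assert site_fst((0, 92), (20, 20)) == 1.0

    def test_identical_frequencies_near_zero(self):
        assert abs(site_fst((46, 92), (10, 20))) < 0.02

    def test_derived_only_in_larger_population(self):
        # closed-form hand computation of the HSM estimator
        hw = (92 * (2 * 70 * 22 / (92 * 91))) / 112
        hb = (70 * 20) / (92 * 20)
        assert site_fst((70, 92), (0, 20)) == pytest.approx(1 - hw / hb)

    def test_no_between_diversity_is_na(self):
        assert math.isnan(site_fst((0, 92), (0, 20)))

    @given(
        ka=st.integers(0, 92), kb=st.integers(0, 20),
    )
    @settings(max_examples=200, deadline=None)
    def test_never_exceeds_one(self, ka, kb):
        f = site_fst((ka, 92), (kb, 20))
        if not math.isnan(f):
            assert f <= 1.0
            if f == 1.0:
                assert ka in (0, 92) and kb in (0, 20)


class TestEmpiricalPercentile:
    def test_below_minimum_is_one(self):
        assert empirical_percentile(0.1, [0.2, 0.3, 0.4]) == 1.0

    def test_tie_counts_in_tail(self):
        assert empirical_percentile(0.3, [0.2, 0.3, 0.4]) >= 0.5

    def test_empty_reference_rejected(self):
        with pytest.raises(InputError):
            empirical_percentile(0.5, [])


class TestConcatenation:
    def _aln(self, gene, seqs):
        return GeneAlignment(gene, seqs)

    def test_equal_length_genes_average(self):
        a = self._aln("g1", {"c1": "A" * 10, "c2": "A" * 9 + "G"})
        b = self._aln("g2", {"c1": "C" * 10, "c2": "C" * 10})
        cat = concatenate_class([a, b])
        pi_a = nucleotide_diversity(list(a.sequences.values()))[0]
        pi_b = nucleotide_diversity(list(b.sequences.values()))[0]
        pi_cat = nucleotide_diversity(list(cat.sequences.values()))[0]
        assert pi_cat == pytest.approx((pi_a + pi_b) / 2)

    def test_pi_is_length_weighted_mean(self, rng):
        genes = []
        for i, ncod in enumerate((4, 7, 11)):
            seqs = random_alignment(rng, 4, ncod)
            genes.append(self._aln(f"g{i}", {f"c{j}": s for j, s in enumerate(seqs)}))
        cat = concatenate_class(genes)
        num = den = 0.0
        for g in genes:
            pi, L, _ = nucleotide_diversity(list(g.sequences.values()))
            num += pi * L
            den += L
        pi_cat, L_cat, _ = nucleotide_diversity(list(cat.sequences.values()))
        assert L_cat == den
        assert pi_cat == pytest.approx(num / den)

    def test_single_gene_identity(self):
        a = self._aln("g1", {"c1": "ACGT", "c2": "ACGA"})
        cat = concatenate_class([a])
        assert cat.sequences == a.sequences

    def test_chromosome_mismatch_policies(self):
        a = self._aln("g1", {"c1": "ACGT", "c2": "ACGA"})
        b = self._aln("g2", {"c1": "ACGT"})
        assert list(concatenate_class([a, b]).sequences) == ["c1"]
        with pytest.raises(InputError):
            concatenate_class([a, b], on_mismatch="error")

    def test_study_class_concatenation_length(self, study_dataset):
        ds = study_dataset
        old = [ds.alignments[g] for g, c, _ in ds.gene_config.genes if c == "old"]
        cat = concatenate_class(old)
        assert cat.length == sum(a.length for a in old)
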