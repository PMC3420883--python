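import itertools

import pytest

from tas2rpop.catalog import (
    call_variants,
    catalog_table,
    collapse_haplotypes,
    deletion_span,
    functional_status,
    sharing_summary,
)
from tas2rpop.errors import InputError
from tas2rpop.io import GeneAlignment, PopulationManifest

from _oracles import BASES, translate_codon


def _orf_alignment(codon, mutated_codon, manifest, carrier="e0"):
    """12-column ORF with `codon` at codon 3; `carrier` gets `mutated_codon`."""
    base = "ATG" + "CTT" + codon + "TAA"
    seqs = {
        c: ("ATG" + "CTT" + (mutated_codon if c == carrier else codon) + "TAA")
        for c, _, _ in manifest.entries
    }
    return GeneAlignment("g", seqs), base


class TestEffectClassification:
    SENSE_CODONS = [
        "".join(c)
        for c in itertools.product(BASES, repeat=3)
        if translate_codon("".join(c)) != "*"
    ]

    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_all_single_base_mutations_match_codon_table(self, codon, small_manifest):
        """Exhaustive check over all 61 sense codons x 9 single-base changes
        placed at an interior codon: effect agrees with direct translation
        (stop codons cannot occupy an interior reference position)."""
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                aln, ref = _orf_alignment(codon, mut, small_manifest)
                variants = call_variants(aln, small_manifest, reference_seq=ref)
                assert len(variants) == 1
                expected = (
                    "gain_of_stop"
                    if translate_codon(mut) == "*"
                    else "synonymous"
                    if translate_codon(mut) == translate_codon(codon)
                    else "nonsynonymous"
                )
                assert variants[0].effect == expected
                assert variants[0].position == 7 + pos

    def test_loss_of_start_takes_precedence(self, small_manifest):
        seqs = {c: "ATGCTTTTTTAA" for c, _, _ in small_manifest.entries}
        seqs["e0"] = "GTGCTTTTTTAA"
        variants = call_variants(
            GeneAlignment("g", seqs), small_manifest, reference_seq="ATGCTTTTTTAA"
        )
        assert [v.effect for v in variants] == ["loss_of_start"]
        assert variants[0].position == 1

    def test_loss_of_stop(self, small_manifest):
        seqs = {c: "ATGCTTTTTTAA" for c, _, _ in small_manifest.entries}
        seqs["e0"] = "ATGCTTTTTCAA"
        variants = call_variants(
            GeneAlignment("g", seqs), small_manifest, reference_seq="ATGCTTTTTTAA"
        )
        assert [v.effect for v in variants] == ["loss_of_stop"]

    def test_gap_run_is_one_frameshift_indel(self, small_manifest):
        ref = "ATGCTTCTTCTTTTTTAA"
        seqs = {c: ref for c, _, _ in small_manifest.entries}
        seqs["w0"] = "ATGCTT-----TTTTTAA"
        variants = call_variants(GeneAlignment("g", seqs), small_manifest, reference_seq=ref)
        assert len(variants) == 1
        v = variants[0]
        assert v.effect == "indel" and v.frameshift
        assert v.position == 7 and len(v.ref_state) == 5
        assert v.counts["west"] == (1, 4) and v.counts["east"] == (0, 4)

    def test_identical_sequences_yield_no_variants(self, small_manifest):
        seqs = {c: "ATGCTTTTTTAA" for c, _, _ in small_manifest.entries}
        assert call_variants(GeneAlignment("g", seqs), small_manifest,
                             reference_seq="ATGCTTTTTTAA") == []

    def test_missing_reference_rejected(self, small_alignment, small_manifest):
        with pytest.raises(InputError, match="reference"):
            call_variants(small_alignment, small_manifest)


class TestFunctionalStatus:
    def test_alternative_start_rescues_loss_of_start(self):
        # no ATG at 1-3 but ATG at 4-6: still translatable
        assert functional_status("GTGATGCTTCTTTAA") == ("functional", "none")

    def test_loss_of_start_without_rescue(self):
        assert functional_status("GTGCTTCTTCTTTAA") == ("nonfunctional", "pseudogene")

    def test_premature_stop(self):
        assert functional_status("ATGTAACTTCTTTAA") == ("nonfunctional", "pseudogene")

    def test_intact_orf(self):
        assert functional_status("ATGCTTCTTCTTTAA") == ("functional", "none")

    def test_frameshift_length(self):
        assert functional_status("ATGCTTCTTCTTTAAG") == ("nonfunctional", "pseudogene")

    def test_in_frame_indel_stays_functional(self):
        assert functional_status("ATGCTTCTTTAA") == ("functional", "none")

    def test_whole_gene_deletion_marker(self):
        assert functional_status(None) == ("nonfunctional", "whole_gene_deletion")

    def test_empty_string_rejected(self):
        with pytest.raises(InputError):
            functional_status("")


class TestCollapse:
    def test_synonymous_changes_collapse_at_protein_level(self, small_alignment, small_manifest):
        nuc = collapse_haplotypes(small_alignment, small_manifest, "nucleotide")
        prot = collapse_haplotypes(small_alignment, small_manifest, "protein")
        assert len(nuc) == 3  # west TTC / east TTT / e3 GTT
        assert len(prot) == 2  # synonymous pair collapses

    def test_deletion_class_counts(self, small_alignment):
        entries = [(f"w{i}", f"ws{i//2}", "west") for i in range(4)]
        entries += [(f"e{i}", f"es{i//2}", "east") for i in range(4)]
        manifest = PopulationManifest(entries, {(f"e{i}", "toy") for i in range(3)})
        aln = small_alignment.subset([c for c, _, _ in entries if (c, "toy") not in manifest.deletions])
        classes = collapse_haplotypes(aln, manifest, "protein")
        wgd = [c for c in classes if c.mechanism == "whole_gene_deletion"]
        assert len(wgd) == 1 and wgd[0].counts == {"west": 0, "east": 3}
        assert wgd[0].key == ""

    def test_counts_conserved_across_all_genes(self, study_dataset):
        """Class counts plus deletion classes sum to total sampled
        chromosomes, per gene per population."""
        ds = study_dataset
        for gene, aln in ds.alignments.items():
            for level in ("nucleotide", "protein"):
                classes = collapse_haplotypes(aln, ds.manifest, level)
                for pop in ds.manifest.populations:
                    total = sum(c.counts[pop] for c in classes)
                    assert total == len(ds.manifest.chromosomes(pop))

    def test_distinct_lesions_stay_distinct_protein_classes(self, small_manifest):
        ref = "ATGCTTACTGCTCATTAA"
        seqs = {c: ref for c, _, _ in small_manifest.entries}
        seqs["w0"] = "ATGTAAACTGCTCATTAA"  # stop at codon 2
        seqs["w1"] = "ATGCTTTAAGCTCATTAA"  # stop at codon 3 (same truncation logic)
        classes = collapse_haplotypes(GeneAlignment("g", seqs), small_manifest, "protein")
        pseudo = [c for c in classes if c.mechanism == "pseudogene"]
        assert len(pseudo) == 2 and pseudo[0].key != pseudo[1].key


class TestSharingSummary:
    def _classes(self, counts_list):
        from tas2rpop.catalog import HaplotypeClass

        return {
            "g": [
                HaplotypeClass("g", "protein", f"K{i}", "functional", "none", c)
                for i, c in enumerate(counts_list)
            ]
        }

    def test_everything_shared(self):
        s = sharing_summary(self._classes([{"a": 2, "b": 3}, {"a": 1, "b": 1}]), ["a", "b"])
        assert s.unique_to_one_population == 0
        assert s.shared == s.total_classes == 2

    def test_unique_plus_shared_is_total(self):
        s = sharing_summary(
            self._classes([{"a": 2, "b": 0}, {"a": 1, "b": 1}, {"a": 0, "b": 4}]),
            ["a", "b"],
        )
        assert s.unique_to_one_population + s.shared == s.total_classes == 3
        assert s.per_population["a"]["unique"] == 1
        assert s.per_population["b"]["unique"] == 1

    def test_high_frequency_filter_drops_singletons(self):
        s = sharing_summary(
            self._classes([{"a": 1, "b": 0}, {"a": 3, "b": 1}]),
            ["a", "b"],
            high_frequency_only=True,
        )
        assert s.total_classes == 1 and s.shared == 1

    def test_unknown_population_rejected(self):
        with pytest.raises(InputError, match="population"):
            sharing_summary(self._classes([{"a": 1, "b": 1}]), ["a", "zz"])


class TestCatalogTable:
    def test_frequencies_rendered_and_wgd_rows_added(self, study_dataset):
        ds = study_dataset
        all_variants = []
        for g, aln in ds.alignments.items():
            all_variants += call_variants(aln, ds.manifest, reference_seq=ds.ancestral[g])
        table = catalog_table(all_variants, ds.alignments, ds.manifest)
        wgd = table[table.mutation == "WGD"]
        assert set(wgd.gene) == {"gene22", "gene24", "gene28"}
        assert (wgd.eastern == "3/20 (15%)").all()
        lic = table[(table.gene == "gene13") & (table.mutation == "LIC")]
        assert lic.function.tolist() == ["Non-functional"]
        assert lic.western.tolist() == ["70/92 (76%)"]
        rescued = table[(table.gene == "gene03") & (table.mutation == "LIC")]
        assert (rescued.function == "Functional").all()

    def test_no_variants_gives_empty_table(self, small_manifest):
        seqs = {c: "ATGCTTTTTTAA" for c, _, _ in small_manifest.entries}
        aln = GeneAlignment("g", seqs)
        table = catalog_table([], {"g": aln}, small_manifest)
        assert len(table) == 0


class TestDeletionSpan:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (11_257_350, 11_324_679, 67_330),
            (11_256_872, 11_324_827, 67_956),
            (514, 586, 73),
            (141, 273, 133),
            (5, 5, 1),
        ],
    )
    def test_inclusive_span(self, start, end, expected):
        assert deletion_span(start, end) == expected

    def test_reversed_interval_rejected(self):
        with pytest.raises(InputError):
            deletion_span(10, 9)
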