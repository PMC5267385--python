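import numpy as np
import pytest

from zeascan.alignments import (
    AlignmentError,
    FormatError,
    PopulationMap,
    RegionAnnotation,
    SequenceAlignment,
    complete_deletion_mask,
    polarize,
    read_fasta,
    read_population_map,
    translate_coding,
    write_fasta,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_basic_parse_preserves_order_and_uppercases(self, tmp_path):
        p = write(tmp_path, "a.fa", ">s1\nacgt\n>s2\nACGA\n")
        aln = read_fasta(p)
        assert aln.sample_ids == ["s1", "s2"]
        assert aln.sequences == ["ACGT", "ACGA"]
        assert (aln.n, aln.length) == (2, 4)

    def test_unequal_lengths_rejected(self, tmp_path):
        p = write(tmp_path, "a.fa", ">s1\nACGT\n>s2\nACGTA\n")
        with pytest.raises(AlignmentError, match="unequal lengths"):
            read_fasta(p)

    def test_illegal_character_rejected(self, tmp_path):
        p = write(tmp_path, "a.fa", ">s1\nACGU\n>s2\nACGA\n")
        with pytest.raises(AlignmentError, match="illegal character"):
            read_fasta(p)

    def test_empty_and_single_record_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            read_fasta(write(tmp_path, "e.fa", ""))
        with pytest.raises(FormatError):
            read_fasta(write(tmp_path, "s.fa", ">only\nACGT\n"))

    def test_write_read_round_trip_is_byte_identical(self, tmp_path):
        aln = SequenceAlignment(["a", "b"], ["ACGTN-" * 30, "ACGAAC" * 30])
        p1, p2 = tmp_path / "r1.fa", tmp_path / "r2.fa"
        write_fasta(aln, p1)
        write_fasta(read_fasta(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestPopulationMap:
    def test_parse_with_outgroup(self, tmp_path):
        p = write(
            tmp_path, "pop.tsv",
            "sample_id\tpopulation\nB73\ttemperate\nKi3\ttropical\nTL92B\toutgroup\n",
        )
        pm = read_population_map(p)
        assert pm.populations() == ["temperate", "tropical"]
        assert pm.outgroup_ids == frozenset({"TL92B"})
        assert pm.ingroup_ids() == ["B73", "Ki3"]

    def test_duplicate_sample_rejected(self, tmp_path):
        p = write(
            tmp_path, "pop.tsv",
            "sample_id\tpopulation\nB73\ttemperate\nB73\ttropical\n",
        )
        with pytest.raises(FormatError, match="duplicate"):
            read_population_map(p)

    def test_all_outgroup_rejected(self, tmp_path):
        p = write(
            tmp_path, "pop.tsv",
            "sample_id\tpopulation\nA\toutgroup\nB\toutgroup\n",
        )
        with pytest.raises(ValueError, match="no ingroup samples"):
            read_population_map(p)


class TestCompleteDeletion:
    def test_gapped_column_dropped(self):
        aln = SequenceAlignment(["a", "b"], ["AC-T", "ACGT"])
        assert complete_deletion_mask(aln).tolist() == [0, 1, 3]

    def test_clean_alignment_keeps_all(self):
        aln = SequenceAlignment(["a", "b"], ["ACGT", "ACGA"])
        assert complete_deletion_mask(aln).tolist() == [0, 1, 2, 3]

    def test_column_gapped_everywhere_excluded_and_n_treated_as_gap(self):
        aln = SequenceAlignment(["a", "b"], ["A-NT", "A-GT"])
        assert complete_deletion_mask(aln).tolist() == [0, 3]

    def test_mask_respects_sample_subset(self):
        aln = SequenceAlignment(["a", "b", "c"], ["ACGT", "AC-T", "ACGT"])
        assert complete_deletion_mask(aln, ["a", "c"]).tolist() == [0, 1, 2, 3]


class TestPolarize:
    def popmap(self):
        return PopulationMap(
            {"i1": "p", "i2": "p", "og": "outgroup"}, frozenset({"og"})
        )

    def test_outgroup_allele_becomes_ancestral(self):
        aln = SequenceAlignment(["i1", "i2", "og"], ["AA", "AT", "AA"])
        m, diag = polarize(aln, self.popmap())
        assert m.num_sites == 1
        assert m.derived[0].tolist() == [0, 1]
        assert diag.unpolarizable == 0

    def test_third_outgroup_allele_is_unpolarizable(self):
        aln = SequenceAlignment(["i1", "i2", "og"], ["AA", "AT", "AG"])
        m, diag = polarize(aln, self.popmap())
        assert m.num_sites == 0
        assert diag.unpolarizable == 1

    def test_monomorphic_column_emits_no_site(self):
        aln = SequenceAlignment(["i1", "i2", "og"], ["AA", "AA", "AT"])
        m, diag = polarize(aln, self.popmap())
        assert m.num_sites == 0
        assert diag.monomorphic == 2

    def test_missing_outgroup_errors(self):
        aln = SequenceAlignment(["i1", "i2"], ["AA", "AT"])
        pm = PopulationMap({"i1": "p", "i2": "p", "x": "p"}, frozenset())
        with pytest.raises(ValueError):
            polarize(aln, pm)

    def test_column_conservation_and_row_permutation_invariance(self):
        rng = np.random.default_rng(11)
        n, L = 6, 60
        base = rng.choice(list("ACGT"), size=L)
        seqs = []
        for _ in range(n + 1):
            s = base.copy()
            hit = rng.random(L) < 0.2
            s[hit] = rng.choice(list("ACGT-"), size=int(hit.sum()))
            seqs.append("".join(s))
        ids = [f"i{k}" for k in range(n)] + ["og"]
        aln = SequenceAlignment(ids, seqs)
        pm = PopulationMap(
            {**{f"i{k}": "p" for k in range(n)}, "og": "outgroup"},
            frozenset({"og"}),
        )
        m, diag = polarize(aln, pm)
        assert (
            diag.polarized + diag.unpolarizable + diag.monomorphic
            + diag.multiallelic
            == diag.analyzed_columns
        )
        # reordering alignment rows changes nothing: matrix rows follow the
        # population map, not the FASTA record order
        perm = [3, 0, 5, 1, 4, 2]
        aln2 = SequenceAlignment(
            [ids[i] for i in perm] + ["og"],
            [seqs[i] for i in perm] + [seqs[-1]],
        )
        m2, diag2 = polarize(aln2, pm)
        assert diag2 == diag
        assert m2.positions.tolist() == m.positions.tolist()
        assert np.array_equal(m2.derived, m.derived)


class TestTranslateCoding:
    def test_standard_codons(self):
        aln = SequenceAlignment(["a", "b"], ["ATGAAA", "ATGAAA"])
        reg = RegionAnnotation([(0, 6, "coding")])
        assert translate_coding(aln, reg) == ["MK", "MK"]

    def test_masked_codon_translates_to_x(self):
        aln = SequenceAlignment(["a", "b"], ["ATGA-A", "ATGANA"])
        reg = RegionAnnotation([(0, 6, "coding")])
        assert translate_coding(aln, reg) == ["MX", "MX"]

    def test_frame_offset_trims_leading_base(self):
        aln = SequenceAlignment(["a", "b"], ["AATGAA", "AATGAA"])
        reg = RegionAnnotation([(0, 6, "coding")], coding_frame_offset=1)
        # offset 1 leaves 5 bases -> not divisible by 3
        with pytest.raises(ValueError):
            translate_coding(aln, reg)
        aln7 = SequenceAlignment(["a", "b"], ["AATGAAA", "AATGAAA"])
        reg7 = RegionAnnotation([(0, 7, "coding")], coding_frame_offset=1)
        assert translate_coding(aln7, reg7) == ["MK", "MK"]

    def test_internal_stop_warns_and_keeps_star(self):
        aln = SequenceAlignment(["a", "b"], ["TAAAAA", "TAAAAA"])
        reg = RegionAnnotation([(0, 6, "coding")])
        with pytest.warns(UserWarning, match="stop"):
            assert translate_coding(aln, reg) == ["*K", "*K"]
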