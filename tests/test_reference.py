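"""Reference construction: masking, flanking, splicing, collapsing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmodscan.reference import (
    CoordinateError,
    GenomicInterval,
    TRNAGeneRecord,
    build_mature_library,
    extract_flanked_genes,
    gene_to_representative,
    mask_genome,
    read_bed,
    read_flanked_fasta,
    read_mature_fasta,
    reverse_complement,
    write_bed12,
    write_flanked_fasta,
    write_mature_fasta,
)


class TestMaskGenome:
    def test_single_locus(self):
        out = mask_genome({"chr1": "ACGTACGT"}, [GenomicInterval("chr1", 2, 5)])
        assert out == {"chr1": "ACNNNCGT"}

    def test_empty_locus_list_is_identity(self):
        genome = {"chr1": "ACGTACGT", "chr2": "TTTT"}
        assert mask_genome(genome, []) == genome

    def test_overlapping_loci_mask_union(self):
        out = mask_genome(
            {"c": "ACGTACGTA"},
            [GenomicInterval("c", 2, 5), GenomicInterval("c", 4, 7)],
        )
        assert out == {"c": "ACNNNNNTA"}

    def test_out_of_bounds_locus_raises(self):
        with pytest.raises(CoordinateError, match="chr1"):
            mask_genome({"chr1": "ACGT"}, [GenomicInterval("chr1", 2, 9)])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_per_base_union_membership(self, data):
        n = data.draw(st.integers(10, 40))
        seq = "".join(data.draw(st.sampled_from("ACGT")) for _ in range(n))
        loci = []
        for _ in range(data.draw(st.integers(0, 4))):
            a = data.draw(st.integers(0, n - 2))
            b = data.draw(st.integers(a + 1, n))
            loci.append(GenomicInterval("c", a, b))
        masked = mask_genome({"c": seq}, loci)["c"]
        # brute-force oracle: per-base membership in the union of loci
        expected = "".join(
            "N" if any(l.start <= i < l.end for l in loci) else seq[i]
            for i in range(n)
        )
        assert masked == expected
        assert len(masked) == len(seq)


class TestFlankedGenes:
    def test_plus_strand_full_flanks(self, toy_genome):
        gene = TRNAGeneRecord.from_genome(
            toy_genome, "g", GenomicInterval("chr1", 60, 100, "+")
        )
        (fl,) = extract_flanked_genes(toy_genome, [gene], flank_len=50)
        assert len(fl.sequence) == 140
        assert fl.body_span == (50, 90)
        assert fl.sequence[50:90] == gene.genomic_seq

    def test_truncated_flank_at_chromosome_start(self, toy_genome):
        gene = TRNAGeneRecord.from_genome(
            toy_genome, "g", GenomicInterval("chr1", 10, 86, "+")
        )
        (fl,) = extract_flanked_genes(toy_genome, [gene], flank_len=50)
        assert fl.flank5 == 10
        assert fl.body_span == (10, 86)

    def test_minus_strand_is_reverse_complement_of_window(self, toy_genome):
        gene = TRNAGeneRecord.from_genome(
            toy_genome, "g", GenomicInterval("chr1", 120, 160, "-")
        )
        (fl,) = extract_flanked_genes(toy_genome, [gene], flank_len=20)
        window = toy_genome["chr1"][100:180]
        assert fl.sequence == reverse_complement(window)
        assert fl.body_span == (20, 60)
        assert fl.sequence[20:60] == gene.genomic_seq


class TestMatureLibrary:
    def _gene(self, gid, seq, introns=()):
        return TRNAGeneRecord(
            gid, GenomicInterval("c", 0, len(seq)), seq, tuple(introns)
        )

    def test_identical_genes_collapse(self):
        lib = build_mature_library(
            [self._gene("a", "GGGAAACCC"), self._gene("b", "GGGAAACCC")]
        )
        assert len(lib) == 1
        assert lib[0].sequence == "GGGAAACCCCCA"
        assert lib[0].member_gene_ids == ("a", "b")
        assert lib[0].rep_id == "a"

    def test_intron_removed_before_cca(self):
        lib = build_mature_library([self._gene("a", "GGGTTTAAACCC", [(3, 6)])])
        assert lib[0].sequence == "GGGAAACCCCCA"

    def test_distinct_sequences_stay_distinct(self, rng):
        genes = [
            self._gene(f"g{i}", "".join(rng.choice(list("ACGT"), 30)))
            for i in range(10)
        ]
        lib = build_mature_library(genes)
        assert len(lib) == 10
        assert all(len(m.member_gene_ids) == 1 for m in lib)

    def test_member_count_conservation_and_cca(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 25)) for _ in range(6)]
        genes = [self._gene(f"g{i}", seqs[i % 6]) for i in range(14)]
        lib = build_mature_library(genes)
        assert sum(len(m.member_gene_ids) for m in lib) == 14
        assert all(m.sequence.endswith("CCA") for m in lib)
        # deterministic lexicographic order
        assert [m.sequence for m in lib] == sorted(m.sequence for m in lib)

    def test_duplicate_gene_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_mature_library([self._gene("a", "ACGT"), self._gene("a", "ACGT")])

    def test_non_acgt_sequence_excluded(self):
        lib = build_mature_library([self._gene("a", "ACNT"), self._gene("b", "ACGT")])
        assert [m.rep_id for m in lib] == ["b"]

    def test_mature_length_arithmetic(self):
        gene = self._gene("a", "GGGTTTAAACCCGGG", [(3, 6), (9, 12)])
        lib = build_mature_library([gene])
        assert len(lib[0].sequence) == 15 - 6 + 3

    def test_cca_if_absent_switch(self):
        gene = self._gene("a", "GGGAAACCA")
        assert build_mature_library([gene])[0].sequence == "GGGAAACCACCA"
        assert build_mature_library([gene], cca_if_absent=True)[0].sequence == (
            "GGGAAACCA"
        )


def test_minus_strand_mirror_property(rng):
    """Building from a genome and from its reverse-complemented mirror (with
    mirrored coordinates and flipped strands) yields identical libraries."""
    seq = "".join(rng.choice(list("ACGT"), 300))
    genome = {"c": seq}
    genes = [
        TRNAGeneRecord.from_genome(
            genome, "g1", GenomicInterval("c", 20, 80, "+"), [(10, 20)]
        ),
        TRNAGeneRecord.from_genome(genome, "g2", GenomicInterval("c", 120, 190, "-")),
    ]
    L = len(seq)
    mirror = {"c": reverse_complement(seq)}
    mgenes = [
        TRNAGeneRecord.from_genome(
            mirror, "g1", GenomicInterval("c", L - 80, L - 20, "-"), [(10, 20)]
        ),
        TRNAGeneRecord.from_genome(mirror, "g2", GenomicInterval("c", L - 190, L - 120, "+")),
    ]
    lib_a = build_mature_library(genes)
    lib_b = build_mature_library(mgenes)
    assert [(m.rep_id, m.sequence, m.member_gene_ids) for m in lib_a] == [
        (m.rep_id, m.sequence, m.member_gene_ids) for m in lib_b
    ]


def test_fasta_and_bed_round_trips(tmp_path, toy_genome, toy_genes):
    flanked = extract_flanked_genes(toy_genome, toy_genes, flank_len=30)
    write_flanked_fasta(tmp_path / "fl.fa", flanked)
    back = read_flanked_fasta(tmp_path / "fl.fa")
    assert [(f.gene_id, f.sequence, f.body_span) for f in back] == [
        (f.gene_id, f.sequence, f.body_span) for f in flanked
    ]

    lib = build_mature_library(toy_genes)
    write_mature_fasta(tmp_path / "mat.fa", lib)
    back_lib = read_mature_fasta(tmp_path / "mat.fa")
    assert [(m.rep_id, m.sequence, m.member_gene_ids) for m in back_lib] == [
        (m.rep_id, m.sequence, m.member_gene_ids) for m in lib
    ]
    assert gene_to_representative(lib) == gene_to_representative(back_lib)

    # BED12 round trip preserves loci and introns (exercise an intron gene)
    genes = toy_genes + [
        TRNAGeneRecord.from_genome(
            toy_genome, "gIntron", GenomicInterval("chr1", 0, 50, "-"), [(10, 20)]
        )
    ]
    write_bed12(tmp_path / "g.bed", genes)
    back_genes = read_bed(tmp_path / "g.bed", toy_genome)
    key = lambda g: (g.gene_id, g.locus, g.introns, g.genomic_seq)
    assert sorted(map(key, back_genes)) == sorted(map(key, genes))
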