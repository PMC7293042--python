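"""The synthetic-data generator: determinism, truth consistency, noise model."""

import numpy as np
import pytest

from tmodscan.pileup import compute_pileup
from tmodscan.reference import build_mature_library
from tmodscan.simulate import (
    ModSpec,
    SimConfig,
    SimTruth,
    default_mod_specs,
    evaluate_calls,
    simulate_genomic_reads,
    simulate_null_pileups,
    simulate_reads,
    simulate_reference,
)
from tmodscan.triage import map_reads

SMALL = SimConfig(n_genes=12, coverage_mean=40, genomic_reads=5)


def _reference(seed=7, config=SMALL):
    rng = np.random.default_rng(seed)
    genome, genes = simulate_reference(config, rng)
    return genome, genes, build_mature_library(genes), rng


class TestReference:
    def test_duplicates_collapse_in_library(self):
        cfg = SimConfig(n_genes=10, frac_duplicates=0.2, frac_intron=0.0)
        rng = np.random.default_rng(3)
        _, genes = simulate_reference(cfg, rng)
        lib = build_mature_library(genes)
        assert len(genes) == 10
        assert len(lib) == 8  # 2 duplicates collapsed
        assert sum(len(m.member_gene_ids) for m in lib) == 10

    def test_same_seed_reproduces_everything(self):
        g1, genes1 = simulate_reference(SMALL, np.random.default_rng(11))
        g2, genes2 = simulate_reference(SMALL, np.random.default_rng(11))
        assert g1 == g2
        assert [(g.gene_id, g.locus, g.genomic_seq, g.introns) for g in genes1] == [
            (g.gene_id, g.locus, g.genomic_seq, g.introns) for g in genes2
        ]

    def test_zero_intron_fraction(self):
        cfg = SimConfig(n_genes=8, frac_intron=0.0)
        _, genes = simulate_reference(cfg, np.random.default_rng(5))
        assert all(g.spliced_seq == g.genomic_seq for g in genes)

    def test_minus_strand_genes_present_and_consistent(self, rng):
        genome, genes = simulate_reference(SMALL, rng)
        minus = [g for g in genes if g.locus.strand == "-"]
        assert minus
        from tmodscan.reference import reverse_complement

        for g in minus:
            raw = genome["chrS"][g.locus.start : g.locus.end]
            assert g.genomic_seq == reverse_complement(raw)


class TestReads:
    def test_noiseless_reads_equal_mature_sequences(self):
        cfg = SimConfig(
            n_genes=6, coverage_mean=20, seq_error=0.0, del_error=0.0,
            precursor_frac=0.0, genomic_reads=0,
        )
        genome, genes, lib, rng = _reference(config=cfg)
        mature = {m.rep_id: m.sequence for m in lib}
        reads, elim, body = simulate_reads(genome, genes, lib, [], cfg, rng, "s1")
        assert not elim
        assert reads
        for r in reads:
            rep = r.read_id.split(":")[2]
            assert r.seq == mature[rep]

    def test_saturated_modification_shows_in_pileup(self):
        cfg = SimConfig(
            n_genes=6, coverage_mean=100, seq_error=0.0, del_error=0.0,
            precursor_frac=0.0, genomic_reads=0,
        )
        genome, genes, lib, rng = _reference(seed=19, config=cfg)
        target = lib[0]
        ref9 = target.sequence[8]
        alts = [b for b in "ACGT" if b != ref9]
        spec = ModSpec(target.rep_id, 9, misinc=1.0, spectrum=(1.0, 0.0, 0.0))
        reads, _, _ = simulate_reads(genome, genes, lib, [spec], cfg, rng, "s1")
        mature = {m.rep_id: m.sequence for m in lib}
        kept = map_reads(reads, lib)
        mat = compute_pileup(kept, mature)[target.rep_id]
        # every read of the target carries the first alternative base at 9
        assert mat.base_counts["ACGT".index(alts[0]), 8] == mat.basecall_coverage[8]
        assert mat.basecall_coverage[8] > 0

    def test_dropout_thins_read_counts(self):
        cfg = SimConfig(
            n_genes=20, coverage_mean=200, seq_error=0.0, precursor_frac=0.0,
            genomic_reads=0, frac_duplicates=0.0,
        )
        genome, genes, lib, rng = _reference(seed=23, config=cfg)
        spec = ModSpec(
            lib[0].rep_id, 9, misinc=0.0, spectrum=(1.0, 0.0, 0.0), dropout=0.5
        )
        counts = {m.rep_id: 0 for m in lib}
        for s in range(6):
            reads, _, _ = simulate_reads(
                genome, genes, lib, [spec], cfg, rng, f"s{s}"
            )
            for r in reads:
                counts[r.read_id.split(":")[2]] += 1
        others = [v for k, v in counts.items() if k != lib[0].rep_id]
        mean_other = np.mean(others)
        n = counts[lib[0].rep_id]
        assert abs(n - 0.5 * mean_other) < 3 * np.sqrt(0.5 * mean_other * 6)

    def test_precursor_reads_extend_into_flanks(self):
        cfg = SimConfig(n_genes=6, coverage_mean=30, precursor_frac=0.2)
        genome, genes, lib, rng = _reference(seed=31, config=cfg)
        reads, elim, _ = simulate_reads(genome, genes, lib, [], cfg, rng, "s1")
        pre = [r for r in reads if r.read_id.split(":")[1] == "p"]
        assert pre and {r.read_id for r in pre} == elim
        gene_len = {g.gene_id: len(g.genomic_seq) for g in genes}
        for r in pre:
            assert len(r.seq) >= gene_len[r.read_id.split(":")[2]] + 4

    def test_genomic_reads_avoid_gene_loci(self):
        genome, genes, lib, rng = _reference(seed=37)
        reads, ids = simulate_genomic_reads(genome, genes, SMALL, rng, "s1")
        assert len(reads) == SMALL.genomic_reads
        loci = [(g.locus.start, g.locus.end) for g in genes]
        for r in reads:
            start = int(r.read_id.split(":")[2])
            end = start + len(r.seq)
            assert all(end <= s or start >= e for s, e in loci)

    def test_deterministic_given_seed(self):
        out = []
        for _ in range(2):
            genome, genes, lib, rng = _reference(seed=41)
            reads, _, _ = simulate_reads(genome, genes, lib, [], SMALL, rng, "s1")
            out.append([(r.read_id, r.seq, r.qual.tolist()) for r in reads])
        assert out[0] == out[1]

    def test_bad_spectrum_rejected(self):
        with pytest.raises(ValueError, match="spectrum"):
            ModSpec("t", 9, 0.1, (0.5, 0.2, 0.2))


class TestNullPileups:
    def test_error_rate_matches_configuration(self, rng):
        frames = simulate_null_pileups(2000, 300, 0.003, 1, rng)
        frame = next(iter(frames.values()))
        total_err = (frame["coverage"] * frame["error_rate"]).sum()
        total = frame["coverage"].sum()
        se = np.sqrt(0.003 * (1 - 0.003) / total)
        assert abs(total_err / total - 0.003) < 3 * se

    def test_counts_are_consistent(self, rng):
        frames = simulate_null_pileups(100, 80, 0.01, 2, rng)
        for frame in frames.values():
            assert (frame[list("ACGT")].sum(axis=1) == frame["coverage"]).all()


class TestEvaluate:
    def _truth(self):
        spec = ModSpec("t1", 9, 0.2, (0.5, 0.3, 0.2))
        other = ModSpec("t2", 9, 0.2, (0.5, 0.3, 0.2))
        return SimTruth(
            mod_specs={"WT": [spec, other], "KO_A": [other]}, gene_map={}
        )

    def test_perfect_calls(self):
        m = evaluate_calls(self._truth(), [("t1", 9), ("t2", 9)])
        assert m["sensitivity"] == 1.0 and m["false_discovery_proportion"] == 0.0

    def test_empty_calls(self):
        m = evaluate_calls(self._truth(), [])
        assert m["sensitivity"] == 0.0

    def test_one_spurious_among_ten(self):
        truth = SimTruth(
            mod_specs={
                "WT": [ModSpec(f"t{i}", 9, 0.2, (0.5, 0.3, 0.2)) for i in range(9)]
            },
            gene_map={},
        )
        calls = [(f"t{i}", 9) for i in range(9)] + [("spurious", 9)]
        m = evaluate_calls(truth, calls)
        assert m["false_discovery_proportion"] == pytest.approx(1 / 10)


def test_default_mod_specs_structure(rng):
    _, genes = simulate_reference(SimConfig(n_genes=40), rng)
    lib = build_mature_library(genes)
    specs = default_mod_specs(lib, rng)
    assert len(specs["WT"]) == 6
    assert len(specs["KO_A"]) == 1  # enzyme A knocked out: only the B site left
    assert len(specs["KO_B"]) == 5
    reps = {m.rep_id: m.sequence for m in lib}
    for m in specs["WT"]:
        assert reps[m.rep_id][m.position - 1] in "AG"
    (b_site,) = specs["KO_A"]
    assert reps[b_site.rep_id][b_site.position - 1] == "A"
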