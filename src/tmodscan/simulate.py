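"""Synthetic genomes, tRNA gene sets and tRNA-seq reads with known truth.

The generator emulates the statistical structure of a small-RNA sequencing
experiment targeted at tRNAs: mature tRNAs of ~60-90 nt read full length
(the two-adapter RNA-level ligation protocol sequences only complete cDNAs,
so reads are not fragmented), per-base sequencing error well below 1%,
modified positions with elevated multi-substitution plus deletion
misincorporation, RT dropout thinning the coverage of modified molecules,
a minority of precursor reads extending into the 50-nt gene flanks, and a
handful of genomic background reads.  Wild type carries all modifications;
each knockout condition removes the sites attributed to its enzyme.

Everything is a pure function of (config, seed): the same seed reproduces
every sequence, read and quality byte for byte.

One deliberate construction guarantees exact triage ground truth: the two
genomic bases immediately 3' of every gene are drawn so that the appended
CCA tail of a mature read can never extend an alignment into the flank, and
precursor flank overhangs are emitted error-free.  Both are documented
simplifications of real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import ReadRecord
from .pileup import PILEUP_COLUMNS
from .reference import (
    GenomicInterval,
    MatureTRNA,
    TRNAGeneRecord,
    build_mature_library,
    gene_to_representative,
    reverse_complement,
)

_ASCII = {b: ord(b) for b in "ACGT"}
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ModSpec:
    """Ground truth for one modified site.

    ``position`` is 1-based on the mature sequence.  Per read of the target:
    with probability ``deletion`` the modified base is deleted from the read
    (RT skip); otherwise with probability ``misinc`` a substitution is drawn
    from ``spectrum`` (probabilities over the three alternative bases in
    alphabetical order); ``dropout`` is the probability that the read is
    lost entirely (abortive RT under a full-length-only library prep).
    """

    rep_id: str
    position: int
    misinc: float
    spectrum: tuple[float, float, float]
    deletion: float = 0.0
    dropout: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.misinc, self.deletion, self.dropout, *self.spectrum):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1] in {self}")
        if abs(sum(self.spectrum) - 1.0) > 1e-9:
            raise ValueError(f"substitution spectrum must sum to 1: {self.spectrum}")
        if self.misinc + self.deletion > 1.0:
            raise ValueError("misinc + deletion exceeds 1")


@dataclass
class SimConfig:
    """Tunable knobs of the generator; defaults emulate the study design
    (three wild-type replicates, two replicates per knockout, ~200x tRNA
    coverage, 50-nt flanks)."""

    n_genes: int = 50
    gene_len: tuple[int, int] = (61, 87)  # mature length 64-90 incl. CCA
    frac_duplicates: float = 0.1
    frac_intron: float = 0.2
    intron_len: tuple[int, int] = (8, 20)
    frac_minus: float = 0.4
    flank: int = 50
    spacing: int = 160  # genomic gap between loci; keeps flanks disjoint
    n_wt: int = 3
    ko_reps: int = 2
    coverage_mean: float = 200.0
    coverage_size: float = 50.0  # negative-binomial size (inverse dispersion)
    seq_error: float = 0.001
    del_error: float = 1e-4
    precursor_frac: float = 0.05
    genomic_reads: int = 50
    low_qual_frac: float = 0.03
    qual_high: tuple[int, int] = (30, 40)
    qual_low: tuple[int, int] = (10, 19)

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.coverage_mean <= 0:
            raise ValueError("n_genes and coverage_mean must be positive")


@dataclass
class SimTruth:
    """Ground-truth manifest: which sites are modified per condition, the
    gene -> representative map, and the read ids triage must eliminate."""

    mod_specs: dict[str, list[ModSpec]]
    gene_map: dict[str, str]
    eliminated_read_ids: dict[str, set[str]] = field(default_factory=dict)
    body_read_ids: dict[str, set[str]] = field(default_factory=dict)

    def modified_sites(self, condition: str) -> set[tuple[str, int]]:
        return {(m.rep_id, m.position) for m in self.mod_specs.get(condition, [])}

    def all_modified_sites(self) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for cond in self.mod_specs:
            out |= self.modified_sites(cond)
        return out

    def to_json(self, path) -> None:
        payload = {
            "mod_specs": {
                c: [asdict(m) for m in specs] for c, specs in self.mod_specs.items()
            },
            "gene_map": self.gene_map,
            "eliminated_read_ids": {
                s: sorted(v) for s, v in self.eliminated_read_ids.items()
            },
            "body_read_ids": {s: sorted(v) for s, v in self.body_read_ids.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def simulate_reference(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[TRNAGeneRecord]]:
    """Random genome with embedded tRNA genes.

    Some genes are exact duplicates (to exercise collapsing), some carry an
    intron (placed after the D-arm region, position >= 32, as in real tRNA
    genes), some lie on the minus strand.  Genes too long for the configured
    genome packing raise a config error.
    """
    n = config.n_genes
    lens = rng.integers(config.gene_len[0], config.gene_len[1] + 1, n)
    n_dup = int(round(config.frac_duplicates * n))
    seqs: list[str] = []
    introns: list[tuple[tuple[int, int], ...]] = []
    for i in range(n):
        if i >= 1 and i < 1 + n_dup:
            # duplicate an earlier unique gene verbatim
            src = int(rng.integers(0, max(i - n_dup, 1)))
            seqs.append(seqs[src])
            introns.append(introns[src])
            continue
        L = int(lens[i])
        seq = _random_seq(rng, L)
        # most real tRNAs carry a purine at position 9; mirror that so
        # modification targets are plentiful
        if rng.random() < 0.8:
            seq = seq[:8] + "AG"[int(rng.integers(0, 2))] + seq[9:]
        if rng.random() < config.frac_intron and L >= 45:
            ilen = int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            istart = int(rng.integers(32, L - ilen - 2))
            seq = seq[:istart] + _random_seq(rng, ilen) + seq[istart:]
            introns.append(((istart, istart + ilen),))
        else:
            introns.append(())
        seqs.append(seq)
    spacing = config.spacing
    if spacing < 2 * config.flank + 10:
        raise ValueError("spacing too small for non-overlapping flanks")
    total = sum(len(s) for s in seqs) + spacing * (n + 1)
    chrom = bytearray(_random_seq(rng, total), "ascii")
    genes: list[TRNAGeneRecord] = []
    pos = spacing
    order = rng.permutation(n)
    not_g = "ACT"
    not_c = "AGT"
    for rank, gi in enumerate(order):
        seq = seqs[gi]
        start, end = pos, pos + len(seq)
        strand = "-" if rng.random() < config.frac_minus else "+"
        if strand == "+":
            chrom[start:end] = seq.encode("ascii")
            # sense 3' flank must not begin with C (CCA tail cannot extend)
            chrom[end] = ord(not_c[rng.integers(0, 3)])
            chrom[end + 1] = ord(not_c[rng.integers(0, 3)])
        else:
            chrom[start:end] = reverse_complement(seq).encode("ascii")
            chrom[start - 1] = ord(not_g[rng.integers(0, 3)])
            chrom[start - 2] = ord(not_g[rng.integers(0, 3)])
        genes.append(
            TRNAGeneRecord(
                gene_id=f"trna{gi:03d}",
                locus=GenomicInterval("chrS", start, end, strand),
                genomic_seq=seq,
                introns=introns[gi],
                anticodon_label=f"sim-{gi:03d}",
            )
        )
        pos = end + spacing
    genes.sort(key=lambda g: g.gene_id)
    return {"chrS": chrom.decode("ascii")}, genes


def default_mod_specs(
    library: Sequence[MatureTRNA],
    rng: np.random.Generator,
    position: int = 9,
    misinc_levels: Sequence[float] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30),
    deletion_scale: float = 0.5,
    dropout: float = 0.2,
    n_enzyme_a: int = 5,
) -> dict[str, list[ModSpec]]:
    """Plant position-9 modifications mirroring a two-enzyme system.

    Enzyme A methylates ``n_enzyme_a`` G9 tRNAs; enzyme B a single A9 tRNA
    (given the strongest signal, as its natural counterpart shows).
    Returns mod specs per condition: WT carries all sites, KO_A loses the
    A sites, KO_B loses the B site.  Deletion probability scales with the
    substitution rate (``deletion_scale``); spectra spread the substitution
    mass over all three alternative bases, as RT misreading of a
    methylated purine does.
    """
    g9 = [m.rep_id for m in library if len(m.sequence) >= position
          and m.sequence[position - 1] == "G"]
    a9 = [m.rep_id for m in library if len(m.sequence) >= position
          and m.sequence[position - 1] == "A"]
    if g9 and a9:
        a_pool, b_pool = g9, a9
    else:
        # tiny libraries may lack one purine entirely; split whatever
        # purine-9 targets exist between the two enzymes
        pool = g9 or a9
        if len(pool) < 2:
            raise ValueError("not enough purine-9 targets to place modifications")
        reserved = str(rng.choice(pool))
        a_pool = [r for r in pool if r != reserved]
        b_pool = [reserved]
    n_enzyme_a = min(n_enzyme_a, len(a_pool))
    a_targets = sorted(rng.choice(a_pool, size=n_enzyme_a, replace=False).tolist())
    b_target = str(rng.choice(b_pool))
    levels = list(misinc_levels)
    spectra = ((0.4, 0.35, 0.25), (0.35, 0.4, 0.25), (0.25, 0.35, 0.4))

    def spec(rep: str, level: float, i: int) -> ModSpec:
        return ModSpec(
            rep_id=rep,
            position=position,
            misinc=level,
            spectrum=spectra[i % len(spectra)],
            deletion=deletion_scale * level,
            dropout=dropout,
        )

    a_specs = [spec(r, levels[i], i) for i, r in enumerate(a_targets)]
    b_spec = spec(b_target, levels[-1], len(a_targets))
    return {
        "WT": a_specs + [b_spec],
        "KO_A": [b_spec],
        "KO_B": list(a_specs),
    }


def _apply_errors(
    mat: np.ndarray, rng: np.random.Generator, rate: float
) -> np.ndarray:
    """Substitute random different bases at rate per position, in place."""
    if rate <= 0:
        return mat
    mask = rng.random(mat.shape) < rate
    if mask.any():
        codes = _CODE[mat[mask]]
        codes = (codes + rng.integers(1, 4, codes.size)) % 4
        mat[mask] = _BASE_BYTES[codes]
    return mat


def _qualities(
    rng: np.random.Generator, n: int, config: SimConfig
) -> np.ndarray:
    q = rng.integers(config.qual_high[0], config.qual_high[1] + 1, n)
    low = rng.random(n) < config.low_qual_frac
    if low.any():
        q[low] = rng.integers(config.qual_low[0], config.qual_low[1] + 1, low.sum())
    return q.astype(np.int16)


def simulate_reads(
    genome: Mapping[str, str],
    genes: Sequence[TRNAGeneRecord],
    library: Sequence[MatureTRNA],
    mod_specs: Sequence[ModSpec],
    config: SimConfig,
    rng: np.random.Generator,
    sample_id: str,
) -> tuple[list[ReadRecord], set[str], set[str]]:
    """Simulate one sample's reads.

    Returns (reads, read ids triage must eliminate, body-read ids).  Read
    counts per representative follow a negative binomial around
    ``coverage_mean``; modified representatives are thinned by their RT
    dropout probability.
    """
    specs = {m.rep_id: m for m in mod_specs}
    reads: list[ReadRecord] = []
    eliminated: set[str] = set()
    body: set[str] = set()
    p_nb = config.coverage_size / (config.coverage_size + config.coverage_mean)
    for rep in library:
        seq = rep.sequence
        L = len(seq)
        count = int(rng.negative_binomial(config.coverage_size, p_nb))
        spec = specs.get(rep.rep_id)
        if spec is not None and spec.dropout > 0:
            count = int(rng.binomial(count, 1.0 - spec.dropout))
        if count == 0:
            continue
        mat = np.tile(np.frombuffer(seq.encode("ascii"), np.uint8), (count, 1)).copy()
        del_rows = np.zeros(count, dtype=bool)
        if spec is not None:
            p0 = spec.position - 1
            u = rng.random(count)
            del_rows = u < spec.deletion
            sub_rows = (~del_rows) & (u < spec.deletion + spec.misinc)
            if sub_rows.any():
                alts = [b for b in "ACGT" if b != seq[p0]]
                choice = rng.choice(
                    [_ASCII[a] for a in alts], size=int(sub_rows.sum()), p=spec.spectrum
                )
                mat[sub_rows, p0] = choice
        _apply_errors(mat, rng, config.seq_error)
        # rare sequencing deletions, one base at a random position
        seq_del = rng.random(count) < config.del_error * L
        del_pos = np.full(count, -1)
        if spec is not None:
            del_pos[del_rows] = spec.position - 1
        extra = seq_del & (del_pos < 0)
        if extra.any():
            del_pos[extra] = rng.integers(0, L, int(extra.sum()))
        for i in range(count):
            rid = f"{sample_id}:m:{rep.rep_id}:{i}"
            if del_pos[i] >= 0:
                row = np.delete(mat[i], del_pos[i])
            else:
                row = mat[i]
            reads.append(
                ReadRecord(rid, row.tobytes().decode("ascii"),
                           _qualities(rng, row.size, config))
            )
            body.add(rid)
    # precursor reads: unspliced gene body plus flank overhangs, per gene
    from .reference import extract_flanked_genes

    flanked_by_gene = {
        f.gene_id: f for f in extract_flanked_genes(genome, genes, config.flank)
    }
    for gene in genes:
        n_pre = int(rng.poisson(config.precursor_frac * config.coverage_mean))
        if n_pre == 0:
            continue
        fl = flanked_by_gene[gene.gene_id]
        b0, b1 = fl.body_span
        f5, body_seq, f3 = fl.sequence[:b0], fl.sequence[b0:b1], fl.sequence[b1:]
        gmat = np.tile(
            np.frombuffer(body_seq.encode("ascii"), np.uint8), (n_pre, 1)
        ).copy()
        _apply_errors(gmat, rng, config.seq_error)
        leads = rng.integers(2, len(f5) + 1, n_pre) if f5 else np.zeros(n_pre, int)
        trails = rng.integers(2, len(f3) + 1, n_pre) if f3 else np.zeros(n_pre, int)
        for i in range(n_pre):
            rid = f"{sample_id}:p:{gene.gene_id}:{i}"
            s = (
                f5[len(f5) - int(leads[i]):]
                + gmat[i].tobytes().decode("ascii")
                + f3[: int(trails[i])]
            )
            reads.append(ReadRecord(rid, s, _qualities(rng, len(s), config)))
            eliminated.add(rid)
    return reads, eliminated, body


def simulate_genomic_reads(
    genome: Mapping[str, str],
    genes: Sequence[TRNAGeneRecord],
    config: SimConfig,
    rng: np.random.Generator,
    sample_id: str,
    read_len: int = 75,
) -> tuple[list[ReadRecord], set[str]]:
    """Background reads from genomic regions outside every tRNA locus."""
    reads: list[ReadRecord] = []
    ids: set[str] = set()
    chrom = genome["chrS"]
    loci = sorted((g.locus.start, g.locus.end) for g in genes)
    free: list[tuple[int, int]] = []
    prev = 0
    for s, e in loci:
        if s - prev >= read_len:
            free.append((prev, s - read_len))
        prev = e
    if len(chrom) - prev >= read_len:
        free.append((prev, len(chrom) - read_len))
    if not free:
        return reads, ids
    widths = np.array([e - s for s, e in free], dtype=float)
    for i in range(config.genomic_reads):
        seg = int(rng.choice(len(free), p=widths / widths.sum()))
        start = int(rng.integers(free[seg][0], free[seg][1] + 1))
        s = chrom[start : start + read_len]
        arr = np.frombuffer(s.encode("ascii"), np.uint8).copy()
        _apply_errors(arr[None, :], rng, config.seq_error)
        rid = f"{sample_id}:g:{start}:{i}"
        reads.append(
            ReadRecord(rid, arr.tobytes().decode("ascii"),
                       _qualities(rng, arr.size, config))
        )
        ids.add(rid)
    return reads, ids


def simulate_null_pileups(
    n_sites: int,
    coverage_mean: float,
    seq_error: float,
    n_replicates: int,
    rng: np.random.Generator,
    del_error: float = 1e-4,
    coverage_size: float = 50.0,
) -> dict[str, pd.DataFrame]:
    """Pileup tables of unmodified sites only, for null calibration.

    Counts are drawn directly at the pileup level: coverage per site is
    negative binomial, each of the three substitution counts is binomial at
    ``seq_error / 3``, deletions at ``del_error``.
    """
    refs = np.array(list("ACGT"))[rng.integers(0, 4, n_sites)]
    out: dict[str, pd.DataFrame] = {}
    p_nb = coverage_size / (coverage_size + coverage_mean)
    for r in range(n_replicates):
        cov = rng.negative_binomial(coverage_size, p_nb, n_sites)
        alt_counts = rng.binomial(cov[:, None], seq_error / 3.0, (n_sites, 3))
        dels = rng.binomial(cov, del_error)
        counts = {b: np.zeros(n_sites, dtype=np.int64) for b in "ACGT"}
        for bi, b in enumerate("ACGT"):
            ref_rows = refs == b
            counts[b][ref_rows] = (cov - alt_counts.sum(axis=1))[ref_rows]
        for b in "ACGT":
            ref_rows = refs == b
            alts = [a for a in "ACGT" if a != b]
            for ai, a in enumerate(alts):
                counts[a][ref_rows] += alt_counts[ref_rows, ai]
        total = sum(counts[b] for b in "ACGT")
        ref_count = np.array([counts[refs[i]][i] for i in range(n_sites)])
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(total > 0, (total - ref_count) / np.maximum(total, 1), np.nan)
        out[f"null_rep{r + 1}"] = pd.DataFrame(
            {
                "target_id": "null",
                "pos": np.arange(1, n_sites + 1),
                "ref": refs,
                "A": counts["A"],
                "C": counts["C"],
                "G": counts["G"],
                "T": counts["T"],
                "del": dels,
                "ins": 0,
                "coverage": total,
                "error_rate": rate,
            },
            columns=PILEUP_COLUMNS,
        )
    return out


def evaluate_calls(
    truth: SimTruth,
    calls: Sequence[tuple[str, int]],
    assignments: pd.DataFrame | None = None,
    wt_condition: str = "WT",
) -> dict:
    """Recovery metrics of a call set (and optionally of the differential
    classification) against the truth manifest."""
    truth_sites = truth.modified_sites(wt_condition)
    called = set((t, int(p)) for t, p in calls)
    tp = len(called & truth_sites)
    metrics = {
        "sensitivity": tp / len(truth_sites) if truth_sites else float("nan"),
        "false_discovery_proportion": (
            len(called - truth_sites) / len(called) if called else 0.0
        ),
        "n_truth": len(truth_sites),
        "n_called": len(called),
        "n_true_positive": tp,
    }
    if assignments is not None and not assignments.empty:
        correct = 0
        total = 0
        for row in assignments.itertuples(index=False):
            site = (row.target_id, int(row.pos))
            if site not in truth_sites:
                continue
            expected = (
                "retained"
                if site in truth.modified_sites(row.ko_condition)
                else "lost"
            )
            total += 1
            correct += int(row.status == expected)
        metrics["classification_total"] = total
        metrics["classification_correct"] = correct
        metrics["classification_accuracy"] = correct / total if total else float("nan")
    return metrics
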