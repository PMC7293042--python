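"""tRNA-aware reference construction.

tRNA sequencing needs two references, used in two successive mapping stages:

1. a *stage-1* reference made of the genome with every tRNA locus masked to
   ``N`` plus, as separate sequences, each tRNA gene with 50 nt of genomic
   flank on either side.  Reads aligning to the core genome, or partially
   into a flank (precursor reads retaining leader/trailer sequence), are
   discarded by the triage step.
2. a *stage-2* reference made of mature tRNA sequences: introns removed,
   ``CCA`` appended, and identical mature sequences collapsed into a single
   representative so that reads from indistinguishable gene copies map
   uniquely.

Coordinates are BED-style 0-based half-open throughout.  Intron coordinates
are gene-local, on the sense strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_FLANK = 50


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence (IUPAC beyond ACGTN not supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """An interval falls outside the bounds of its chromosome."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open stranded interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def check_bounds(self, genome: Mapping[str, str]) -> None:
        if self.chrom not in genome:
            raise CoordinateError(f"unknown chromosome {self.chrom!r}")
        if self.end > len(genome[self.chrom]):
            raise CoordinateError(
                f"locus {self.chrom}:{self.start}-{self.end} extends beyond "
                f"chromosome end ({len(genome[self.chrom])} nt)"
            )


@dataclass
class TRNAGeneRecord:
    """A genomic tRNA gene: locus, sense-strand sequence and introns.

    ``introns`` are 0-based half-open sub-intervals in gene-local sense-strand
    coordinates.  ``spliced_seq`` is the genomic sequence with introns
    removed; for minus-strand genes ``genomic_seq`` is already the reverse
    complement of the locus slice.
    """

    gene_id: str
    locus: GenomicInterval
    genomic_seq: str
    introns: tuple[tuple[int, int], ...] = ()
    anticodon_label: str = ""

    def __post_init__(self) -> None:
        self.genomic_seq = self.genomic_seq.upper()
        self.introns = tuple((int(a), int(b)) for a, b in self.introns)
        n = len(self.genomic_seq)
        if n != len(self.locus):
            raise ValueError(
                f"{self.gene_id}: sequence length {n} != locus length {len(self.locus)}"
            )
        prev = 0
        for a, b in self.introns:
            if not (0 < a < b < n):
                raise ValueError(f"{self.gene_id}: intron [{a},{b}) outside gene body")
            if a < prev:
                raise ValueError(f"{self.gene_id}: introns overlap or are unsorted")
            prev = b

    @classmethod
    def from_genome(
        cls,
        genome: Mapping[str, str],
        gene_id: str,
        locus: GenomicInterval,
        introns: Sequence[tuple[int, int]] = (),
        anticodon_label: str = "",
    ) -> "TRNAGeneRecord":
        locus.check_bounds(genome)
        seq = genome[locus.chrom][locus.start : locus.end]
        if locus.strand == "-":
            seq = reverse_complement(seq)
        return cls(gene_id, locus, seq, tuple(introns), anticodon_label)

    @property
    def spliced_seq(self) -> str:
        if not self.introns:
            return self.genomic_seq
        parts, prev = [], 0
        for a, b in self.introns:
            parts.append(self.genomic_seq[prev:a])
            prev = b
        parts.append(self.genomic_seq[prev:])
        return "".join(parts)

    @property
    def mature_seq(self) -> str:
        """Spliced sequence with the 3' CCA tail appended."""
        return self.spliced_seq + "CCA"


@dataclass
class FlankedGeneSeq:
    """A tRNA gene with genomic flanks, in sense-strand orientation.

    Flanks are truncated (never padded) at chromosome ends; the actual flank
    lengths are recorded so the gene body can always be located inside
    ``sequence``.
    """

    gene_id: str
    sequence: str
    flank5: int
    flank3: int

    @property
    def body_span(self) -> tuple[int, int]:
        return (self.flank5, len(self.sequence) - self.flank3)


@dataclass
class MatureTRNA:
    """A collapsed representative mature tRNA sequence."""

    rep_id: str
    sequence: str
    member_gene_ids: tuple[str, ...]


def mask_genome(
    genome: Mapping[str, str], loci: Iterable[GenomicInterval]
) -> dict[str, str]:
    """Replace every base inside any locus with ``N``.

    Names, order and per-chromosome lengths are preserved; overlapping loci
    mask the union of their positions.
    """
    buffers = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    for locus in loci:
        locus.check_bounds(genome)
        buffers[locus.chrom][locus.start : locus.end] = b"N" * len(locus)
    return {name: buf.decode("ascii") for name, buf in buffers.items()}


def extract_flanked_genes(
    genome: Mapping[str, str],
    genes: Sequence[TRNAGeneRecord],
    flank_len: int = DEFAULT_FLANK,
) -> list[FlankedGeneSeq]:
    """Cut each gene plus up to ``flank_len`` nt of genomic flank per side.

    Minus-strand genes take their flanks from the genomically downstream /
    upstream sides and the whole window is reverse complemented, so the
    returned sequence is always 5'flank + gene + 3'flank on the sense strand.
    """
    out = []
    for gene in genes:
        loc = gene.locus
        loc.check_bounds(genome)
        chrom = genome[loc.chrom]
        left = min(flank_len, loc.start)
        right = min(flank_len, len(chrom) - loc.end)
        window = chrom[loc.start - left : loc.end + right]
        if loc.strand == "-":
            window = reverse_complement(window)
            flank5, flank3 = right, left
        else:
            flank5, flank3 = left, right
        out.append(FlankedGeneSeq(gene.gene_id, window.upper(), flank5, flank3))
    return out


def build_mature_library(
    genes: Sequence[TRNAGeneRecord], cca_if_absent: bool = False
) -> list[MatureTRNA]:
    """Collapse genes into representative mature sequences.

    The collapsing key is the exact mature sequence string (spliced + CCA,
    uppercased).  With ``cca_if_absent`` the tail is only appended when the
    spliced sequence does not already end in CCA; by default it is appended
    unconditionally.  Genes whose mature sequence contains non-ACGT
    characters are excluded with a warning.  Output is ordered
    lexicographically by sequence; each representative is named after the
    lexicographically smallest member gene id.
    """
    seen_ids: set[str] = set()
    by_seq: dict[str, list[str]] = {}
    for gene in genes:
        if gene.gene_id in seen_ids:
            raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
        seen_ids.add(gene.gene_id)
        spliced = gene.spliced_seq.upper()
        if cca_if_absent and spliced.endswith("CCA"):
            mature = spliced
        else:
            mature = spliced + "CCA"
        if set(mature) - set("ACGT"):
            logger.warning(
                "excluding %s from mature library: non-ACGT characters", gene.gene_id
            )
            continue
        by_seq.setdefault(mature, []).append(gene.gene_id)
    library = []
    for seq in sorted(by_seq):
        members = tuple(sorted(by_seq[seq]))
        library.append(MatureTRNA(rep_id=members[0], sequence=seq, member_gene_ids=members))
    return library


def gene_to_representative(library: Sequence[MatureTRNA]) -> dict[str, str]:
    """Map every member gene id to its representative id."""
    return {g: rep.rep_id for rep in library for g in rep.member_gene_ids}


# ---------------------------------------------------------------------------
# File formats


def write_fasta(path, records: Mapping[str, str] | Iterable[tuple[str, str]]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    items = records.items() if isinstance(records, Mapping) else records
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in items),
        str(path),
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_flanked_fasta(path, flanked: Sequence[FlankedGeneSeq]) -> None:
    write_fasta(
        path,
        [
            (f"{f.gene_id}|flank5={f.flank5}|flank3={f.flank3}", f.sequence)
            for f in flanked
        ],
    )


def read_flanked_fasta(path) -> list[FlankedGeneSeq]:
    out = []
    for name, seq in read_fasta(path).items():
        gene_id, f5, f3 = name.split("|")
        out.append(
            FlankedGeneSeq(
                gene_id,
                seq,
                int(f5.removeprefix("flank5=")),
                int(f3.removeprefix("flank3=")),
            )
        )
    return out


def write_mature_fasta(path, library: Sequence[MatureTRNA]) -> None:
    write_fasta(
        path,
        [
            (f"{m.rep_id}|members={','.join(m.member_gene_ids)}", m.sequence)
            for m in library
        ],
    )


def read_mature_fasta(path) -> list[MatureTRNA]:
    out = []
    for name, seq in read_fasta(path).items():
        rep_id, members = name.split("|", 1)
        out.append(
            MatureTRNA(rep_id, seq, tuple(members.removeprefix("members=").split(",")))
        )
    return out


def write_gene_map(path, library: Sequence[MatureTRNA]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\trep_id\n")
        for rep in library:
            for g in rep.member_gene_ids:
                fh.write(f"{g}\t{rep.rep_id}\n")


def write_bed12(path, genes: Sequence[TRNAGeneRecord]) -> None:
    """Write genes as BED12; blocks are exons (gene minus introns)."""
    with open(path, "w") as fh:
        for g in genes:
            loc = g.locus
            n = len(loc)
            # gene-local sense-strand exon intervals
            exons, prev = [], 0
            for a, b in g.introns:
                exons.append((prev, a))
                prev = b
            exons.append((prev, n))
            if loc.strand == "-":
                exons = [(n - b, n - a) for a, b in reversed(exons)]
            starts = ",".join(str(a) for a, _ in exons)
            sizes = ",".join(str(b - a) for a, b in exons)
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{g.gene_id}\t0\t{loc.strand}\t"
                f"{loc.start}\t{loc.end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


def read_bed(path, genome: Mapping[str, str]) -> list[TRNAGeneRecord]:
    """Read tRNA genes from BED6 or BED12 (blocks = exons, gaps = introns)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            locus = GenomicInterval(chrom, start, end, strand)
            introns: list[tuple[int, int]] = []
            if len(f) >= 12:
                nblocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")][:nblocks]
                starts = [int(x) for x in f[11].rstrip(",").split(",")][:nblocks]
                exons = [(s, s + l) for s, l in zip(starts, sizes)]
                exons.sort()
                n = end - start
                if strand == "-":
                    exons = [(n - b, n - a) for a, b in reversed(exons)]
                for (_, b1), (a2, _) in zip(exons, exons[1:]):
                    if a2 > b1:
                        introns.append((b1, a2))
            genes.append(TRNAGeneRecord.from_genome(genome, name, locus, introns))
    return genes
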