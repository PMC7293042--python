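"""A minimal built-in short-read aligner and alignment records.

The aligner exists so that the pipeline can be exercised end-to-end on
synthetic libraries without an external mapper; real data can enter through
SAM files instead (:func:`read_sam`).  Alignment is local ("glocal" with
free soft-clipping of read ends): the aligned segment is scored with
match +1, mismatch -1, linear gap -2 by default, and unaligned read ends are
reported as soft clips.  All maximal-scoring sites across all targets are
returned, which is what the multimapper filter needs.

The dynamic programming matrix is filled row-wise with numpy; with a linear
gap penalty the within-row (left-gap) dependency reduces to a running
maximum, so each row is a handful of vectorised operations.  A k-mer index
restricts dynamic programming to plausible targets; reads that match a
target exactly are found by plain substring search, which is provably
optimal under positive match score.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_CIG_RE = re.compile(r"(\d+)([MIDS])")

READ_CONSUMING = frozenset("MIS")
TARGET_CONSUMING = frozenset("MD")


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap: int = -2  # linear: gap open and extend cost the same


@dataclass
class ReadRecord:
    """A sequencing read; ``qual`` holds Phred scores (None = unknown)."""

    read_id: str
    seq: str
    qual: np.ndarray | None = None


@dataclass
class AlignmentRecord:
    """One alignment of a read to a target sequence.

    ``cigar`` is a list of (op, length) with ops M (match/mismatch), I
    (insertion to target), D (deletion from target) and S (soft clip).
    """

    read_id: str
    target_id: str
    target_start: int
    cigar: list[tuple[str, int]]
    score: int
    mapq: int = 60
    base_quals: np.ndarray | None = None
    read_seq: str | None = None
    n_best_sites: int = 1

    @property
    def cigar_string(self) -> str:
        return "".join(f"{l}{op}" for op, l in self.cigar)

    @property
    def reference_span(self) -> int:
        return sum(l for op, l in self.cigar if op in TARGET_CONSUMING)

    @property
    def target_end(self) -> int:
        return self.target_start + self.reference_span

    @property
    def read_length(self) -> int:
        return sum(l for op, l in self.cigar if op in READ_CONSUMING)

    def validate(self, target_len: int | None = None) -> None:
        if self.read_seq is not None and self.read_length != len(self.read_seq):
            raise ValueError(
                f"{self.read_id}: cigar consumes {self.read_length} bases, "
                f"read has {len(self.read_seq)}"
            )
        if target_len is not None and self.target_end > target_len:
            raise ValueError(
                f"{self.read_id}: alignment ends at {self.target_end} beyond "
                f"target length {target_len}"
            )

    def aligned_pairs(self) -> list[tuple[int | None, int | None]]:
        """(read index, target index) pairs; None marks a gap. Clips are skipped."""
        pairs: list[tuple[int | None, int | None]] = []
        r, t = 0, self.target_start
        for op, l in self.cigar:
            if op == "M":
                pairs.extend((r + i, t + i) for i in range(l))
                r += l
                t += l
            elif op == "I":
                pairs.extend((r + i, None) for i in range(l))
                r += l
            elif op == "D":
                pairs.extend((None, t + i) for i in range(l))
                t += l
            else:  # S
                r += l
        return pairs

    def aligned_target_substring(self, target_seq: str) -> str:
        return target_seq[self.target_start : self.target_end]


@dataclass
class MappingGroup:
    """All best-scoring alignments of one read."""

    read_id: str
    alignments: list[AlignmentRecord]

    def __post_init__(self) -> None:
        if self.alignments:
            scores = {a.score for a in self.alignments}
            if len(scores) > 1:
                raise ValueError(f"{self.read_id}: mixed scores in mapping group")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIG_RE.findall(cigar)]


def _merge_cigar(ops: Iterable[str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _sw_matrix(q: np.ndarray, t: np.ndarray, sc: Scoring) -> np.ndarray:
    """Local-alignment score matrix, (len(q)+1) x (len(t)+1)."""
    m, n = q.size, t.size
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    c = -sc.gap
    ramp = (c * np.arange(1, n + 1)).astype(np.int32)
    subs: dict[int, np.ndarray] = {}
    for i in range(1, m + 1):
        b = int(q[i - 1])
        sub = subs.get(b)
        if sub is None:
            sub = np.where(t == b, sc.match, sc.mismatch).astype(np.int32)
            subs[b] = sub
        prev = H[i - 1]
        best = prev[:-1] + sub
        np.maximum(best, prev[1:] + sc.gap, out=best)
        np.maximum(best, 0, out=best)
        # left-gap closure: running maximum of best[k] - c*(j-k)
        best += ramp
        np.maximum.accumulate(best, out=best)
        best -= ramp
        H[i, 1:] = best
    return H


def _traceback(
    H: np.ndarray, q: np.ndarray, t: np.ndarray, i: int, j: int, sc: Scoring
) -> tuple[int, list[tuple[str, int]]]:
    """Trace one alignment ending at cell (i, j); ties prefer M, then I, then D."""
    end_i = i
    ops: list[str] = []
    while i > 0 and j > 0 and H[i, j] > 0:
        s = sc.match if q[i - 1] == t[j - 1] else sc.mismatch
        h = H[i, j]
        if h == H[i - 1, j - 1] + s:
            ops.append("M")
            i -= 1
            j -= 1
        elif h == H[i - 1, j] + sc.gap:
            ops.append("I")
            i -= 1
        elif h == H[i, j - 1] + sc.gap:
            ops.append("D")
            j -= 1
        else:  # restart cell
            break
    cigar = _merge_cigar(reversed(ops))
    if i > 0:
        cigar.insert(0, ("S", i))
    if end_i < q.size:
        cigar.append(("S", q.size - end_i))
    return j, cigar


@dataclass
class TargetIndex:
    """k-mer index over a set of target sequences."""

    names: list[str]
    seqs: list[str]
    k: int = 13
    kmers: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ti, seq in enumerate(self.seqs):
            for pos in range(0, len(seq) - self.k + 1):
                self.kmers.setdefault(seq[pos : pos + self.k], []).append((ti, pos))

    @property
    def total_bases(self) -> int:
        return sum(len(s) for s in self.seqs)


def build_index(targets: Mapping[str, str], k: int = 13) -> TargetIndex:
    names = list(targets)
    return TargetIndex(names=names, seqs=[targets[n].upper() for n in names], k=k)


def _candidate_windows(
    index: TargetIndex, seq: str, pad: int
) -> dict[int, tuple[int, int]]:
    """Candidate targets and the window of each worth aligning against."""
    hits: dict[int, list[int]] = {}
    k = index.k
    for qpos in range(0, max(len(seq) - k + 1, 1), max(1, k // 2)):
        for ti, tpos in index.kmers.get(seq[qpos : qpos + k], ()):
            hits.setdefault(ti, []).append(tpos - qpos)
    windows = {}
    for ti, diags in hits.items():
        tlen = len(index.seqs[ti])
        if tlen <= 4 * (len(seq) + pad):
            windows[ti] = (0, tlen)
        else:
            lo = max(0, min(diags) - pad)
            hi = min(tlen, max(diags) + len(seq) + pad)
            windows[ti] = (lo, hi)
    return windows


# below this many total target bases every target is aligned exhaustively;
# above it a k-mer seed step selects candidate targets first
EXHAUSTIVE_BASES = 1_500
FALLBACK_BASES = 200_000


def _align_seq(
    seq: str, index: TargetIndex, sc: Scoring
) -> list[tuple[int, int, list[tuple[str, int]], int]]:
    """All best-scoring sites of ``seq``: (target_idx, start, cigar, score)."""
    # exact substring hits achieve the maximal possible score; no DP needed
    exact = []
    for ti, tseq in enumerate(index.seqs):
        start = tseq.find(seq)
        while start != -1:
            exact.append((ti, start, [("M", len(seq))], sc.match * len(seq)))
            start = tseq.find(seq, start + 1)
    if exact:
        return exact

    q = _encode(seq)
    pad = max(30, len(seq) // 2)
    if index.total_bases <= EXHAUSTIVE_BASES:
        windows = {ti: (0, len(s)) for ti, s in enumerate(index.seqs)}
    else:
        windows = _candidate_windows(index, seq, pad)
        if not windows and index.total_bases <= FALLBACK_BASES:
            windows = {ti: (0, len(s)) for ti, s in enumerate(index.seqs)}
    best_score = 0
    sites: list[tuple[int, int, list[tuple[str, int]], int]] = []
    for ti, (lo, hi) in sorted(windows.items()):
        t = _encode(index.seqs[ti][lo:hi])
        H = _sw_matrix(q, t, sc)
        score = int(H.max())
        if score <= 0 or score < best_score:
            continue
        if score > best_score:
            best_score = score
            sites = []
        seen = set()
        ii, jj = np.nonzero(H == score)
        for i, j in sorted(zip(ii.tolist(), jj.tolist()), key=lambda x: (x[1], x[0])):
            start, cigar = _traceback(H, q, t, i, j, sc)
            key = (lo + start, tuple(cigar))
            if key not in seen:
                seen.add(key)
                sites.append((ti, lo + start, cigar, score))
    return sites


def naive_align(
    reads: Iterable[ReadRecord],
    targets: Mapping[str, str] | TargetIndex,
    scoring: Scoring = Scoring(),
    min_score: int = 1,
    cache: dict | None = None,
) -> list[MappingGroup]:
    """Align reads against every target; return all maximal-scoring sites.

    Reads longer than 500 nt are rejected (this is a desk-scale aligner);
    empty reads are skipped with a warning.  Results are deterministic:
    alignments are ordered by (target_id, target_start) and identical read
    sequences share one alignment computation.
    """
    index = targets if isinstance(targets, TargetIndex) else build_index(targets)
    if not index.names:
        raise ValueError("no target sequences")
    if cache is None:
        cache = {}
    groups = []
    for read in reads:
        if not read.seq:
            logger.warning("skipping empty read %s", read.read_id)
            continue
        if len(read.seq) > 500:
            raise ValueError(f"read {read.read_id} exceeds 500 nt")
        seq = read.seq.upper()
        sites = cache.get(seq)
        if sites is None:
            sites = _align_seq(seq, index, scoring)
            sites.sort(key=lambda s: (index.names[s[0]], s[1]))
            cache[seq] = sites
        alns = [
            AlignmentRecord(
                read_id=read.read_id,
                target_id=index.names[ti],
                target_start=start,
                cigar=list(cigar),
                score=score,
                base_quals=read.qual,
                read_seq=seq,
                n_best_sites=len(sites),
            )
            for ti, start, cigar, score in sites
            if score >= min_score
        ]
        if alns:
            groups.append(MappingGroup(read.read_id, alns))
    return groups


def left_normalize_indels(aln: AlignmentRecord, target_seq: str) -> AlignmentRecord:
    """Shift each indel as far left as an identical aligned sequence allows.

    Approximates indel-realignment tools operating read-by-read: a deletion
    (or insertion) inside a repeat is moved to the leftmost equivalent
    placement.  The alignment score is unchanged because the swapped
    match/mismatch status of flanking bases is preserved by the identity
    condition.
    """
    if aln.read_seq is None:
        raise ValueError("left_normalize_indels requires read_seq")
    read = aln.read_seq.upper()
    target = target_seq.upper()
    # expand to unit ops with read/target cursors
    units: list[str] = []
    for op, l in aln.cigar:
        units.extend(op * l)
    changed = True
    while changed:
        changed = False
        r, t = 0, aln.target_start
        positions = []  # (unit index, op, read pos, target pos)
        for idx, op in enumerate(units):
            positions.append((idx, op, r, t))
            if op in READ_CONSUMING:
                r += 1
            if op in TARGET_CONSUMING:
                t += 1
        for idx, op, r, t in positions:
            if op not in "ID" or idx == 0 or units[idx - 1] != "M":
                continue
            # length of this indel run
            end = idx
            while end < len(units) and units[end] == op:
                end += 1
            l = end - idx
            if op == "D":
                ok = target[t - 1] == target[t + l - 1]
            else:
                ok = read[r - 1] == read[r + l - 1]
            if ok:
                # move the preceding M to after the indel run
                units[idx - 1 : end] = units[idx:end] + ["M"]
                changed = True
                break
    return replace(aln, cigar=_merge_cigar(units))


# ---------------------------------------------------------------------------
# SAM interoperability (external aligners in, kept alignments out)


def read_sam(path, with_sequence: bool = True) -> list[MappingGroup]:
    """Load alignments from SAM/BAM and group them by read.

    The alignment score is taken from the AS tag when present, else from the
    number of matching bases implied by the cigar; within each read only the
    best-scoring alignments are kept, mirroring how mapping groups are built
    internally.
    """
    import pysam

    by_read: dict[str, list[AlignmentRecord]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.cigartuples is None:
                continue
            cigar = [
                ("MIDS"[op], l) for op, l in seg.cigartuples if op in (0, 1, 2, 4)
            ]
            quals = (
                np.asarray(seg.query_qualities, dtype=np.int16)
                if seg.query_qualities is not None
                else None
            )
            score = (
                int(seg.get_tag("AS"))
                if seg.has_tag("AS")
                else sum(l for op, l in cigar if op == "M")
            )
            by_read.setdefault(seg.query_name, []).append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    target_id=seg.reference_name,
                    target_start=seg.reference_start,
                    cigar=cigar,
                    score=score,
                    mapq=seg.mapping_quality,
                    base_quals=quals,
                    read_seq=seg.query_sequence if with_sequence else None,
                )
            )
    groups = []
    for read_id, alns in by_read.items():
        top = max(a.score for a in alns)
        best = sorted(
            (a for a in alns if a.score == top),
            key=lambda a: (a.target_id, a.target_start),
        )
        for a in best:
            a.n_best_sites = len(best)
        groups.append(MappingGroup(read_id, best))
    groups.sort(key=lambda g: g.read_id)
    return groups


def write_sam(path, alignments: Sequence[AlignmentRecord], targets: Mapping[str, str]) -> None:
    import pysam

    names = list(targets)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(targets[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = aln.read_id
            seg.reference_id = tid[aln.target_id]
            seg.reference_start = aln.target_start
            seg.mapping_quality = aln.mapq
            seg.cigarstring = aln.cigar_string
            if aln.read_seq is not None:
                seg.query_sequence = aln.read_seq
                if aln.base_quals is not None:
                    seg.query_qualities = [int(q) for q in aln.base_quals]
            seg.set_tag("AS", int(aln.score))
            seg.set_tag("NH", int(aln.n_best_sites))
            fh.write(seg)


def write_fastq(path, reads: Sequence[ReadRecord]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    def _records():
        for r in reads:
            quals = (
                [int(q) for q in r.qual] if r.qual is not None else [40] * len(r.seq)
            )
            rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = quals
            yield rec

    SeqIO.write(_records(), str(path), "fastq")


def read_fastq(path) -> list[ReadRecord]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            ReadRecord(
                rec.id,
                str(rec.seq).upper(),
                np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16),
            )
        )
    return out
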