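"""Quality-gated per-position event counts on mature tRNAs.

Alignments are converted into per-position counts of each called base,
deletions and insertion starts.  Reads below the mapping-quality threshold
are skipped entirely; base calls below the base-quality threshold are
excluded from the base counts but the read still counts toward
``reads_spanning``.  Deletions are attributed to every deleted reference
position; insertions to the reference position immediately 5' of the
insertion.

The per-sample TSV written by :func:`write_pileup_tsv` (columns target_id,
pos, ref, A, C, G, T, del, ins, coverage, error_rate; ``pos`` is 1-based on
the mature sequence) is the interchange format consumed by the site caller
and the differential report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord

BASES = "ACGT"
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

PILEUP_COLUMNS = [
    "target_id", "pos", "ref", "A", "C", "G", "T", "del", "ins",
    "coverage", "error_rate",
]


@dataclass
class PileupMatrix:
    """Per-position event counts for one target sequence."""

    target_id: str
    ref_seq: str
    base_counts: np.ndarray = field(init=False)  # (4, L): A, C, G, T
    deletions: np.ndarray = field(init=False)
    insertions: np.ndarray = field(init=False)
    reads_spanning: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        L = len(self.ref_seq)
        self.base_counts = np.zeros((4, L), dtype=np.int64)
        self.deletions = np.zeros(L, dtype=np.int64)
        self.insertions = np.zeros(L, dtype=np.int64)
        self.reads_spanning = np.zeros(L, dtype=np.int64)

    @property
    def basecall_coverage(self) -> np.ndarray:
        return self.base_counts.sum(axis=0)

    def add(self, other: "PileupMatrix") -> None:
        if other.ref_seq != self.ref_seq:
            raise ValueError("pileup matrices refer to different sequences")
        self.base_counts += other.base_counts
        self.deletions += other.deletions
        self.insertions += other.insertions
        self.reads_spanning += other.reads_spanning


def compute_pileup(
    alignments: Iterable[AlignmentRecord],
    targets: Mapping[str, str],
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
) -> dict[str, PileupMatrix]:
    """Count quality-gated events per target position.

    ``targets`` maps target_id to sequence (e.g. the mature library).
    Alignments with ``base_quals`` of None are treated as passing the base
    quality gate.
    """
    mats = {tid: PileupMatrix(tid, seq.upper()) for tid, seq in targets.items()}
    for aln in alignments:
        if aln.mapq < min_mapping_quality:
            continue
        mat = mats.get(aln.target_id)
        if mat is None:
            raise KeyError(f"alignment to unknown target {aln.target_id!r}")
        if aln.target_end > len(mat.ref_seq):
            raise ValueError(
                f"alignment of {aln.read_id} ends at {aln.target_end}, beyond "
                f"{aln.target_id} length {len(mat.ref_seq)}"
            )
        if aln.read_seq is None:
            raise ValueError(f"alignment of {aln.read_id} carries no read sequence")
        codes = _BASE_CODE[np.frombuffer(aln.read_seq.encode("ascii"), np.uint8)]
        quals = aln.base_quals
        mat.reads_spanning[aln.target_start : aln.target_end] += 1
        r, t = 0, aln.target_start
        for op, l in aln.cigar:
            if op == "M":
                seg = codes[r : r + l]
                ok = seg >= 0
                if quals is not None:
                    ok &= np.asarray(quals[r : r + l]) >= min_base_quality
                tpos = np.arange(t, t + l)[ok]
                np.add.at(mat.base_counts, (seg[ok], tpos), 1)
                r += l
                t += l
            elif op == "D":
                mat.deletions[t : t + l] += 1
                t += l
            elif op == "I":
                if t > 0:
                    mat.insertions[t - 1] += 1
                r += l
            else:  # S
                r += l
    return mats


def site_error_rate(
    pileup: PileupMatrix, pos: int, include_deletions: bool = False
) -> float:
    """Fraction of non-reference events at a 0-based position.

    Deletions are excluded from numerator and denominator unless
    ``include_deletions``.  Returns NaN (missing, not zero) when there is no
    base-call coverage.
    """
    ref_code = _BASE_CODE[ord(pileup.ref_seq[pos])]
    column = pileup.base_counts[:, pos]
    denom = int(column.sum())
    if ref_code < 0:
        raise ValueError(f"reference base {pileup.ref_seq[pos]!r} at {pos} is not ACGT")
    mism = denom - int(column[ref_code])
    if include_deletions:
        mism += int(pileup.deletions[pos])
        denom += int(pileup.deletions[pos])
    if denom == 0:
        return float("nan")
    return mism / denom


def pileup_to_frame(
    pileups: Mapping[str, PileupMatrix] | Sequence[PileupMatrix],
    include_deletions_in_rate: bool = False,
) -> pd.DataFrame:
    """Flatten pileup matrices into the interchange table (pos is 1-based)."""
    if isinstance(pileups, Mapping):
        pileups = [pileups[k] for k in sorted(pileups)]
    frames = []
    for mat in pileups:
        L = len(mat.ref_seq)
        cov = mat.basecall_coverage
        ref_codes = _BASE_CODE[np.frombuffer(mat.ref_seq.encode("ascii"), np.uint8)]
        ref_counts = mat.base_counts[ref_codes, np.arange(L)]
        if include_deletions_in_rate:
            denom = cov + mat.deletions
            mism = cov - ref_counts + mat.deletions
        else:
            denom = cov
            mism = cov - ref_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(denom > 0, mism / np.maximum(denom, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "target_id": mat.target_id,
                    "pos": np.arange(1, L + 1),
                    "ref": list(mat.ref_seq),
                    "A": mat.base_counts[0],
                    "C": mat.base_counts[1],
                    "G": mat.base_counts[2],
                    "T": mat.base_counts[3],
                    "del": mat.deletions,
                    "ins": mat.insertions,
                    "coverage": cov,
                    "error_rate": rate,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=PILEUP_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_pileup_tsv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_pileup_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"target_id": str, "ref": str})
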