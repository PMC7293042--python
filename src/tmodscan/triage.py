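"""Two-stage read triage for tRNA sequencing.

Stage 1 separates precursor- and genome-derived reads from mature-tRNA
reads: any read whose best alignment lands on a core-genome sequence, or
overlaps at least one flank position of a flanked tRNA gene, is eliminated.
Stage 2 maps the surviving reads to the mature tRNA library and applies the
multimapper rule: a read is kept only if it maps uniquely, or if all of its
equally-scoring sites produce character-identical alignments (in which case
one representative site is retained).

Soft-clipped bases consume no reference and therefore never count toward
flank overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import (
    AlignmentRecord,
    MappingGroup,
    ReadRecord,
    Scoring,
    TargetIndex,
    build_index,
    naive_align,
)
from .reference import FlankedGeneSeq, MatureTRNA

logger = logging.getLogger(__name__)


class ReferenceMismatchError(KeyError):
    """An alignment refers to a sequence absent from the triage reference."""


@dataclass
class FlankIndex:
    """Stage-1 reference layout: which names are core genome, and where the
    gene body sits inside each flanked-gene sequence."""

    core_names: frozenset[str]
    body_spans: dict[str, tuple[int, int]]

    @classmethod
    def from_reference(
        cls, genome_names: Iterable[str], flanked: Sequence[FlankedGeneSeq]
    ) -> "FlankIndex":
        return cls(
            core_names=frozenset(genome_names),
            body_spans={f.gene_id: f.body_span for f in flanked},
        )


@dataclass
class TriageResult:
    eliminated: set[str]
    candidates: set[str]


def _overlaps_flank(aln: AlignmentRecord, body: tuple[int, int]) -> bool:
    return aln.target_start < body[0] or aln.target_end > body[1]


def triage_stage1(
    groups: Iterable[MappingGroup], flank_index: FlankIndex
) -> TriageResult:
    """Partition reads into eliminated and stage-2 candidates.

    A read is eliminated if *any* of its best alignments is on a core-genome
    sequence or touches at least one flank position; reads with no alignment
    at all are candidates (elimination requires positive evidence).
    """
    eliminated: set[str] = set()
    candidates: set[str] = set()
    for group in groups:
        bad = False
        for aln in group.alignments:
            if aln.target_id in flank_index.core_names:
                bad = True
            elif aln.target_id in flank_index.body_spans:
                bad = bad or _overlaps_flank(
                    aln, flank_index.body_spans[aln.target_id]
                )
            else:
                raise ReferenceMismatchError(
                    f"alignment of {group.read_id} refers to unknown reference "
                    f"{aln.target_id!r}"
                )
        (eliminated if bad else candidates).add(group.read_id)
    return TriageResult(eliminated=eliminated, candidates=candidates)


def filter_multimappers(
    group: MappingGroup, targets: Mapping[str, str]
) -> list[AlignmentRecord]:
    """Keep a read only if uniquely mapped or identically multi-mapped.

    "Identical alignments" is operationalised as identical (aligned target
    substring, cigar) pairs across all best sites; when all sites are
    identical, the one with the lexicographically smallest (target_id,
    target_start) is retained with ``n_best_sites`` recording the original
    multiplicity.
    """
    alns = sorted(group.alignments, key=lambda a: (a.target_id, a.target_start))
    if not alns:
        return []
    if len(alns) == 1:
        alns[0].n_best_sites = 1
        return alns
    keys = {
        (a.aligned_target_substring(targets[a.target_id]), a.cigar_string)
        for a in alns
    }
    if len(keys) > 1:
        return []
    kept = alns[0]
    kept.n_best_sites = len(alns)
    return [kept]


def map_reads(
    reads: Iterable[ReadRecord],
    mature: Sequence[MatureTRNA] | Mapping[str, str],
    scoring: Scoring = Scoring(),
    index: TargetIndex | None = None,
) -> list[AlignmentRecord]:
    """Stage-2 mapping: align reads to the mature library and apply the
    multimapper rule; returns the kept alignments."""
    if not isinstance(mature, Mapping):
        mature = {m.rep_id: m.sequence for m in mature}
    if index is None:
        index = build_index(mature)
    groups = naive_align(reads, index, scoring)
    kept: list[AlignmentRecord] = []
    for group in groups:
        kept.extend(filter_multimappers(group, mature))
    return kept
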