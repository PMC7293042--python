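"""End-to-end pipeline: reference build, triage, mapping, pileup, calling,
differential report — and the fully synthetic demo experiment.

:func:`run_synthetic_experiment` is the in-memory workhorse used by the
test-suite and the acceptance script: it simulates a reference and a
multi-condition read set with known truth, pushes everything through the
pipeline stages and evaluates recovery.  :func:`run_demo` wraps it and
writes every stage artifact (FASTA/BED/FASTQ/TSV/JSON) to a directory so
each stage can be inspected or re-run from files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .align import ReadRecord, Scoring, build_index, naive_align, write_fastq
from .diffmod import SampleSheet, classify_sites, condition_means, write_report
from .pileup import compute_pileup, pileup_to_frame, write_pileup_tsv
from .reference import (
    build_mature_library,
    extract_flanked_genes,
    gene_to_representative,
    mask_genome,
    write_bed12,
    write_fasta,
    write_flanked_fasta,
    write_gene_map,
    write_mature_fasta,
)
from .simulate import (
    SimConfig,
    SimTruth,
    default_mod_specs,
    evaluate_calls,
    simulate_genomic_reads,
    simulate_reads,
    simulate_reference,
)
from .stats import ModificationCallSet, call_sites, write_calls_tsv
from .triage import FlankIndex, filter_multimappers, triage_stage1

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline tunables with their standard defaults."""

    flank: int = 50
    min_cov: int = 10
    fdr: float = 0.01
    min_base_quality: int = 20
    min_mapping_quality: int = 20
    min_fold: float = 5.0
    events: str = "subs+del"
    cca_if_absent: bool = False
    left_normalize: bool = False
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("sim", {}) or {}).items()
        })
        return cls(sim=sim, **raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class ExperimentResult:
    """Everything an end-to-end synthetic run produces."""

    truth: SimTruth
    sheet: SampleSheet
    pileups: dict[str, pd.DataFrame]
    callset: ModificationCallSet
    error_table: pd.DataFrame
    assignments: pd.DataFrame
    metrics: dict
    triage_counts: dict[str, dict[str, int]]
    library_size: int = 0


def _sample_plan(config: SimConfig, with_ko: bool) -> list[tuple[str, str]]:
    plan = [(f"WT_{i + 1}", "WT") for i in range(config.n_wt)]
    if with_ko:
        for cond in ("KO_A", "KO_B"):
            plan += [(f"{cond}_{i + 1}", cond) for i in range(config.ko_reps)]
    return plan


def run_synthetic_experiment(
    config: PipelineConfig,
    seed: int,
    with_ko: bool = True,
) -> ExperimentResult:
    """Simulate, run all pipeline stages, and evaluate against the truth.

    Deterministic given (config, seed).  Stage order mirrors the analysis
    workflow: masked genome + flanked genes -> stage-1 triage -> mature
    library mapping with the multimapper rule -> quality-gated pileup ->
    site calling -> condition means -> loss classification.
    """
    rng = np.random.default_rng(seed)
    genome, genes = simulate_reference(config.sim, rng)
    masked = mask_genome(genome, [g.locus for g in genes])
    flanked = extract_flanked_genes(genome, genes, config.flank)
    library = build_mature_library(genes, cca_if_absent=config.cca_if_absent)
    specs_by_cond = default_mod_specs(library, rng)
    truth = SimTruth(
        mod_specs=specs_by_cond, gene_map=gene_to_representative(library)
    )

    stage1_targets: dict[str, str] = dict(masked)
    stage1_targets.update({f.gene_id: f.sequence for f in flanked})
    stage1_index = build_index(stage1_targets)
    flank_index = FlankIndex.from_reference(masked.keys(), flanked)
    mature_seqs = {m.rep_id: m.sequence for m in library}
    stage2_index = build_index(mature_seqs)
    scoring = Scoring()
    stage1_cache: dict = {}
    stage2_cache: dict = {}

    plan = _sample_plan(config.sim, with_ko)
    sheet = SampleSheet.from_mapping(dict(plan))
    pileups: dict[str, pd.DataFrame] = {}
    triage_counts: dict[str, dict[str, int]] = {}
    for sample_id, condition in plan:
        reads, elim_expected, body_ids = simulate_reads(
            genome, genes, library, specs_by_cond.get(condition, []),
            config.sim, rng, sample_id,
        )
        greads, gids = simulate_genomic_reads(
            genome, genes, config.sim, rng, sample_id
        )
        reads += greads
        truth.eliminated_read_ids[sample_id] = elim_expected | gids
        truth.body_read_ids[sample_id] = body_ids

        groups1 = naive_align(reads, stage1_index, scoring, cache=stage1_cache)
        triage = triage_stage1(groups1, flank_index)
        # reads with no stage-1 alignment at all remain candidates
        aligned_ids = {g.read_id for g in groups1}
        unaligned = {r.read_id for r in reads} - aligned_ids
        candidates = triage.candidates | unaligned
        stage2_reads = [r for r in reads if r.read_id in candidates]

        groups2 = naive_align(stage2_reads, stage2_index, scoring, cache=stage2_cache)
        kept = []
        for group in groups2:
            kept.extend(filter_multimappers(group, mature_seqs))
        mats = compute_pileup(
            kept,
            mature_seqs,
            min_base_quality=config.min_base_quality,
            min_mapping_quality=config.min_mapping_quality,
        )
        pileups[sample_id] = pileup_to_frame(mats)
        triage_counts[sample_id] = {
            "total": len(reads),
            "eliminated": len(triage.eliminated),
            "candidates": len(candidates),
            "kept_alignments": len(kept),
        }

    callset = call_sites(
        pileups, min_cov=config.min_cov, fdr=config.fdr, events=config.events
    )
    error_table = condition_means(pileups, sheet, callset.sites or [])
    ko_conditions = [c for c in sheet.conditions if c != "WT"]
    assignments = classify_sites(
        callset, error_table, sheet, "WT", ko_conditions, min_fold=config.min_fold
    ) if ko_conditions and not error_table.empty else pd.DataFrame()
    metrics = evaluate_calls(truth, callset.sites, assignments if with_ko else None)
    return ExperimentResult(
        truth=truth,
        sheet=sheet,
        pileups=pileups,
        callset=callset,
        error_table=error_table,
        assignments=assignments,
        metrics=metrics,
        triage_counts=triage_counts,
        library_size=len(library),
    )


def write_references(outdir, genome, genes, flanked, library) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    masked = mask_genome(genome, [g.locus for g in genes])
    write_fasta(outdir / "genome.fa", genome)
    write_fasta(outdir / "genome.masked.fa", masked)
    write_bed12(outdir / "trna_genes.bed", genes)
    write_flanked_fasta(outdir / "flanked_genes.fa", flanked)
    write_mature_fasta(outdir / "mature_library.fa", library)
    write_gene_map(outdir / "gene_map.tsv", library)


def run_demo(
    outdir, config: PipelineConfig | None = None, seed: int = 1
) -> ExperimentResult:
    """End-to-end demo: simulate, analyse, evaluate, and write artifacts."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # write the reference artifacts from an identical generator pass
    rng = np.random.default_rng(seed)
    genome, genes = simulate_reference(config.sim, rng)
    flanked = extract_flanked_genes(genome, genes, config.flank)
    library = build_mature_library(genes, cca_if_absent=config.cca_if_absent)
    write_references(outdir / "reference", genome, genes, flanked, library)

    result = run_synthetic_experiment(config, seed)

    sheet_path = outdir / "samples.tsv"
    result.sheet.frame.to_csv(sheet_path, sep="\t", index=False)
    pdir = outdir / "pileup"
    pdir.mkdir(exist_ok=True)
    for sample_id, frame in result.pileups.items():
        write_pileup_tsv(pdir / f"{sample_id}.pileup.tsv", frame)
    write_calls_tsv(outdir / "calls.tsv", result.callset)
    write_report(result.error_table, result.assignments, outdir / "report")
    result.truth.to_json(outdir / "truth.json")
    summary = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "n_mature_representatives": result.library_size,
        "triage": result.triage_counts,
        "n_called_sites": len(result.callset.sites),
        "metrics": result.metrics,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return result
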