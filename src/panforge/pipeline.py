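"""Stage orchestration: configuration, panreference building, end-to-end runs.

The pipeline mirrors the map-then-assemble flow: triage the read pairs the
reference mapping left behind, assemble them per individual, filter and
deduplicate the contigs, concatenate the survivors onto the reference as a
panreference, remap, and anchor each contig through bridging mate pairs.

Two entry modes exist.  File mode consumes real alignments (BAM/SAM from an
external mapper) at each boundary.  Simulation mode generates everything —
genomes, reads, truth-aware alignments — from one seed and additionally
scores the run against the planted truth; it is the basis of the end-to-end
tests and of the reproduction script.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import yaml

from . import io as pio
from .anchoring import AnchorParams, Placement, anchor, anchoring_summary
from .assembly import AssemblyParams, assembly_stats, build_unitigs
from .cluster import cluster_greedy, cluster_stats, representatives
from .filtering import filter_cascade
from .records import SequenceRecord
from .simulate import (
    ContigProvenance,
    DonorSet,
    SimConfig,
    locate_contigs,
    novel_segment_coverage,
    refined_assembly_hits,
    reads_to_fastq,
    simulate_donors,
    simulate_reads,
    simulate_reference,
    truth_aligner,
    truth_flank_hits,
    truth_panref_aligner,
    write_truth_csv,
)
from .triage import TriageMode, extract_left_behind
from .validation import ValidationParams, flank_concordance, validate_contigs


@dataclass(frozen=True)
class TriageConfig:
    mode: str = "not-proper-pair"


@dataclass(frozen=True)
class AssemblyConfig:
    k: int = 63
    # noise floor for k-mer counts; scales roughly with depth/10 so that
    # recurrent sequencing errors do not seed branch k-mers at 30x
    min_kmer_count: int = 3
    min_contig_len: int = 300
    # assemble only the unmapped members of selected pairs: the mapped mates
    # are reference sequence by definition and would only pad contigs with
    # reference flank of erratic depth, pushing the anchorable junction out
    # of the contig end windows
    unmapped_reads_only: bool = True

    def params(self) -> AssemblyParams:
        return AssemblyParams(k=self.k, min_kmer_count=self.min_kmer_count, min_contig_len=self.min_contig_len)


@dataclass(frozen=True)
class FilterConfig:
    min_len: int = 300
    min_vector_identity: float = 0.9
    min_vector_match_len: int = 30
    allowed_taxa: tuple[str, ...] = ()
    organelle_targets: tuple[str, ...] = ()


@dataclass(frozen=True)
class DedupConfig:
    min_identity: float = 0.80
    min_len_ratio: float = 0.95


@dataclass(frozen=True)
class AnchorConfig:
    end_window: int = 300
    min_support: int = 10
    min_mapq: int = 10
    max_span: int = 2000
    merge_distance: Optional[int] = None

    def params(self) -> AnchorParams:
        return AnchorParams(
            end_window=self.end_window,
            min_support=self.min_support,
            min_mapq=self.min_mapq,
            max_span=self.max_span,
            merge_distance=self.merge_distance,
        )


@dataclass(frozen=True)
class ValidateConfig:
    min_identity: float = 0.90
    min_coverage: float = 0.80
    min_aln_len: int = 300
    flank_len: int = 1000
    concordance_tol: int = 2000

    def params(self) -> ValidationParams:
        return ValidationParams(
            min_identity=self.min_identity,
            min_coverage=self.min_coverage,
            min_aln_len=self.min_aln_len,
            flank_len=self.flank_len,
            concordance_tol=self.concordance_tol,
        )


@dataclass(frozen=True)
class PipelineConfig:
    triage: TriageConfig = TriageConfig()
    assembly: AssemblyConfig = AssemblyConfig()
    filter: FilterConfig = FilterConfig()
    dedup: DedupConfig = DedupConfig()
    anchor: AnchorConfig = AnchorConfig()
    validate: ValidateConfig = ValidateConfig()
    simulate: SimConfig = SimConfig()

    _BLOCKS = {
        "triage": TriageConfig,
        "assembly": AssemblyConfig,
        "filter": FilterConfig,
        "dedup": DedupConfig,
        "anchor": AnchorConfig,
        "validate": ValidateConfig,
        "simulate": SimConfig,
    }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        kwargs = {}
        for key, block in data.items():
            if key not in cls._BLOCKS:
                raise ValueError(f"unknown config section {key!r}")
            block_cls = cls._BLOCKS[key]
            names = {f.name for f in dataclasses.fields(block_cls)}
            for k in block:
                if k not in names:
                    raise ValueError(f"unknown config key {key}.{k}")
            block = dict(block)
            for k, v in block.items():
                if isinstance(v, list):
                    block[k] = tuple(v)
            kwargs[key] = block_cls(**block)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_panref(
    reference: Sequence[SequenceRecord], contigs: Sequence[SequenceRecord]
) -> list[SequenceRecord]:
    """Concatenate reference chromosomes and non-redundant contigs.

    Errors out on any name collision, since anchoring distinguishes
    chromosome targets from contig targets purely by name.
    """
    names = [r.id for r in reference] + [c.id for c in contigs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"panreference name collision: {sorted(dupes)}")
    return list(reference) + list(contigs)


# ---------------------------------------------------------------------------
# Simulation-mode end-to-end run
# ---------------------------------------------------------------------------

@dataclass
class SimRunResult:
    config: PipelineConfig
    reference: list[SequenceRecord]
    donor_set: DonorSet
    contigs_by_sample: dict[str, list[SequenceRecord]]
    nonredundant: list[SequenceRecord]
    provenance: ContigProvenance
    placements: list[Placement]
    report: dict[str, Any]


def run_simulation(
    config: PipelineConfig,
    workdir,
    write_outputs: bool = True,
) -> SimRunResult:
    """Simulate a pangenome and run the whole pipeline against it.

    All intermediate files (FASTQ, SAM, FASTA) are written under ``workdir``
    so every stage exercises its real file interface.  The report carries
    per-stage counts plus truth-based recovery metrics.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    rng_root = np.random.default_rng(sim.seed)
    ref_rng, donor_rng = rng_root.spawn(2)

    reference = simulate_reference(sim, ref_rng)
    donor_set = simulate_donors(reference, sim, donor_rng)
    pio.write_fasta(reference, workdir / "reference.fa")
    write_truth_csv(donor_set.truth, workdir / "truth.csv")

    mode = TriageMode(config.triage.mode)
    asm_params = config.assembly.params()
    report: dict[str, Any] = {"config_hash": config.config_hash(), "samples": {}}

    reads_by_sample = {}
    contigs_by_sample: dict[str, list[SequenceRecord]] = {}
    all_kept: list[SequenceRecord] = []
    for i, sample in enumerate(sorted(donor_set.donors)):
        read_rng = rng_root.spawn(1)[0]
        pairs = simulate_reads(donor_set.donors[sample], sim, read_rng, sample)
        reads_by_sample[sample] = pairs
        sam_path = truth_aligner(pairs, reference, donor_set, workdir / f"{sample}.ref.sam")
        reader = pio.stream_pair_alignments(sam_path)
        selected, triage_summary = extract_left_behind(iter(reader), mode)
        fastq_reads = [r for pair in selected for r in pair]
        pio.write_fastq((r.as_fastq() for r in fastq_reads), workdir / f"{sample}.leftbehind.fastq")
        if config.assembly.unmapped_reads_only:
            asm_input = [r.seq for r in fastq_reads if r.was_unmapped]
        else:
            asm_input = [r.seq for r in fastq_reads]
        contigs = build_unitigs(asm_input, asm_params, sample=sample)
        kept, filt_report = filter_cascade(contigs, min_len=config.filter.min_len)
        contigs_by_sample[sample] = kept
        all_kept.extend(kept)
        stats = assembly_stats([len(c) for c in kept]) if kept else None
        report["samples"][sample] = {
            "n_pairs": triage_summary.total_pairs,
            "n_selected_pairs": triage_summary.selected_pairs,
            "selected_fraction": triage_summary.selected_fraction,
            "n_contigs_raw": len(contigs),
            "n_contigs_kept": filt_report.kept_count,
            "assembled_bases": sum(len(c) for c in kept),
            "n50": stats.n50 if stats else 0,
        }

    clusters = cluster_greedy(all_kept, config.dedup.min_identity, config.dedup.min_len_ratio)
    reps = representatives(clusters, all_kept)
    cstats = cluster_stats(clusters)
    report["dedup"] = {
        "n_input": len(all_kept),
        "n_clusters": cstats.n_clusters,
        "singleton_fraction": cstats.singleton_fraction,
    }
    if write_outputs:
        pio.write_fasta(reps, workdir / "nonredundant.fa")

    panref = build_panref(reference, reps)
    pio.write_fasta(panref, workdir / "panreference.fa")
    provenance = locate_contigs(reps, donor_set)

    contig_lengths = {c.id: len(c.seq) for c in reps}
    chrom_names = {r.id for r in reference}
    anchor_params = config.anchor.params()

    def _pooled_pairs():
        for sample in sorted(reads_by_sample):
            sam = truth_panref_aligner(
                reads_by_sample[sample], reference, reps, donor_set, provenance,
                workdir / f"{sample}.panref.sam",
            )
            yield from pio.stream_pair_alignments(sam)

    placements = anchor(_pooled_pairs(), contig_lengths, chrom_names, anchor_params)
    summary = anchoring_summary(placements)
    report["anchoring"] = summary
    if write_outputs:
        pio.write_placements_csv(placements, workdir / "placements.csv")
        pio.write_placements_bed(placements, workdir / "placements.bed")

    # truth-based scoring
    val_params = config.validate.params()
    hits = refined_assembly_hits(reps, donor_set, provenance)
    val_records, validated_fraction = validate_contigs(hits, contig_lengths, val_params)
    flanks = truth_flank_hits(reps, donor_set, provenance, val_params.flank_len)
    conc_records, flank_accuracy = flank_concordance(placements, flanks, val_params)
    coverage = novel_segment_coverage(provenance, donor_set.novel_segments)
    recovery = evaluate_anchoring(placements, donor_set, provenance)
    report["validation"] = {
        "validated_fraction": validated_fraction,
        "flank_accuracy": flank_accuracy,
        "n_flank_evaluable": sum(1 for r in conc_records if r.evaluable),
    }
    report["recovery"] = recovery
    report["recovery"]["novel_segment_mean_coverage"] = (
        sum(coverage.values()) / len(coverage) if coverage else 0.0
    )
    if write_outputs:
        with open(workdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=list)
    return SimRunResult(
        config=config,
        reference=reference,
        donor_set=donor_set,
        contigs_by_sample=contigs_by_sample,
        nonredundant=reps,
        provenance=provenance,
        placements=placements,
        report=report,
    )


def evaluate_anchoring(
    placements: Sequence[Placement],
    donor_set: DonorSet,
    provenance: ContigProvenance,
    tolerance: int = 2000,
) -> dict[str, Any]:
    """Score unique placements against the planted insertion positions.

    A representative counts as recovered when it is uniquely placed and its
    locus lies within ``tolerance`` of the true reference insertion point of
    the novel segment it derives from.  The denominator is all non-redundant
    representatives.
    """
    true_pos = {t.novel_seq_id: (t.chrom, t.ref_pos) for t in donor_set.truth}
    contig_novel: dict[str, str] = {}
    contig_novel_span: dict[str, int] = {}
    for nid, entries in provenance.novel_entries.items():
        for contig_id, ns_start, ns_end, _, _ in entries:
            cur = contig_novel.get(contig_id)
            if cur is None or (ns_end - ns_start) > contig_novel_span.get(contig_id, -1):
                contig_novel[contig_id] = nid
                contig_novel_span[contig_id] = ns_end - ns_start
    n_total = len(placements)
    n_unique = 0
    n_recovered = 0
    for p in placements:
        if p.status != "unique":
            continue
        n_unique += 1
        nid = contig_novel.get(p.contig_id)
        if nid is None or nid not in true_pos:
            continue
        chrom, pos = true_pos[nid]
        locus = p.loci[0]
        if locus.chrom != chrom:
            continue
        dist = max(0, locus.start - pos, pos - locus.end)
        if dist <= tolerance:
            n_recovered += 1
    return {
        "n_representatives": n_total,
        "n_unique": n_unique,
        "n_unique_within_tol": n_recovered,
        "unique_recovery_fraction": n_recovered / n_total if n_total else 0.0,
    }
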