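"""Contig filtering cascade: minimum length, vector screen, taxonomic screen.

The cascade order is fixed (length -> vector -> taxon/organelle) and each
stage is a pure filter, so the cascade is idempotent and the report counts
reconcile exactly.  The taxonomic stage removes contigs only on positive
evidence: a best database hit outside the allowed taxa or on an organelle
target.  Contigs with no hits at all are kept — absence of a hit is not
evidence of alien origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .align import ungapped_local_match
from .records import AlignmentHit, SequenceRecord, revcomp


@dataclass
class FilterReport:
    input_count: int = 0
    removed_short: int = 0
    removed_vector: int = 0
    removed_taxon: int = 0
    removed_organelle: int = 0
    kept_count: int = 0

    def check(self) -> None:
        removed = (
            self.removed_short + self.removed_vector + self.removed_taxon + self.removed_organelle
        )
        assert self.kept_count == self.input_count - removed, "filter report does not reconcile"


def filter_by_length(
    contigs: Sequence[SequenceRecord], min_len: int = 300
) -> list[SequenceRecord]:
    """Keep contigs of length >= min_len (a 299 bp contig goes, 300 bp stays)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [c for c in contigs if len(c) >= min_len]


def screen_vectors(
    contigs: Sequence[SequenceRecord],
    vector_db: Sequence[SequenceRecord],
    min_identity: float = 0.9,
    min_match_len: int = 30,
) -> tuple[list[SequenceRecord], list[str]]:
    """Remove contigs with a local vector/adapter match.

    A contig is flagged when any vector sequence (either strand) has an
    ungapped local match of >= min_match_len bases at >= min_identity.
    Returns (kept, flagged_ids).  An empty vector database keeps everything.
    """
    kept, flagged = [], []
    vectors = [(v.seq, revcomp(v.seq)) for v in vector_db]
    for c in contigs:
        hit = any(
            ungapped_local_match(strand, c.seq, min_identity, min_match_len)
            for fwd, rev in vectors
            for strand in (fwd, rev)
        )
        (flagged if hit else kept).append(c.id if hit else c)
    return kept, flagged


def best_hits(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Best hit per query: maximal bitscore, ties by identity then target id."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        score = h.bitscore if h.bitscore is not None else h.identity * h.aligned_len
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        cur_score = cur.bitscore if cur.bitscore is not None else cur.identity * cur.aligned_len
        # ties broken by identity, then toward the lexicographically first target
        if (score, h.identity) > (cur_score, cur.identity) or (
            (score, h.identity) == (cur_score, cur.identity) and h.target_id < cur.target_id
        ):
            best[h.query_id] = h
    return best


def taxonomic_filter(
    contigs: Sequence[SequenceRecord],
    hits: Sequence[AlignmentHit],
    taxa: Mapping[str, str],
    allowed_taxa: set[str],
    organelle_targets: set[str] = frozenset(),
) -> tuple[list[SequenceRecord], list[str], list[str]]:
    """Remove contigs whose best hit is outside ``allowed_taxa`` or organellar.

    ``taxa`` maps target_id -> taxon label (pre-resolved strings, no taxonomy
    tree).  Returns (kept, removed_taxon_ids, removed_organelle_ids).
    """
    known = {c.id for c in contigs}
    for h in hits:
        if h.query_id not in known:
            raise ValueError(f"hit references unknown contig {h.query_id!r}")
    best = best_hits(hits)
    kept, removed_taxon, removed_organelle = [], [], []
    for c in contigs:
        h = best.get(c.id)
        if h is None:
            kept.append(c)
        elif h.target_id in organelle_targets:
            removed_organelle.append(c.id)
        elif taxa.get(h.target_id) not in allowed_taxa:
            removed_taxon.append(c.id)
        else:
            kept.append(c)
    return kept, removed_taxon, removed_organelle


def filter_cascade(
    contigs: Sequence[SequenceRecord],
    min_len: int = 300,
    vector_db: Sequence[SequenceRecord] = (),
    hits: Sequence[AlignmentHit] = (),
    taxa: Optional[Mapping[str, str]] = None,
    allowed_taxa: Optional[set[str]] = None,
    organelle_targets: set[str] = frozenset(),
    min_vector_identity: float = 0.9,
    min_vector_match_len: int = 30,
) -> tuple[list[SequenceRecord], FilterReport]:
    """Run the full cascade and return (kept contigs, reconciled report)."""
    report = FilterReport(input_count=len(contigs))
    stage = filter_by_length(contigs, min_len)
    report.removed_short = len(contigs) - len(stage)
    if vector_db:
        stage, flagged = screen_vectors(stage, vector_db, min_vector_identity, min_vector_match_len)
        report.removed_vector = len(flagged)
    if hits and allowed_taxa is not None:
        # restrict hits to contigs still alive so stage order is honoured
        alive = {c.id for c in stage}
        stage_hits = [h for h in hits if h.query_id in alive]
        stage, rm_tax, rm_org = taxonomic_filter(
            stage, stage_hits, taxa or {}, allowed_taxa, organelle_targets
        )
        report.removed_taxon = len(rm_tax)
        report.removed_organelle = len(rm_org)
    report.kept_count = len(stage)
    report.check()
    return stage, report
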