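"""Validation of contigs and placements against an independent assembly.

Contig validation filters contig-vs-assembly alignments (nucmer coords or
PAF style) at identity/length gates and asks whether the surviving hits
cover enough of the contig.  Coverage is the union of surviving hit
query-intervals by default — the cumulative reading of "coverage of the
contig" — with a single-best-hit mode available.

Flank concordance validates *placements*: sequence flanking the contig in the
independent assembly is realigned to the reference, and the placement is
concordant when the flank's best hit lands on the same chromosome within a
tolerance of the called locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .anchoring import Placement
from .records import AlignmentHit


@dataclass(frozen=True)
class ValidationParams:
    min_identity: float = 0.90
    min_coverage: float = 0.80
    min_aln_len: int = 300
    flank_len: int = 1000
    concordance_tol: int = 2000
    coverage_mode: str = "union"  # or "best"

    def __post_init__(self):
        if not (0 < self.min_identity <= 1 and 0 < self.min_coverage <= 1):
            raise ValueError("identity/coverage fractions must lie in (0, 1]")
        if min(self.min_aln_len, self.flank_len, self.concordance_tol) <= 0:
            raise ValueError("length parameters must be positive")
        if self.coverage_mode not in ("union", "best"):
            raise ValueError("coverage_mode must be 'union' or 'best'")


@dataclass(frozen=True)
class ValidationRecord:
    contig_id: str
    validated: bool
    best_target: Optional[str]
    covered_fraction: float
    identity_of_best: float


def _union_len(intervals: Sequence[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def validate_contigs(
    hits: Sequence[AlignmentHit],
    contig_lengths: Mapping[str, int],
    params: ValidationParams = ValidationParams(),
) -> tuple[list[ValidationRecord], float]:
    """Gate hits and score per-contig coverage; returns records + validated fraction.

    Hits below min_identity or shorter than min_aln_len are discarded;
    coverage is then the union (or best single hit) of surviving query
    intervals over the contig length.  Every contig in ``contig_lengths``
    is scored; no surviving hit means coverage 0.
    """
    surviving: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        L = contig_lengths.get(h.query_id)
        if L is None:
            raise ValueError(f"hit references unknown contig {h.query_id!r}")
        if h.q_end > L:
            raise ValueError(f"hit interval exceeds contig length for {h.query_id!r}")
        if h.identity < params.min_identity or h.aligned_len < params.min_aln_len:
            continue
        surviving.setdefault(h.query_id, []).append(h)
    records = []
    n_validated = 0
    for contig_id in sorted(contig_lengths):
        L = contig_lengths[contig_id]
        hs = surviving.get(contig_id, [])
        if not hs:
            records.append(ValidationRecord(contig_id, False, None, 0.0, 0.0))
            continue
        best = max(hs, key=lambda h: (h.q_end - h.q_start, h.identity))
        if params.coverage_mode == "union":
            covered = _union_len([(h.q_start, h.q_end) for h in hs]) / L
        else:
            covered = (best.q_end - best.q_start) / L
        ok = covered >= params.min_coverage
        n_validated += ok
        records.append(ValidationRecord(contig_id, ok, best.target_id, covered, best.identity))
    fraction = n_validated / len(contig_lengths) if contig_lengths else 0.0
    return records, fraction


@dataclass(frozen=True)
class ConcordanceRecord:
    contig_id: str
    evaluable: bool
    concordant: bool
    flank_chrom: Optional[str] = None
    flank_pos: Optional[int] = None
    distance: Optional[int] = None


def flank_concordance(
    placements: Sequence[Placement],
    flank_hits: Sequence[AlignmentHit],
    params: ValidationParams = ValidationParams(),
) -> tuple[list[ConcordanceRecord], float]:
    """Check placed contigs against realigned flanking sequence.

    ``flank_hits`` align flanks (query_id = contig id the flank surrounds)
    back to the reference; the best hit per contig is compared with the
    contig's placement locus.  Concordant iff same chromosome and the hit
    start lies within ``concordance_tol`` of a locus boundary.  Placements
    without any flank hit are non-evaluable and excluded from the accuracy
    denominator; only UNIQUE placements are evaluated.
    """
    best: dict[str, AlignmentHit] = {}
    for h in flank_hits:
        cur = best.get(h.query_id)
        score = (h.identity * h.aligned_len, h.identity)
        if cur is None or score > (cur.identity * cur.aligned_len, cur.identity):
            best[h.query_id] = h
    records = []
    n_conc = n_eval = 0
    for p in placements:
        if p.status != "unique":
            continue
        h = best.get(p.contig_id)
        if h is None:
            records.append(ConcordanceRecord(p.contig_id, evaluable=False, concordant=False))
            continue
        locus = p.loci[0]
        dist = max(0, max(locus.start, h.t_start) - min(locus.end, h.t_start))
        same_chrom = h.target_id == locus.chrom
        ok = same_chrom and dist <= params.concordance_tol
        n_eval += 1
        n_conc += ok
        records.append(
            ConcordanceRecord(
                p.contig_id,
                evaluable=True,
                concordant=ok,
                flank_chrom=h.target_id,
                flank_pos=h.t_start,
                distance=dist if same_chrom else None,
            )
        )
    return records, (n_conc / n_eval if n_eval else 0.0)
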