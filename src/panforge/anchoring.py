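"""Anchoring assembled contigs onto reference chromosomes with mate pairs.

After contigs join the reference in a concatenated panreference and reads are
remapped, a read pair whose two mates land on a contig and on a chromosome is
evidence that the contig belongs near the mate's chromosomal position.  A
contig end is anchored at a locus when

* the contig-side read aligns within the first or last ``end_window`` bases
  of the contig with mapping quality >= ``min_mapq``, the mate on a
  chromosome,
* at least ``min_support`` such mates fall on one chromosome, and
* those mate positions all lie within a span strictly shorter than
  ``max_span``.

Loci are discovered by a sliding window over sorted mate positions: every
maximal run with span < max_span and >= min_support members qualifies, and
overlapping qualifying runs merge into one locus reported as
[min position, max position].  Loci called from the two ends of a contig on
the same chromosome merge into a single placement when they lie within
``merge_distance`` of each other (mates from opposite contig ends flank the
insertion site by at most insert-size-scale distances, bounded here by
contig length + 2 * max_span).  A contig is then UNIQUE (one locus),
MULTIPLE (several) or UNPLACED (none).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .records import PairAlignmentRecord

FIRST = "first"
LAST = "last"

UNIQUE = "unique"
MULTIPLE = "multiple"
UNPLACED = "unplaced"


@dataclass(frozen=True)
class AnchorParams:
    end_window: int = 300
    min_support: int = 10
    min_mapq: int = 10
    max_span: int = 2000
    merge_distance: Optional[int] = None  # default: contig length + 2 * max_span
    mapq_on_both_mates: bool = False
    include_secondary: bool = False

    def __post_init__(self):
        if min(self.end_window, self.min_support, self.max_span) <= 0 or self.min_mapq < 0:
            raise ValueError("anchoring parameters must be positive")

    def merge_distance_for(self, contig_len: int) -> int:
        return self.merge_distance if self.merge_distance is not None else contig_len + 2 * self.max_span


@dataclass
class AnchorEvidence:
    """Bridging-mate evidence for one (contig, contig end, chromosome)."""

    contig_id: str
    contig_end: str  # FIRST or LAST
    chrom: str
    mate_positions: list[int] = field(default_factory=list)
    mapqs: list[int] = field(default_factory=list)

    def sort(self) -> None:
        order = sorted(range(len(self.mate_positions)), key=self.mate_positions.__getitem__)
        self.mate_positions = [self.mate_positions[i] for i in order]
        self.mapqs = [self.mapqs[i] for i in order]

    @property
    def span(self) -> int:
        return self.mate_positions[-1] - self.mate_positions[0] if self.mate_positions else 0


@dataclass(frozen=True)
class Locus:
    chrom: str
    start: int
    end: int
    n_support: int
    ends_supporting: frozenset[str] = frozenset((FIRST,))
    # contig orientation, known only when both ends anchor: '+' when the
    # FIRST-end mate cloud lies left of the LAST-end cloud
    orientation: Optional[str] = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("locus start > end")


@dataclass
class Placement:
    contig_id: str
    status: str
    loci: list[Locus]

    def __post_init__(self):
        expected = UNPLACED if not self.loci else (UNIQUE if len(self.loci) == 1 else MULTIPLE)
        if self.status != expected:
            raise ValueError(f"status {self.status} inconsistent with {len(self.loci)} loci")


def preselect_bridging_pairs(
    pairs: Iterable[tuple[PairAlignmentRecord, PairAlignmentRecord]],
    contig_lengths: Mapping[str, int],
    chrom_names: set[str],
    params: AnchorParams = AnchorParams(),
) -> dict[tuple[str, str, str], AnchorEvidence]:
    """Collect bridging read pairs, grouped by (contig, contig end, chromosome).

    A pair qualifies when one mate aligns in a terminal window of a contig at
    MAPQ >= min_mapq and the other mate aligns on a chromosome.  A contig
    shorter than 2*end_window can place one read in both windows; it then
    counts once per end, but a single pair never counts twice at one end.
    """
    groups: dict[tuple[str, str, str], AnchorEvidence] = {}
    for r1, r2 in pairs:
        for contig_side, chrom_side in ((r1, r2), (r2, r1)):
            if contig_side.is_unmapped or chrom_side.is_unmapped:
                continue
            if not params.include_secondary and (
                contig_side.flags.is_secondary_or_supplementary
                or chrom_side.flags.is_secondary_or_supplementary
            ):
                continue
            L = contig_lengths.get(contig_side.target)
            if L is None:
                if contig_side.target not in chrom_names:
                    raise ValueError(f"unknown alignment target {contig_side.target!r}")
                continue
            if chrom_side.target not in chrom_names:
                if chrom_side.target not in contig_lengths:
                    raise ValueError(f"unknown alignment target {chrom_side.target!r}")
                continue
            if contig_side.mapq < params.min_mapq:
                continue
            if params.mapq_on_both_mates and chrom_side.mapq < params.min_mapq:
                continue
            ends = []
            if contig_side.pos < params.end_window:
                ends.append(FIRST)
            if contig_side.aln_end > L - params.end_window:
                ends.append(LAST)
            for end in ends:
                key = (contig_side.target, end, chrom_side.target)
                ev = groups.get(key)
                if ev is None:
                    ev = groups[key] = AnchorEvidence(
                        contig_id=contig_side.target, contig_end=end, chrom=chrom_side.target
                    )
                ev.mate_positions.append(chrom_side.pos)
                ev.mapqs.append(chrom_side.mapq)
    for ev in groups.values():
        ev.sort()
    return groups


def call_loci(evidence: AnchorEvidence, params: AnchorParams = AnchorParams()) -> list[Locus]:
    """Valid loci for one (contig, end, chromosome) evidence group.

    Sliding window over sorted mate positions: each maximal run with span
    strictly below max_span qualifies if it holds >= min_support positions;
    overlapping qualifying runs merge.  Deterministic and oracle-checkable by
    brute-force window enumeration.
    """
    pos = evidence.mate_positions
    n = len(pos)
    if n < params.min_support:
        return []
    # j_max[i] = last index j with pos[j] - pos[i] < max_span (two pointers)
    j_max = [0] * n
    j = 0
    for i in range(n):
        j = max(j, i)
        while j + 1 < n and pos[j + 1] - pos[i] < params.max_span:
            j += 1
        j_max[i] = j
    windows = []
    for i in range(n):
        if i > 0 and j_max[i - 1] == j_max[i]:
            continue  # contained in the window starting at i-1
        if j_max[i] - i + 1 >= params.min_support:
            windows.append((i, j_max[i]))
    merged: list[list[int]] = []
    for i, j in windows:
        if merged and i <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], j)
        else:
            merged.append([i, j])
    return [
        Locus(
            chrom=evidence.chrom,
            start=pos[i],
            end=pos[j],
            n_support=j - i + 1,
            ends_supporting=frozenset((evidence.contig_end,)),
        )
        for i, j in merged
    ]


def _interval_gap(a: Locus, b: Locus) -> int:
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def call_placements(
    loci_by_contig: Mapping[str, Sequence[Locus]],
    contig_lengths: Mapping[str, int],
    params: AnchorParams = AnchorParams(),
) -> list[Placement]:
    """Merge two-end loci and call a placement status per contig.

    Every contig in ``contig_lengths`` receives a Placement (UNPLACED when it
    has no valid locus), so statuses always partition the contig set.  A
    FIRST-end locus and a LAST-end locus on the same chromosome merge when
    their gap is at most the merge distance; each locus merges at most once,
    nearest pairs first.  Loci are reported sorted by (chrom, start).
    """
    placements = []
    for contig_id in sorted(contig_lengths):
        loci = list(loci_by_contig.get(contig_id, ()))
        merge_dist = params.merge_distance_for(contig_lengths[contig_id])
        firsts = [l for l in loci if l.ends_supporting == frozenset((FIRST,))]
        lasts = [l for l in loci if l.ends_supporting == frozenset((LAST,))]
        pairs = sorted(
            (
                (_interval_gap(f, l), fi, li)
                for fi, f in enumerate(firsts)
                for li, l in enumerate(lasts)
                if f.chrom == l.chrom and _interval_gap(f, l) <= merge_dist
            )
        )
        used_f: set[int] = set()
        used_l: set[int] = set()
        merged: list[Locus] = []
        for _, fi, li in pairs:
            if fi in used_f or li in used_l:
                continue
            used_f.add(fi)
            used_l.add(li)
            f, l = firsts[fi], lasts[li]
            merged.append(
                Locus(
                    chrom=f.chrom,
                    start=min(f.start, l.start),
                    end=max(f.end, l.end),
                    n_support=f.n_support + l.n_support,
                    ends_supporting=frozenset((FIRST, LAST)),
                    orientation="+" if (f.start, f.end) <= (l.start, l.end) else "-",
                )
            )
        merged.extend(f for fi, f in enumerate(firsts) if fi not in used_f)
        merged.extend(l for li, l in enumerate(lasts) if li not in used_l)
        merged.sort(key=lambda l: (l.chrom, l.start, l.end))
        status = UNPLACED if not merged else (UNIQUE if len(merged) == 1 else MULTIPLE)
        placements.append(Placement(contig_id=contig_id, status=status, loci=merged))
    return placements


def anchor(
    pairs: Iterable[tuple[PairAlignmentRecord, PairAlignmentRecord]],
    contig_lengths: Mapping[str, int],
    chrom_names: set[str],
    params: AnchorParams = AnchorParams(),
) -> list[Placement]:
    """Full anchoring pass: preselect bridging pairs, call loci, call placements."""
    groups = preselect_bridging_pairs(pairs, contig_lengths, chrom_names, params)
    loci_by_contig: dict[str, list[Locus]] = defaultdict(list)
    for ev in groups.values():
        loci_by_contig[ev.contig_id].extend(call_loci(ev, params))
    return call_placements(loci_by_contig, contig_lengths, params)


def anchoring_summary(placements: Sequence[Placement]) -> dict[str, float]:
    """Counts and fractions per placement status (fractions sum to 1)."""
    n = len(placements)
    counts = {UNIQUE: 0, MULTIPLE: 0, UNPLACED: 0}
    for p in placements:
        counts[p.status] += 1
    out: dict[str, float] = {"n_contigs": n}
    for status, c in counts.items():
        out[f"n_{status}"] = c
        out[f"fraction_{status}"] = c / n if n else 0.0
    return out
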