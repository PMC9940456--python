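"""Selection of "left-behind" read pairs from alignments to the reference.

The classic extraction is ``samtools view -F 2``: keep every record lacking
the properly-paired bit.  That recruits pairs where both mates failed to map,
pairs with one unmapped mate, and discordant-but-mapped pairs — the latter are
exactly the breakpoint-spanning pairs that let assembly walk from reference
flank into novel sequence.  Stricter alternatives (both or either mate
unmapped) are exposed as modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .records import PairAlignmentRecord

Pair = tuple[PairAlignmentRecord, PairAlignmentRecord]


class TriageMode(str, Enum):
    NOT_PROPER_PAIR = "not-proper-pair"  # samtools view -F 2 semantics
    BOTH_UNMAPPED = "both-unmapped"
    EITHER_UNMAPPED = "either-unmapped"


@dataclass
class TriageSummary:
    total_pairs: int = 0
    selected_pairs: int = 0

    @property
    def selected_fraction(self) -> float:
        return self.selected_pairs / self.total_pairs if self.total_pairs else 0.0


@dataclass(frozen=True)
class TriagedRead:
    """A FASTQ-ready read from a selected pair, in sequencing orientation."""

    name: str
    seq: str
    qual: Optional[str]
    was_unmapped: bool

    def as_fastq(self) -> tuple[str, str, Optional[str]]:
        return (self.name, self.seq, self.qual)


def select_pair(pair: Pair, mode: TriageMode) -> bool:
    """Decide whether a read pair is left behind by reference mapping.

    Pure predicate over the two mates' flags; both records must be primary.
    """
    r1, r2 = pair
    for r in pair:
        if r.flags.is_secondary_or_supplementary:
            raise ValueError(f"triage requires primary records (read {r.read_id})")
    if mode is TriageMode.NOT_PROPER_PAIR:
        return not (r1.flags.is_proper_pair and r2.flags.is_proper_pair)
    if mode is TriageMode.BOTH_UNMAPPED:
        return r1.is_unmapped and r2.is_unmapped
    if mode is TriageMode.EITHER_UNMAPPED:
        return r1.is_unmapped or r2.is_unmapped
    raise ValueError(f"unknown triage mode {mode!r}")


def extract_left_behind(
    pairs: Iterable[Pair],
    mode: TriageMode = TriageMode.NOT_PROPER_PAIR,
) -> tuple[list[tuple[TriagedRead, TriagedRead]], TriageSummary]:
    """Select left-behind pairs and return FASTQ-ready read pairs.

    Reads aligned on the reverse strand are reverse-complemented back to
    sequencing orientation (SAM stores the aligned-strand sequence), so the
    assembler sees reads exactly as they came off the machine.  Each read
    remembers whether it was itself unmapped, letting downstream stages
    assemble only the truly unmapped sequence while still emitting complete
    pairs for pair-aware external assemblers.
    """
    out = []
    summary = TriageSummary()
    for pair in pairs:
        summary.total_pairs += 1
        if not select_pair(pair, mode):
            continue
        summary.selected_pairs += 1
        out.append(
            tuple(
                TriagedRead(r.read_id, r.original_seq(), r.original_qual(), r.is_unmapped)
                for r in pair
            )
        )
    return out, summary
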