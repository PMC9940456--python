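"""Shared record types for sequences, alignments and alignment hits.

Coordinate convention: everything in memory is 0-based, half-open.
1-based conversions happen only at SAM ingestion (handled by pysam) and at
CSV export, never in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Sentinel target name for unmapped records.
UNMAPPED = "*"

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N, case kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, optionally tagged with its sample of origin."""

    id: str
    seq: str
    sample: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return replace(self, seq=revcomp(self.seq))


@dataclass(frozen=True)
class SamFlags:
    """Decoded SAM flag booleans relevant to pairing and triage."""

    is_paired: bool
    is_proper_pair: bool
    is_unmapped: bool
    mate_unmapped: bool
    is_reverse: bool
    is_secondary_or_supplementary: bool


def decode_flags(flag: int) -> SamFlags:
    """Decode an integer SAM FLAG field into the booleans the pipeline uses."""
    return SamFlags(
        is_paired=bool(flag & FLAG_PAIRED),
        is_proper_pair=bool(flag & FLAG_PROPER_PAIR),
        is_unmapped=bool(flag & FLAG_UNMAPPED),
        mate_unmapped=bool(flag & FLAG_MATE_UNMAPPED),
        is_reverse=bool(flag & FLAG_REVERSE),
        is_secondary_or_supplementary=bool(flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY)),
    )


@dataclass
class PairAlignmentRecord:
    """One read of a pair as aligned (or not) to a target sequence.

    ``pos``/``aln_end`` are the 0-based half-open alignment interval on the
    target; both are None for unmapped reads, as is ``mapq``.  ``seq`` is the
    sequence as stored in the SAM record, i.e. on the aligned strand; use
    :meth:`original_seq` to recover the sequence as it came off the sequencer.
    """

    read_id: str
    mate_index: int  # 1 or 2
    target: str = UNMAPPED
    pos: Optional[int] = None
    aln_end: Optional[int] = None
    mapq: Optional[int] = None
    flags: SamFlags = field(
        default_factory=lambda: decode_flags(FLAG_PAIRED | FLAG_UNMAPPED | FLAG_MATE_UNMAPPED)
    )
    seq: Optional[str] = None
    qual: Optional[str] = None

    def __post_init__(self):
        if self.mate_index not in (1, 2):
            raise ValueError(f"mate_index must be 1 or 2, got {self.mate_index}")
        if self.flags.is_unmapped:
            if self.pos is not None or self.mapq is not None:
                raise ValueError(f"unmapped record {self.read_id} carries pos/mapq")
        else:
            if self.pos is None or self.mapq is None:
                raise ValueError(f"mapped record {self.read_id} lacks pos/mapq")

    @property
    def is_unmapped(self) -> bool:
        return self.flags.is_unmapped

    def original_seq(self) -> str:
        """Read sequence in sequencing orientation (undo aligned-strand storage)."""
        if self.seq is None:
            raise ValueError(f"record {self.read_id} carries no sequence")
        return revcomp(self.seq) if (not self.is_unmapped and self.flags.is_reverse) else self.seq

    def original_qual(self) -> Optional[str]:
        if self.qual is None:
            return None
        return self.qual[::-1] if (not self.is_unmapped and self.flags.is_reverse) else self.qual


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment row (BLAST outfmt-6 / PAF / show-coords style).

    Intervals are 0-based half-open on query and target; identity is a
    fraction in [0, 1].
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    identity: float
    aligned_len: int
    strand: str = "+"
    bitscore: Optional[float] = None

    def __post_init__(self):
        if not (self.q_end > self.q_start and self.t_end > self.t_start):
            raise ValueError(f"degenerate hit interval for {self.query_id}->{self.target_id}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0,1]")
        if self.aligned_len < max(self.q_end - self.q_start, self.t_end - self.t_start):
            raise ValueError("aligned_len shorter than alignment span")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
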