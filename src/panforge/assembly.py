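"""Minimal de Bruijn unitig assembler and assembly statistics.

The assembler counts canonical k-mers (a k-mer and its reverse complement are
the same object; k must be odd so no k-mer is its own reverse complement),
drops k-mers below a count threshold, and emits every maximal non-branching
path of the resulting graph as a contig.  There is no bubble popping, no
paired-end scaffolding and no gap filling: a sequencing-error k-mer that
survives the count threshold breaks the unitig at the branch point.  The
count threshold is therefore the only error control; 1 is appropriate for
error-free reads, and for error-bearing reads it should scale with depth
(roughly depth/10).

k-mer size selection follows the common grid-search recipe: assemble at each
k, keep contigs above the length floor, and rank the grid lexicographically
by (N50 descending, contig count ascending, L50 ascending).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import SequenceRecord, revcomp

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class AssemblyParams:
    k: int = 63
    min_kmer_count: int = 2
    min_contig_len: int = 300

    def __post_init__(self):
        if not (15 <= self.k <= 127) or self.k % 2 == 0:
            raise ValueError(f"k must be odd and in [15, 127], got {self.k}")
        if self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1")


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_len: int
    n50: int
    l50: int
    max_len: int
    mean_len: float


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def count_kmers(reads: Iterable[str], k: int) -> dict[str, int]:
    """Count canonical k-mers across reads; k-mers containing non-ACGT are skipped."""
    counts: dict[str, int] = {}
    for seq in reads:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if not _VALID.issuperset(kmer):
                continue
            c = canonical(kmer)
            counts[c] = counts.get(c, 0) + 1
    return counts


def _extensions(kmers: set[str], node: str, forward: bool) -> list[str]:
    """Oriented successor (forward) or predecessor (backward) k-mers present in the graph."""
    out = []
    if forward:
        stem = node[1:]
        for b in "ACGT":
            cand = stem + b
            if canonical(cand) in kmers:
                out.append(cand)
    else:
        stem = node[:-1]
        for b in "ACGT":
            cand = b + stem
            if canonical(cand) in kmers:
                out.append(cand)
    return out


def _walk(kmers: set[str], start: str, forward: bool) -> list[str]:
    """Extend from an oriented k-mer along the unique non-branching path."""
    path = []
    cur = start
    seen = {canonical(start)}
    while True:
        nxt_list = _extensions(kmers, cur, forward)
        if len(nxt_list) != 1:
            break
        nxt = nxt_list[0]
        # the next node must also have a unique link back, or it is a junction
        if len(_extensions(kmers, nxt, not forward)) != 1:
            break
        c = canonical(nxt)
        if c in seen:  # cycle guard
            break
        seen.add(c)
        path.append(nxt)
        cur = nxt
    return path


def build_unitigs(
    reads: Iterable[str | SequenceRecord],
    params: AssemblyParams,
    sample: str | None = None,
) -> list[SequenceRecord]:
    """Assemble reads into unitigs (maximal non-branching dBG paths).

    Output is deterministic: contigs are emitted in canonical orientation
    (lexicographically smaller of the two strands) and sorted by sequence.
    Contigs shorter than ``min_contig_len`` are NOT removed here — length
    filtering is a separate, explicit stage.
    """
    seqs = [r.seq if isinstance(r, SequenceRecord) else r for r in reads]
    counts = count_kmers(seqs, params.k)
    kmers = {km for km, c in counts.items() if c >= params.min_kmer_count}
    visited: set[str] = set()
    unitigs: set[str] = set()
    for km in kmers:
        if km in visited:
            continue
        right = _walk(kmers, km, forward=True)
        left = _walk(kmers, km, forward=False)
        nodes = list(reversed(left)) + [km] + right
        visited.update(canonical(n) for n in nodes)
        seq = nodes[0] + "".join(n[-1] for n in nodes[1:])
        unitigs.add(canonical(seq))
    ordered = sorted(unitigs, key=lambda s: (s, len(s)))
    return [
        SequenceRecord(id=f"{sample + '_' if sample else ''}u{i}", seq=s, sample=sample)
        for i, s in enumerate(ordered, start=1)
    ]


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    """N50/L50 and friends.

    N50 is the length of the smallest contig in the minimal set of longest
    contigs whose summed length reaches half the total; L50 is the size of
    that set.  Empty input yields all-zero stats.
    """
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    if not lengths:
        return AssemblyStats(0, 0, 0, 0, 0, 0.0)
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    acc = 0
    for i, l in enumerate(ordered, start=1):
        acc += l
        if 2 * acc >= total:
            return AssemblyStats(
                n_contigs=len(ordered),
                total_len=total,
                n50=l,
                l50=i,
                max_len=ordered[0],
                mean_len=total / len(ordered),
            )
    raise AssertionError("unreachable")


def select_k(
    reads: Sequence[str | SequenceRecord],
    k_grid: Sequence[int],
    params: AssemblyParams | None = None,
) -> tuple[int, list[tuple[int, AssemblyStats]]]:
    """Grid-search k, ranking by (N50 desc, contig count asc, L50 asc).

    Stats are computed after the length filter, matching how assemblies are
    reported.  Returns the winning k and the full per-k table.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    base = params or AssemblyParams()
    table: list[tuple[int, AssemblyStats]] = []
    for k in k_grid:
        p = AssemblyParams(k=k, min_kmer_count=base.min_kmer_count, min_contig_len=base.min_contig_len)
        contigs = build_unitigs(reads, p)
        lengths = [len(c) for c in contigs if len(c) >= p.min_contig_len]
        table.append((k, assembly_stats(lengths)))
    if all(st.n_contigs == 0 for _, st in table):
        raise ValueError("no contigs at any k")
    best_k, _ = min(table, key=lambda row: (-row[1].n50, row[1].n_contigs, row[1].l50))
    return best_k, table
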