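"""Synthetic pangenome simulator with ground truth.

Generates a uniform-random reference, per-sample donor genomes carrying novel
insertions absent from the reference (absence is enforced at 31-mer
resolution, far stronger than an exact-substring check), error-bearing
paired-end reads with a Gaussian insert-size distribution, and truth tables.

Two *truth-aware aligners* write valid SAM by looking up each read's true
origin (encoded in its name) instead of aligning: one against the reference
(the triage input) and one against the panreference (the anchoring input).
They are explicit test doubles for an external short-read mapper and are
never used when real alignments are supplied.  Reads are emitted mapped at
their true coordinates with MAPQ 60 when they fit wholly inside mappable
sequence, unmapped otherwise; a pair is properly paired only when its whole
fragment lies contiguously inside one mapped segment.  A read lying wholly
in reference sequence that a contig also carries (flank overhang) is
assigned to the chromosome — the longer, unique context — mirroring how a
mapper resolves such ties.

All randomness flows from one integer seed through numpy Generator streams,
so every artefact is reproducible byte-for-byte.
"""

from __future__ import annotations

import bisect
import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .align import locate_infix
from .records import AlignmentHit, SequenceRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


# ---------------------------------------------------------------------------
# Configuration and truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic pangenome.

    Defaults describe a desk-scale rice-like scenario: a 1 Mb single-
    chromosome reference, five accessions each carrying ten novel insertions
    of 1-3 kb (half of them shared between accessions), sequenced as 150 bp
    pairs at 30x with a 500 +/- 50 bp insert and 0.5% substitution error.
    """

    ref_len: int = 1_000_000
    n_chroms: int = 1
    n_samples: int = 5
    insertions_per_sample: int = 10
    insertion_len_range: tuple[int, int] = (1000, 3000)
    sharing: float = 0.5
    read_len: int = 150
    depth: float = 30.0
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    base_error_rate: float = 0.005
    seed: int = 0
    min_event_gap: int = 5000  # keeps insertion loci well separated
    novelty_k: int = 31  # novel segments share no k-mer of this size with the reference

    def __post_init__(self):
        if self.insert_mean <= 2 * self.read_len:
            raise ValueError("insert_mean must exceed twice the read length")
        if min(self.ref_len, self.n_chroms, self.n_samples, self.read_len) <= 0:
            raise ValueError("sizes must be positive")
        if not 0 <= self.sharing <= 1:
            raise ValueError("sharing must be a probability")


@dataclass(frozen=True)
class InsertionTruth:
    sample_id: str
    chrom: str
    ref_pos: int  # 0-based insertion point on the reference
    novel_seq_id: str
    novel_len: int
    shared_with: tuple[str, ...] = ()


@dataclass(frozen=True)
class Segment:
    """One contiguous block of a donor chromosome."""

    donor_start: int
    donor_end: int
    kind: str  # 'ref' or 'novel'
    ref_start: int = -1  # for kind='ref'
    novel_id: str = ""  # for kind='novel'


@dataclass
class DonorSet:
    donors: dict[str, list[SequenceRecord]]
    segment_maps: dict[str, dict[str, list[Segment]]]  # sample -> chrom -> segments
    truth: list[InsertionTruth]
    novel_segments: dict[str, str]  # novel_seq_id -> sequence


@dataclass(frozen=True)
class ReadPair:
    """A sequenced fragment; name encodes the true donor-coordinate origin."""

    name: str
    seq1: str  # forward read from the fragment's left end
    seq2: str  # reverse read from the right end, in sequencing orientation
    sample: str
    chrom: str
    start: int  # fragment start, donor coordinates
    insert: int


# ---------------------------------------------------------------------------
# Reference and donors
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def simulate_reference(config: SimConfig, rng: Optional[np.random.Generator] = None) -> list[SequenceRecord]:
    """Uniform-random chromosomes totalling ``ref_len`` bases."""
    rng = rng or np.random.default_rng(config.seed)
    per = config.ref_len // config.n_chroms
    return [
        SequenceRecord(id=f"chr{i + 1}", seq=random_dna(rng, per))
        for i in range(config.n_chroms)
    ]


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.uint64)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | codes[j : j + n]
    return out


def _novel_segment(rng: np.random.Generator, length: int, ref_kmers: np.ndarray, k: int) -> str:
    """Random sequence sharing no k-mer with the reference (resampled on collision)."""
    while True:
        seq = random_dna(rng, length)
        if not np.isin(_kmer_codes(seq, k), ref_kmers, assume_unique=False).any():
            return seq


def simulate_donors(
    reference: Sequence[SequenceRecord],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> DonorSet:
    """Plant novel insertions into per-sample copies of the reference.

    Insertion events are drawn until every sample carries its quota; with
    probability ``sharing`` an event is shared by a random subset (>= 2) of
    the samples still needing insertions, making it identical in sequence
    and reference position across its carriers (the fuel for redundancy
    clustering).  Events on one chromosome are kept ``min_event_gap`` apart.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    ref_kmers = np.unique(
        np.concatenate([_kmer_codes(r.seq, config.novelty_k) for r in reference])
    )
    margin = int(2 * config.insert_mean)
    lo, hi = config.insertion_len_range

    counts = {s: 0 for s in samples}
    events = []  # (chrom, ref_pos, novel_id, seq, carriers)
    used_pos: dict[str, list[int]] = {r.id: [] for r in reference}
    eid = 0
    while any(c < config.insertions_per_sample for c in counts.values()):
        eligible = [s for s in samples if counts[s] < config.insertions_per_sample]
        if len(eligible) >= 2 and rng.random() < config.sharing:
            k = int(rng.integers(2, len(eligible) + 1))
            carriers = sorted(rng.choice(eligible, size=k, replace=False).tolist())
        else:
            carriers = [eligible[int(rng.integers(len(eligible)))]]
        chrom = reference[int(rng.integers(len(reference)))]
        for _ in range(1000):
            pos = int(rng.integers(margin, len(chrom.seq) - margin))
            if all(abs(pos - p) >= config.min_event_gap for p in used_pos[chrom.id]):
                break
        else:
            raise RuntimeError("could not place insertion with required gap")
        used_pos[chrom.id].append(pos)
        length = int(rng.integers(lo, hi + 1))
        eid += 1
        nid = f"ins{eid}"
        events.append((chrom.id, pos, nid, _novel_segment(rng, length, ref_kmers, config.novelty_k), carriers))
        for s in carriers:
            counts[s] += 1

    ref_by_id = {r.id: r.seq for r in reference}
    donors: dict[str, list[SequenceRecord]] = {}
    segment_maps: dict[str, dict[str, list[Segment]]] = {}
    truth: list[InsertionTruth] = []
    novel_segments = {nid: seq for _, _, nid, seq, _ in events}
    for s in samples:
        donors[s] = []
        segment_maps[s] = {}
        for r in reference:
            mine = sorted(
                (pos, nid, seq) for chrom, pos, nid, seq, carriers in events
                if chrom == r.id and s in carriers
            )
            parts = []
            segs: list[Segment] = []
            cursor_ref = 0
            cursor_donor = 0
            for pos, nid, seq in mine:
                if pos > cursor_ref:
                    parts.append(ref_by_id[r.id][cursor_ref:pos])
                    segs.append(Segment(cursor_donor, cursor_donor + pos - cursor_ref, "ref", ref_start=cursor_ref))
                    cursor_donor += pos - cursor_ref
                    cursor_ref = pos
                parts.append(seq)
                segs.append(Segment(cursor_donor, cursor_donor + len(seq), "novel", novel_id=nid))
                cursor_donor += len(seq)
            tail = ref_by_id[r.id][cursor_ref:]
            if tail:
                parts.append(tail)
                segs.append(Segment(cursor_donor, cursor_donor + len(tail), "ref", ref_start=cursor_ref))
            donors[s].append(SequenceRecord(id=r.id, seq="".join(parts), sample=s))
            segment_maps[s][r.id] = segs
    for chrom, pos, nid, seq, carriers in events:
        for s in carriers:
            truth.append(
                InsertionTruth(
                    sample_id=s,
                    chrom=chrom,
                    ref_pos=pos,
                    novel_seq_id=nid,
                    novel_len=len(seq),
                    shared_with=tuple(c for c in carriers if c != s),
                )
            )
    return DonorSet(donors=donors, segment_maps=segment_maps, truth=truth, novel_segments=novel_segments)


def classify_interval(segments: Sequence[Segment], start: int, end: int) -> Optional[Segment]:
    """The segment wholly containing [start, end), or None if it straddles."""
    idx = bisect.bisect_right([s.donor_start for s in segments], start) - 1
    if idx < 0:
        return None
    seg = segments[idx]
    return seg if end <= seg.donor_end else None


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(
    donor: Sequence[SequenceRecord],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    sample: str = "S1",
) -> list[ReadPair]:
    """Sequence a donor genome into error-bearing read pairs.

    Fragments are uniform over each chromosome, insert length Gaussian
    truncated below at 2*read_len; mate 1 is the fragment's left end read
    forward, mate 2 the right end read reverse-complemented.  Substitution
    errors are injected at ``base_error_rate`` per base (no indels).
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    rl = config.read_len
    pairs: list[ReadPair] = []
    for rec in donor:
        L = len(rec.seq)
        if L < 2 * rl:
            raise ValueError(f"{rec.id}: genome shorter than a fragment")
        n_pairs = int(round(config.depth * L / (2 * rl)))
        ins = np.rint(rng.normal(config.insert_mean, config.insert_sd, n_pairs)).astype(np.int64)
        ins = np.clip(ins, 2 * rl, L)
        starts = (rng.random(n_pairs) * (L - ins + 1)).astype(np.int64)
        nerr = rng.binomial(2 * rl, config.base_error_rate, n_pairs)
        total_err = int(nerr.sum())
        err_pos = rng.integers(0, 2 * rl, total_err)
        err_shift = rng.integers(1, 4, total_err)
        ptr = 0
        for i in range(n_pairs):
            s, ilen = int(starts[i]), int(ins[i])
            r1 = rec.seq[s : s + rl]
            r2 = revcomp(rec.seq[s + ilen - rl : s + ilen])
            ne = int(nerr[i])
            if ne:
                r1b, r2b = bytearray(r1, "ascii"), bytearray(r2, "ascii")
                for j in range(ne):
                    p = int(err_pos[ptr + j])
                    sh = int(err_shift[ptr + j])
                    buf, off = (r1b, p) if p < rl else (r2b, p - rl)
                    buf[off] = _BASES[(int(_CODE[buf[off]]) + sh) % 4]
                r1, r2 = r1b.decode(), r2b.decode()
            ptr += ne
            pairs.append(
                ReadPair(
                    name=f"{sample}:{rec.id}:{i}:{s}:{ilen}",
                    seq1=r1,
                    seq2=r2,
                    sample=sample,
                    chrom=rec.id,
                    start=s,
                    insert=ilen,
                )
            )
    return pairs


def reads_to_fastq(pairs: Sequence[ReadPair], prefix) -> tuple[Path, Path]:
    from .io import write_fastq

    p1 = write_fastq(((p.name, p.seq1, None) for p in pairs), f"{prefix}_1.fastq")
    p2 = write_fastq(((p.name, p.seq2, None) for p in pairs), f"{prefix}_2.fastq")
    return p1, p2


# ---------------------------------------------------------------------------
# Truth-aware aligners (test doubles for the external mapper)
# ---------------------------------------------------------------------------

_FLAG = dict(paired=0x1, proper=0x2, unmapped=0x4, munmapped=0x8, rev=0x10, mrev=0x20, first=0x40, second=0x80)


def _sam_line(name, flag, rname, pos, mapq, cigar, rnext, pnext, seq, rl):
    return (
        f"{name}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t{rnext}\t{pnext}\t0\t{seq}\t{'I' * rl}\n"
    )


def _write_pair_sam(fh, pair: ReadPair, m1, m2, proper: bool, rl: int):
    """Emit one pair; m1/m2 are (target, pos, reverse) or None when unmapped."""
    for mate_idx, (mine, other, read) in enumerate(
        ((m1, m2, pair.seq1), (m2, m1, pair.seq2)), start=1
    ):
        flag = _FLAG["paired"] | (_FLAG["first"] if mate_idx == 1 else _FLAG["second"])
        if proper:
            flag |= _FLAG["proper"]
        if mine is None:
            flag |= _FLAG["unmapped"]
        elif mine[2]:
            flag |= _FLAG["rev"]
        if other is None:
            flag |= _FLAG["munmapped"]
        elif other[2]:
            flag |= _FLAG["mrev"]
        if mine is None:
            rname, pos, mapq, cigar, seq = "*", 0, 0, "*", read
        else:
            rname, pos, mapq, cigar = mine[0], mine[1] + 1, 60, f"{rl}M"
            seq = revcomp(read) if mine[2] else read
        if other is None:
            rnext, pnext = "*", 0
        else:
            rnext = "=" if (mine is not None and other[0] == mine[0]) else other[0]
            pnext = other[1] + 1
        fh.write(_sam_line(pair.name, flag, rname, pos, mapq, cigar, rnext, pnext, seq, rl))


def _sam_header(fh, sq: Sequence[tuple[str, int]]):
    fh.write("@HD\tVN:1.6\tSO:unknown\n")
    for name, length in sq:
        fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")


def truth_aligner(
    pairs: Sequence[ReadPair],
    reference: Sequence[SequenceRecord],
    donor_set: DonorSet,
    path,
) -> Path:
    """Write reference alignments for simulated reads by true-origin lookup.

    A read maps iff it lies wholly inside a reference-derived donor segment;
    a pair is proper iff the whole fragment does.  Reads touching novel
    sequence come out unmapped — exactly the triage fuel.
    """
    path = Path(path)
    rl = None
    with open(path, "w") as fh:
        _sam_header(fh, [(r.id, len(r.seq)) for r in reference])
        for pair in pairs:
            rl = len(pair.seq1)
            segs = donor_set.segment_maps[pair.sample][pair.chrom]
            s, ilen = pair.start, pair.insert
            placed = []
            for u, v, rev in ((s, s + rl, False), (s + ilen - rl, s + ilen, True)):
                seg = classify_interval(segs, u, v)
                if seg is not None and seg.kind == "ref":
                    placed.append((pair.chrom, seg.ref_start + (u - seg.donor_start), rev))
                else:
                    placed.append(None)
            frag_seg = classify_interval(segs, s, s + ilen)
            proper = frag_seg is not None and frag_seg.kind == "ref"
            _write_pair_sam(fh, pair, placed[0], placed[1], proper, rl)
    return path


@dataclass
class ContigProvenance:
    """Where each assembled contig truly sits, for the panreference aligner."""

    # sample -> chrom -> sorted list of (donor_start, donor_end, contig_id, strand)
    donor_spans: dict[str, dict[str, list[tuple[int, int, str, str]]]]
    # novel_seq_id -> list of (contig_id, ns_start, ns_end, ctg_start, strand)
    novel_entries: dict[str, list[tuple[str, int, int, int, str]]]
    located: dict[str, tuple[str, str, int, int, str]]  # contig -> (sample, chrom, a, b, strand)


def locate_contigs(
    contigs: Sequence[SequenceRecord],
    donor_set: DonorSet,
    max_divergence: float = 0.05,
) -> ContigProvenance:
    """Place each contig on its sample-of-origin donor genome by alignment.

    Uses infix edit-distance alignment on both strands; a contig whose best
    placement diverges more than ``max_divergence`` gets no provenance (its
    reads will be emitted unmapped).  The located donor interval is then
    intersected with the sample's novel segments to express the contig in
    novel-segment coordinates, which lets reads from *other* carriers of a
    shared insertion find the representative contig.
    """
    donor_spans: dict[str, dict[str, list]] = {s: {c: [] for c in dm} for s, dm in donor_set.segment_maps.items()}
    novel_entries: dict[str, list] = {}
    located: dict[str, tuple] = {}
    for contig in contigs:
        sample = contig.sample
        if sample is None or sample not in donor_set.donors:
            continue
        best = None
        for rec in donor_set.donors[sample]:
            if len(contig.seq) > len(rec.seq):
                continue
            for strand, seq in (("+", contig.seq), ("-", revcomp(contig.seq))):
                d, a, b = locate_infix(seq, rec.seq)
                if best is None or d < best[0]:
                    best = (d, rec.id, a, b, strand)
        if best is None or best[0] > max_divergence * len(contig.seq):
            continue
        _, chrom, a, b, strand = best
        located[contig.id] = (sample, chrom, a, b, strand)
        donor_spans[sample][chrom].append((a, b, contig.id, strand))
        for seg in donor_set.segment_maps[sample][chrom]:
            if seg.kind != "novel":
                continue
            os_, oe = max(a, seg.donor_start), min(b, seg.donor_end)
            if oe - os_ <= 0:
                continue
            ns_start, ns_end = os_ - seg.donor_start, oe - seg.donor_start
            ctg_start = (os_ - a) if strand == "+" else (b - oe)
            novel_entries.setdefault(seg.novel_id, []).append(
                (contig.id, ns_start, ns_end, ctg_start, strand)
            )
    for chrom_map in donor_spans.values():
        for spans in chrom_map.values():
            spans.sort()
    return ContigProvenance(donor_spans=donor_spans, novel_entries=novel_entries, located=located)


def _place_on_panref(
    pair_sample: str,
    chrom: str,
    u: int,
    v: int,
    rev: bool,
    segs: Sequence[Segment],
    prov: ContigProvenance,
):
    """True panreference placement of one read interval, or None."""
    seg = classify_interval(segs, u, v)
    if seg is not None and seg.kind == "ref":
        return (chrom, seg.ref_start + (u - seg.donor_start), rev)
    # junction or novel read: inside a located contig span of this sample?
    for a, b, contig_id, strand in prov.donor_spans.get(pair_sample, {}).get(chrom, ()):
        if a <= u and v <= b:
            if strand == "+":
                return (contig_id, u - a, rev)
            return (contig_id, b - v, not rev)
    # novel-interior read: translate through novel-segment coordinates
    if seg is not None and seg.kind == "novel":
        off = u - seg.donor_start
        rl = v - u
        for contig_id, ns_start, ns_end, ctg_start, strand in prov.novel_entries.get(seg.novel_id, ()):
            if ns_start <= off and off + rl <= ns_end:
                if strand == "+":
                    return (contig_id, ctg_start + (off - ns_start), rev)
                return (contig_id, ctg_start + ns_end - off - rl, not rev)
    return None


def truth_panref_aligner(
    pairs: Sequence[ReadPair],
    reference: Sequence[SequenceRecord],
    contigs: Sequence[SequenceRecord],
    donor_set: DonorSet,
    provenance: ContigProvenance,
    path,
) -> Path:
    """Write panreference alignments (chromosomes + contigs) by true origin.

    Reads wholly inside reference-derived segments map to chromosomes; reads
    inside a contig's located donor span (novel sequence plus any assembled
    flank overhang, junction reads included) map to the contig; novel-
    interior reads of other carriers reach the contig through novel-segment
    coordinates.  Everything else is unmapped.
    """
    path = Path(path)
    with open(path, "w") as fh:
        _sam_header(
            fh,
            [(r.id, len(r.seq)) for r in reference] + [(c.id, len(c.seq)) for c in contigs],
        )
        for pair in pairs:
            rl = len(pair.seq1)
            segs = donor_set.segment_maps[pair.sample][pair.chrom]
            s, ilen = pair.start, pair.insert
            m1 = _place_on_panref(pair.sample, pair.chrom, s, s + rl, False, segs, provenance)
            m2 = _place_on_panref(pair.sample, pair.chrom, s + ilen - rl, s + ilen, True, segs, provenance)
            proper = (
                m1 is not None
                and m2 is not None
                and m1[0] == m2[0]
                and classify_interval(segs, s, s + ilen) is not None
            )
            _write_pair_sam(fh, pair, m1, m2, proper, rl)
    return path


# ---------------------------------------------------------------------------
# Truth-derived alignment tables for validation
# ---------------------------------------------------------------------------

def truth_assembly_hits(
    contigs: Sequence[SequenceRecord],
    provenance: ContigProvenance,
) -> list[AlignmentHit]:
    """Contig-vs-donor-assembly hits (the donor genome stands in for an
    independent long-read assembly of the same individual)."""
    hits = []
    for contig in contigs:
        loc = provenance.located.get(contig.id)
        if loc is None:
            continue
        sample, chrom, a, b, strand = loc
        hits.append(
            AlignmentHit(
                query_id=contig.id,
                target_id=f"{sample}:{chrom}",
                q_start=0,
                q_end=len(contig.seq),
                t_start=a,
                t_end=b,
                identity=1.0,  # located within max_divergence; exact identity refined below
                aligned_len=max(len(contig.seq), b - a),
                strand=strand,
            )
        )
    return hits


def refined_assembly_hits(
    contigs: Sequence[SequenceRecord],
    donor_set: DonorSet,
    provenance: ContigProvenance,
) -> list[AlignmentHit]:
    """Like :func:`truth_assembly_hits` but with edit-distance identities."""
    import edlib

    hits = []
    donors = {(s, rec.id): rec.seq for s, recs in donor_set.donors.items() for rec in recs}
    for contig in contigs:
        loc = provenance.located.get(contig.id)
        if loc is None:
            continue
        sample, chrom, a, b, strand = loc
        target = donors[(sample, chrom)][a:b]
        query = contig.seq if strand == "+" else revcomp(contig.seq)
        d = edlib.align(query, target, mode="NW", task="distance")["editDistance"]
        ident = max(0.0, 1.0 - d / len(contig.seq))
        hits.append(
            AlignmentHit(
                query_id=contig.id,
                target_id=f"{sample}:{chrom}",
                q_start=0,
                q_end=len(contig.seq),
                t_start=a,
                t_end=b,
                identity=ident,
                aligned_len=max(len(contig.seq), b - a),
                strand=strand,
            )
        )
    return hits


def novel_segment_coverage(
    provenance: ContigProvenance,
    novel_segments: dict[str, str],
) -> dict[str, float]:
    """Fraction of each planted novel segment covered by located contigs."""
    cov = {}
    for nid, seq in novel_segments.items():
        intervals = sorted(
            (ns_start, ns_end) for _, ns_start, ns_end, _, _ in provenance.novel_entries.get(nid, ())
        )
        covered = 0
        cur_s = cur_e = None
        for s, e in intervals:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        cov[nid] = covered / len(seq)
    return cov


def truth_flank_hits(
    contigs: Sequence[SequenceRecord],
    donor_set: DonorSet,
    provenance: ContigProvenance,
    flank_len: int = 1000,
) -> list[AlignmentHit]:
    """Realign (by lookup) the donor sequence flanking each located contig.

    Emits one hit per resolvable flank, query_id = contig id, target = the
    reference chromosome where the flank's donor interval maps.  Flanks
    falling outside reference-derived sequence (e.g. into a neighbouring
    insertion) are skipped and the contig becomes non-evaluable.
    """
    hits = []
    for contig in contigs:
        loc = provenance.located.get(contig.id)
        if loc is None:
            continue
        sample, chrom, a, b, _ = loc
        segs = donor_set.segment_maps[sample][chrom]
        for u, v in ((max(0, a - flank_len), a), (b, b + flank_len)):
            if v <= u:
                continue
            seg = classify_interval(segs, u, v)
            if seg is None or seg.kind != "ref":
                continue
            t_start = seg.ref_start + (u - seg.donor_start)
            hits.append(
                AlignmentHit(
                    query_id=contig.id,
                    target_id=chrom,
                    q_start=0,
                    q_end=v - u,
                    t_start=t_start,
                    t_end=t_start + (v - u),
                    identity=1.0,
                    aligned_len=v - u,
                    strand="+",
                )
            )
    return hits


def write_truth_csv(truth: Sequence[InsertionTruth], path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "chrom", "ref_pos", "novel_seq_id", "novel_len", "shared_with"])
        for t in truth:
            w.writerow([t.sample_id, t.chrom, t.ref_pos, t.novel_seq_id, t.novel_len, ";".join(t.shared_with)])
    return path
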