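"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ parsing goes through Biopython, SAM/BAM through pysam.  Tabular
alignment hits are accepted in three dialects: BLAST outfmt-6 (optionally
with a trailing taxon-label column), PAF, and ``show-coords -T`` tables.
All in-memory coordinates are 0-based half-open (see :mod:`panforge.records`);
the placements CSV is exported 1-based inclusive, BED 0-based half-open.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pysam
from Bio import SeqIO

from .records import (
    UNMAPPED,
    AlignmentHit,
    PairAlignmentRecord,
    SequenceRecord,
    decode_flags,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike, sample: Optional[str] = None) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, ids checked unique)."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise ValueError(f"{path}: record {i} has an empty header")
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: record {i} ({rec.id!r}) has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r} (record {i})")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), sample=sample))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, line_width: int = 60) -> Path:
    """Write records as FASTA, wrapping sequence lines at ``line_width``."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i : i + line_width] + "\n")
    return path


def read_fastq(path: PathLike, sample: Optional[str] = None) -> list[SequenceRecord]:
    """Read a FASTQ file; qualities are discarded (assembly is quality-blind)."""
    return [
        SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), sample=sample)
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[tuple[str, str, Optional[str]]], path: PathLike) -> Path:
    """Write (name, seq, qual) triples as FASTQ; missing quality becomes 'I'."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual or 'I' * len(seq)}\n")
    return path


# ---------------------------------------------------------------------------
# SAM/BAM pair streaming
# ---------------------------------------------------------------------------

class PairReader:
    """Iterate mate pairs from a SAM/BAM file.

    Pairing is reconstructed by read name + mate index, so the input may be
    name-grouped or coordinate sorted.  Secondary/supplementary records are
    collected on :attr:`secondary` (never silently dropped, never paired);
    reads whose mate never appears end up on :attr:`orphans`.  Both lists and
    the counters are complete only after the iterator is exhausted.
    """

    def __init__(self, path: PathLike):
        self.path = str(path)
        self.orphans: list[PairAlignmentRecord] = []
        self.secondary: list[PairAlignmentRecord] = []
        self.n_records = 0
        self.n_pairs = 0

    @staticmethod
    def _convert(read: pysam.AlignedSegment) -> PairAlignmentRecord:
        flags = decode_flags(read.flag)
        unmapped = flags.is_unmapped
        return PairAlignmentRecord(
            read_id=read.query_name,
            mate_index=2 if read.is_read2 else 1,
            target=UNMAPPED if unmapped else read.reference_name,
            pos=None if unmapped else read.reference_start,
            aln_end=None if unmapped else read.reference_end,
            mapq=None if unmapped else read.mapping_quality,
            flags=flags,
            seq=read.query_sequence,
            qual=pysam.qualities_to_qualitystring(read.query_qualities)
            if read.query_qualities is not None
            else None,
        )

    def __iter__(self) -> Iterator[tuple[PairAlignmentRecord, PairAlignmentRecord]]:
        pending: dict[str, PairAlignmentRecord] = {}
        with pysam.AlignmentFile(self.path, check_sq=False) as af:
            for read in af:
                self.n_records += 1
                rec = self._convert(read)
                if rec.flags.is_secondary_or_supplementary:
                    self.secondary.append(rec)
                    continue
                mate = pending.get(rec.read_id)
                if mate is None:
                    pending[rec.read_id] = rec
                elif mate.mate_index == rec.mate_index:
                    # duplicate primary record for the same mate: keep newest
                    self.orphans.append(mate)
                    pending[rec.read_id] = rec
                else:
                    del pending[rec.read_id]
                    self.n_pairs += 1
                    yield (mate, rec) if mate.mate_index == 1 else (rec, mate)
        self.orphans.extend(pending.values())

    @property
    def n_orphans(self) -> int:
        return len(self.orphans)


def stream_pair_alignments(path: PathLike) -> PairReader:
    """Open a SAM/BAM file for mate-pair streaming (see :class:`PairReader`)."""
    return PairReader(path)


# ---------------------------------------------------------------------------
# Placements CSV / BED
# ---------------------------------------------------------------------------

CSV_HEADER = ["contig_id", "status", "chrom", "start", "end", "n_support", "span"]


def write_placements_csv(placements, path: PathLike) -> Path:
    """Write placements as CSV, one row per locus (1-based inclusive coords).

    Unplaced contigs get a single row with empty locus columns.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        for p in placements:
            if not p.loci:
                w.writerow([p.contig_id, p.status, "", "", "", 0, ""])
                continue
            for locus in p.loci:
                w.writerow(
                    [
                        p.contig_id,
                        p.status,
                        locus.chrom,
                        locus.start + 1,
                        locus.end,
                        locus.n_support,
                        locus.end - locus.start,
                    ]
                )
    return path


def write_placements_bed(placements, path: PathLike) -> Path:
    """Write uniquely placed contigs as BED4 (0-based half-open)."""
    path = Path(path)
    with open(path, "w") as fh:
        for p in placements:
            if p.status != "unique":
                continue
            locus = p.loci[0]
            fh.write(f"{locus.chrom}\t{locus.start}\t{locus.end}\t{p.contig_id}\n")
    return path


# ---------------------------------------------------------------------------
# Alignment-hit tables
# ---------------------------------------------------------------------------

def read_blast_tab(path: PathLike) -> tuple[list[AlignmentHit], dict[str, str]]:
    """Read a BLAST outfmt-6 TSV, optionally with a 13th taxon-label column.

    Returns the hits plus a ``{query_id: taxon}`` map for the best-scoring
    labelled row per query (empty when the column is absent).  BLAST's
    1-based inclusive coordinates are converted to 0-based half-open; a
    target interval given end-before-start marks a minus-strand hit.
    """
    hits: list[AlignmentHit] = []
    taxa: dict[str, tuple[float, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            qseqid, sseqid = f[0], f[1]
            pident, length = float(f[2]), int(f[3])
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            bitscore = float(f[11])
            strand = "+" if send >= sstart else "-"
            if strand == "-":
                sstart, send = send, sstart
            hit = AlignmentHit(
                query_id=qseqid,
                target_id=sseqid,
                q_start=qstart - 1,
                q_end=qend,
                t_start=sstart - 1,
                t_end=send,
                identity=pident / 100.0,
                aligned_len=length,
                strand=strand,
                bitscore=bitscore,
            )
            hits.append(hit)
            if len(f) >= 13 and f[12]:
                best = taxa.get(qseqid)
                if best is None or bitscore > best[0]:
                    taxa[qseqid] = (bitscore, f[12])
    return hits, {q: t for q, (_, t) in taxa.items()}


def read_paf(path: PathLike) -> list[AlignmentHit]:
    """Read a PAF file into AlignmentHits (identity = matches / block length)."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            matches, block = int(f[9]), int(f[10])
            hits.append(
                AlignmentHit(
                    query_id=f[0],
                    target_id=f[5],
                    q_start=int(f[2]),
                    q_end=int(f[3]),
                    t_start=int(f[7]),
                    t_end=int(f[8]),
                    identity=matches / block if block else 0.0,
                    aligned_len=block,
                    strand=f[4],
                )
            )
    return hits


def read_show_coords(path: PathLike) -> list[AlignmentHit]:
    """Read a ``show-coords -T`` (tab-delimited) nucmer table.

    Expected columns: S1 E1 S2 E2 LEN1 LEN2 %IDY REF QRY (header lines are
    skipped).  The reference is the anchoring target, the query the contig.
    Coordinates are 1-based inclusive; a reversed query interval marks a
    minus-strand hit.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            try:
                s1, e1, s2, e2 = int(f[0]), int(f[1]), int(f[2]), int(f[3])
                len1, len2, idy = int(f[4]), int(f[5]), float(f[6])
            except ValueError:
                continue  # header / separator line
            strand = "+" if e2 >= s2 else "-"
            if strand == "-":
                s2, e2 = e2, s2
            hits.append(
                AlignmentHit(
                    query_id=f[8],
                    target_id=f[7],
                    q_start=s2 - 1,
                    q_end=e2,
                    t_start=s1 - 1,
                    t_end=e1,
                    identity=idy / 100.0,
                    aligned_len=max(len1, len2),
                    strand=strand,
                )
            )
    return hits


def read_cdhit_clstr(path: PathLike) -> list[tuple[str, list[str]]]:
    """Parse a CD-HIT ``.clstr`` file into (rep_id, member_ids) tuples."""
    clusters: list[tuple[Optional[str], list[str]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">Cluster"):
                clusters.append((None, []))
            elif line:
                name = line.split(">", 1)[1].split("...", 1)[0]
                rep, members = clusters[-1]
                members.append(name)
                if line.endswith("*"):
                    clusters[-1] = (name, members)
    out = []
    for rep, members in clusters:
        if rep is None:
            raise ValueError("cluster without a representative ('*') entry")
        out.append((rep, members))
    return out
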