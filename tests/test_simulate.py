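"""Simulator determinism, bookkeeping, and truth-aware alignment semantics."""

import numpy as np
import pytest

from panforge import io as pio
from panforge.records import revcomp
from panforge.simulate import (
    SimConfig,
    classify_interval,
    locate_contigs,
    reads_to_fastq,
    simulate_donors,
    simulate_reads,
    simulate_reference,
    truth_aligner,
)
from panforge.triage import TriageMode, select_pair


def test_reference_deterministic_under_seed():
    cfg = SimConfig(ref_len=1000, n_chroms=1, seed=7)
    a = simulate_reference(cfg)
    b = simulate_reference(cfg)
    assert a[0].seq == b[0].seq


def test_reference_chromosome_split():
    cfg = SimConfig(ref_len=1000, n_chroms=2, seed=1)
    recs = simulate_reference(cfg)
    assert [len(r.seq) for r in recs] == [500, 500]
    assert [r.id for r in recs] == ["chr1", "chr2"]


def test_reference_base_composition_near_uniform():
    cfg = SimConfig(ref_len=400_000, seed=2)
    seq = simulate_reference(cfg)[0].seq
    n = len(seq)
    for base in "ACGT":
        # binomial sd ~ sqrt(n*0.25*0.75); allow 5 sigma
        assert abs(seq.count(base) - n / 4) < 5 * np.sqrt(n * 0.1875)


def test_donor_length_conservation(tiny_sim):
    config, reference, donor_set = tiny_sim
    ref_len = sum(len(r.seq) for r in reference)
    for sample, recs in donor_set.donors.items():
        ins_len = sum(t.novel_len for t in donor_set.truth if t.sample_id == sample)
        assert sum(len(r.seq) for r in recs) == ref_len + ins_len


def test_zero_insertions_donor_equals_reference():
    cfg = SimConfig(ref_len=5000, insertions_per_sample=0, n_samples=2, seed=3)
    reference = simulate_reference(cfg)
    ds = simulate_donors(reference, cfg)
    for recs in ds.donors.values():
        assert recs[0].seq == reference[0].seq
    assert ds.truth == []


def test_novel_segments_share_no_kmer_with_reference(tiny_sim):
    config, reference, donor_set = tiny_sim
    k = config.novelty_k
    ref = reference[0].seq
    for seq in donor_set.novel_segments.values():
        assert all(seq[i : i + k] not in ref for i in range(0, len(seq) - k + 1, 17))


def test_shared_insertions_identical_across_carriers(tiny_sim):
    _, _, donor_set = tiny_sim
    by_nid = {}
    for t in donor_set.truth:
        by_nid.setdefault(t.novel_seq_id, []).append(t)
    for rows in by_nid.values():
        assert len({(r.chrom, r.ref_pos, r.novel_len) for r in rows}) == 1


def test_read_count_matches_depth_arithmetic():
    cfg = SimConfig(ref_len=100_000, depth=30.0, read_len=150, seed=4)
    genome = simulate_reference(cfg)
    pairs = simulate_reads(genome, cfg, sample="S1")
    expected = cfg.depth * 100_000 / (2 * cfg.read_len)
    assert abs(len(pairs) - expected) / expected < 0.01


def test_error_free_reads_are_exact_substrings():
    cfg = SimConfig(ref_len=20_000, depth=5.0, base_error_rate=0.0, seed=5)
    genome = simulate_reference(cfg)
    seq = genome[0].seq
    for p in simulate_reads(genome, cfg, sample="S1")[:50]:
        assert p.seq1 in seq and revcomp(p.seq2) in seq


def test_fastq_byte_identical_under_seed(tmp_path):
    cfg = SimConfig(ref_len=20_000, depth=2.0, seed=6)
    genome = simulate_reference(cfg)
    out = []
    for run in ("a", "b"):
        rng = np.random.default_rng(99)
        pairs = simulate_reads(genome, cfg, rng, sample="S1")
        p1, p2 = reads_to_fastq(pairs, tmp_path / run)
        out.append(p1.read_text() + p2.read_text())
    assert out[0] == out[1]


def test_genome_shorter_than_fragment_errors():
    cfg = SimConfig(ref_len=20_000, seed=7)
    from panforge.records import SequenceRecord

    with pytest.raises(ValueError, match="shorter"):
        simulate_reads([SequenceRecord("chr1", "ACGT" * 10)], cfg, sample="S1")


# ---------------------------------------------------------------------------
# truth-aware reference aligner
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def aligned_pairs(tmp_path_factory, tiny_sim):
    config, reference, donor_set = tiny_sim
    sample = sorted(donor_set.donors)[0]
    rng = np.random.default_rng(11)
    pairs = simulate_reads(donor_set.donors[sample], config, rng, sample)
    sam = truth_aligner(pairs, reference, donor_set, tmp_path_factory.mktemp("sam") / "t.sam")
    reader = pio.stream_pair_alignments(sam)
    sam_pairs = {p[0].read_id: p for p in reader}
    return config, donor_set, sample, pairs, sam_pairs


def _overlap(a, b, c, d):
    return max(a, c) < min(b, d)


def test_truth_aligner_classes(aligned_pairs):
    config, donor_set, sample, pairs, sam_pairs = aligned_pairs
    rl = config.read_len
    segs_by_chrom = donor_set.segment_maps[sample]
    novel = [
        (s.donor_start, s.donor_end, seg_chrom)
        for seg_chrom, segs in segs_by_chrom.items()
        for s in segs
        if s.kind == "novel"
    ]
    n_ref = n_novel = n_straddle = 0
    for p in pairs:
        r1, r2 = sam_pairs[p.name]
        segs = segs_by_chrom[p.chrom]
        for rec, (u, v) in ((r1, (p.start, p.start + rl)), (r2, (p.start + p.insert - rl, p.start + p.insert))):
            seg = classify_interval(segs, u, v)
            if seg is not None and seg.kind == "ref":
                assert not rec.is_unmapped
                assert rec.pos == seg.ref_start + (u - seg.donor_start)
                assert rec.mapq == 60
                n_ref += 1
            else:
                assert rec.is_unmapped
                n_novel += 1
        frag_seg = classify_interval(segs, p.start, p.start + p.insert)
        proper = frag_seg is not None and frag_seg.kind == "ref"
        assert r1.flags.is_proper_pair == proper == r2.flags.is_proper_pair
        if r1.is_unmapped != r2.is_unmapped:
            n_straddle += 1
            assert select_pair((r1, r2), TriageMode.NOT_PROPER_PAIR)
    # the simulation must actually exercise all three classes
    assert n_ref > 0 and n_novel > 0 and n_straddle > 0


def test_locate_contigs_finds_planted_segment(tiny_sim):
    config, reference, donor_set = tiny_sim
    from panforge.records import SequenceRecord

    sample = sorted(donor_set.donors)[0]
    nid, seq = next(
        (t.novel_seq_id, donor_set.novel_segments[t.novel_seq_id])
        for t in donor_set.truth
        if t.sample_id == sample
    )
    contig = SequenceRecord("test_ctg", seq, sample=sample)
    prov = locate_contigs([contig], donor_set)
    entries = prov.novel_entries[nid]
    assert entries == [("test_ctg", 0, len(seq), 0, "+")]
    # reverse complement locates on the minus strand with the same span
    rc = SequenceRecord("test_rc", revcomp(seq), sample=sample)
    prov_rc = locate_contigs([rc], donor_set)
    (cid, ns_s, ns_e, ctg_s, strand) = prov_rc.novel_entries[nid][0]
    assert (ns_s, ns_e, ctg_s, strand) == (0, len(seq), 0, "-")
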