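"""Mate-pair anchoring: window preselection, locus calling, placement status."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panforge.anchoring import (
    FIRST,
    LAST,
    AnchorEvidence,
    AnchorParams,
    Locus,
    anchoring_summary,
    call_loci,
    call_placements,
    preselect_bridging_pairs,
)

from conftest import make_record

PARAMS = AnchorParams()


def _bridge_pair(contig, contig_pos, chrom, chrom_pos, contig_mapq=60, read_len=100):
    contig_read = make_record(
        "r", 0x1 | 0x40, target=contig, pos=contig_pos, mapq=contig_mapq,
        seq="A" * read_len, aln_end=contig_pos + read_len,
    )
    chrom_read = make_record(
        "r", 0x1 | 0x80, target=chrom, pos=chrom_pos, seq="A" * read_len,
        aln_end=chrom_pos + read_len,
    )
    return (contig_read, chrom_read)


CONTIGS = {"c1": 1000}
CHROMS = {"chr1", "chr2"}


def test_preselect_first_window():
    groups = preselect_bridging_pairs([_bridge_pair("c1", 50, "chr1", 5000)], CONTIGS, CHROMS, PARAMS)
    assert set(groups) == {("c1", FIRST, "chr1")}
    assert groups[("c1", FIRST, "chr1")].mate_positions == [5000]


def test_preselect_outside_windows_rejected():
    groups = preselect_bridging_pairs([_bridge_pair("c1", 400, "chr1", 5000)], CONTIGS, CHROMS, PARAMS)
    assert groups == {}


def test_preselect_last_window_by_alignment_end():
    # read starting at 650 with length 100 ends at 750 > 1000-300
    groups = preselect_bridging_pairs([_bridge_pair("c1", 650, "chr1", 5000)], CONTIGS, CHROMS, PARAMS)
    assert set(groups) == {("c1", LAST, "chr1")}


def test_preselect_mapq_gate_on_contig_side():
    groups = preselect_bridging_pairs(
        [_bridge_pair("c1", 50, "chr1", 5000, contig_mapq=5)], CONTIGS, CHROMS, PARAMS
    )
    assert groups == {}


def test_preselect_short_contig_counts_once_per_end():
    contigs = {"c1": 500}
    groups = preselect_bridging_pairs([_bridge_pair("c1", 250, "chr1", 5000)], contigs, CHROMS, PARAMS)
    assert set(groups) == {("c1", FIRST, "chr1"), ("c1", LAST, "chr1")}
    assert all(len(ev.mate_positions) == 1 for ev in groups.values())


def test_preselect_unknown_target_errors():
    with pytest.raises(ValueError, match="unknown alignment target"):
        preselect_bridging_pairs([_bridge_pair("mystery", 50, "chr1", 5000)], CONTIGS, CHROMS, PARAMS)


# ---------------------------------------------------------------------------
# locus calling
# ---------------------------------------------------------------------------

def _evidence(positions, chrom="chr1", end=FIRST):
    ev = AnchorEvidence("c1", end, chrom, list(positions), [60] * len(positions))
    ev.sort()
    return ev


def test_ten_mates_in_1900bp_span_one_locus():
    ev = _evidence(range(1000, 2000, 100))  # 1000..1900
    (locus,) = call_loci(ev, PARAMS)
    assert (locus.start, locus.end, locus.n_support) == (1000, 1900, 10)


def test_nine_mates_no_locus():
    assert call_loci(_evidence(range(1000, 1900, 100)), PARAMS) == []


def test_span_exactly_2000_is_too_wide():
    positions = list(range(1000, 2800, 200)) + [3000]  # max-min = 2000, strict gate
    assert call_loci(_evidence(positions), PARAMS) == []


def test_outliers_excluded_from_tight_locus():
    tight = list(np.linspace(5000, 6800, 10).astype(int))  # 10 mates within 1.8 kb
    positions = sorted(tight + [100, 9900])
    (locus,) = call_loci(_evidence(positions), PARAMS)
    assert (locus.start, locus.end, locus.n_support) == (5000, 6800, 10)


def brute_force_loci(positions, min_support, max_span):
    """Enumerate all maximal in-span windows, filter by support, merge overlaps."""
    n = len(positions)
    windows = []
    for i in range(n):
        for j in range(i, n):
            if positions[j] - positions[i] >= max_span:
                break
            left_ok = i == 0 or positions[j] - positions[i - 1] >= max_span
            right_ok = j == n - 1 or positions[j + 1] - positions[i] >= max_span
            if left_ok and right_ok and j - i + 1 >= min_support:
                windows.append((i, j))
    merged = []
    for i, j in sorted(windows):
        if merged and i <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], j)
        else:
            merged.append([i, j])
    return [(positions[i], positions[j], j - i + 1) for i, j in merged]


@settings(max_examples=200, deadline=None)
@given(
    st.lists(st.integers(min_value=0, max_value=30000), min_size=0, max_size=200),
    st.integers(min_value=1, max_value=12),
    st.integers(min_value=100, max_value=5000),
)
def test_call_loci_equals_brute_force(positions, min_support, max_span):
    positions = sorted(positions)
    params = AnchorParams(min_support=min_support, max_span=max_span)
    got = [(l.start, l.end, l.n_support) for l in call_loci(_evidence(positions), params)]
    assert got == brute_force_loci(positions, min_support, max_span)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=30000), min_size=0, max_size=100))
def test_tightening_parameters_never_creates_loci(positions):
    positions = sorted(positions)
    loose = AnchorParams(min_support=5, max_span=3000)
    tight_support = AnchorParams(min_support=8, max_span=3000)
    tight_span = AnchorParams(min_support=5, max_span=1500)
    base = call_loci(_evidence(positions), loose)
    base_iv = [(l.start, l.end) for l in base]
    for tight in (tight_support, tight_span):
        tight_loci = call_loci(_evidence(positions), tight)
        if not base:
            assert tight_loci == []
        # every tight locus lies inside some loose locus
        for l in tight_loci:
            assert any(s <= l.start and l.end <= e for s, e in base_iv)


# ---------------------------------------------------------------------------
# placement calling
# ---------------------------------------------------------------------------

def _locus(chrom, start, end, end_tag, n=10):
    return Locus(chrom=chrom, start=start, end=end, n_support=n, ends_supporting=frozenset((end_tag,)))


def test_two_end_merge_gives_unique():
    loci = [_locus("chr1", 10000, 11500, FIRST), _locus("chr1", 12000, 13400, LAST)]
    (p,) = call_placements({"c1": loci}, {"c1": 1000}, PARAMS)
    assert p.status == "unique"
    assert p.loci[0].start == 10000 and p.loci[0].end == 13400
    assert p.loci[0].ends_supporting == frozenset((FIRST, LAST))
    assert p.loci[0].orientation == "+"  # FIRST-end cloud left of LAST-end cloud


def test_two_end_merge_reverse_orientation():
    loci = [_locus("chr1", 12000, 13400, FIRST), _locus("chr1", 10000, 11500, LAST)]
    (p,) = call_placements({"c1": loci}, {"c1": 1000}, PARAMS)
    assert p.status == "unique" and p.loci[0].orientation == "-"


def test_conflicting_chromosome_ends_give_multiple():
    loci = [_locus("chr1", 10000, 11500, FIRST), _locus("chr5", 12000, 13400, LAST)]
    (p,) = call_placements({"c1": loci}, {"c1": 1000}, PARAMS)
    assert p.status == "multiple" and len(p.loci) == 2


def test_no_loci_gives_unplaced():
    (p,) = call_placements({}, {"c1": 1000}, PARAMS)
    assert p.status == "unplaced" and p.loci == []


def test_far_apart_same_chrom_loci_not_merged():
    # gap 50 kb >> contig length + 2*max_span
    loci = [_locus("chr1", 10000, 11000, FIRST), _locus("chr1", 61000, 62000, LAST)]
    (p,) = call_placements({"c1": loci}, {"c1": 1000}, PARAMS)
    assert p.status == "multiple"


def test_partition_invariant_and_summary():
    loci_map = {
        "a": [_locus("chr1", 0, 1000, FIRST), _locus("chr1", 1500, 2000, LAST)],
        "b": [_locus("chr1", 0, 1000, FIRST), _locus("chr2", 0, 1000, FIRST)],
    }
    lengths = {"a": 800, "b": 900, "c": 700, "d": 600}
    placements = call_placements(loci_map, lengths, PARAMS)
    summary = anchoring_summary(placements)
    assert summary["n_unique"] + summary["n_multiple"] + summary["n_unplaced"] == len(lengths)
    assert summary["fraction_unique"] + summary["fraction_multiple"] + summary["fraction_unplaced"] == pytest.approx(1.0)


def test_summary_fractions():
    placements = call_placements(
        {
            "u1": [_locus("chr1", 0, 500, FIRST)],
            "m1": [_locus("chr1", 0, 500, FIRST), _locus("chr2", 0, 500, FIRST)],
        },
        {"u1": 500, "m1": 500, "x1": 400, "x2": 300, "u2": 350},
        PARAMS,
    )
    s = anchoring_summary(placements)
    assert (s["n_unique"], s["n_multiple"], s["n_unplaced"]) == (1, 1, 3)


def test_empty_summary_zeros():
    s = anchoring_summary([])
    assert s["n_contigs"] == 0 and s["fraction_unique"] == 0.0
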