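"""Validation gates, interval-union coverage, flank concordance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panforge.anchoring import Locus, Placement
from panforge.records import AlignmentHit
from panforge.validation import (
    ValidationParams,
    flank_concordance,
    validate_contigs,
)

PARAMS = ValidationParams()


def _hit(q="c1", t="asm1", q_start=0, q_end=850, identity=0.95, aligned_len=None, t_start=0):
    alen = aligned_len if aligned_len is not None else (q_end - q_start)
    return AlignmentHit(q, t, q_start, q_end, t_start, t_start + alen, identity, alen)


def test_single_hit_above_gates_validates():
    records, fraction = validate_contigs([_hit(q_end=850)], {"c1": 1000}, PARAMS)
    assert records[0].validated and fraction == 1.0
    assert records[0].covered_fraction == pytest.approx(0.85)


def test_two_hit_union_coverage():
    hits = [
        _hit(q_start=0, q_end=500, identity=0.92),
        _hit(q_start=500, q_end=850, identity=0.92, t_start=2000),
    ]
    records, fraction = validate_contigs(hits, {"c1": 1000}, PARAMS)
    assert records[0].covered_fraction == pytest.approx(0.85) and fraction == 1.0


def test_min_alignment_length_gate():
    # a 250 bp hit at 99% identity on a 300 bp contig fails the 300 bp gate
    records, fraction = validate_contigs(
        [_hit(q_end=250, identity=0.99)], {"c1": 300}, PARAMS
    )
    assert not records[0].validated and fraction == 0.0


def test_gate_boundaries_are_inclusive():
    # identity exactly 0.90, alignment exactly 300, coverage exactly 0.80 all pass
    records, fraction = validate_contigs(
        [_hit(q_end=300, identity=0.90)], {"c1": 375}, PARAMS
    )
    assert records[0].validated and records[0].covered_fraction == pytest.approx(0.80)


def test_identity_below_gate_discarded():
    records, _ = validate_contigs([_hit(identity=0.89)], {"c1": 1000}, PARAMS)
    assert not records[0].validated and records[0].covered_fraction == 0.0


def test_hit_exceeding_contig_length_errors():
    with pytest.raises(ValueError, match="exceeds contig length"):
        validate_contigs([_hit(q_end=1200)], {"c1": 1000}, PARAMS)


def test_single_best_mode_ignores_secondary_hits():
    hits = [
        _hit(q_start=0, q_end=500, identity=0.95),
        _hit(q_start=500, q_end=850, identity=0.95, t_start=2000),
    ]
    params = ValidationParams(coverage_mode="best")
    records, fraction = validate_contigs(hits, {"c1": 1000}, params)
    assert records[0].covered_fraction == pytest.approx(0.50) and fraction == 0.0


@settings(max_examples=100, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 900), st.integers(1, 400)), min_size=1, max_size=15
    )
)
def test_union_coverage_equals_base_marking(intervals):
    L = 1300
    hits = [
        _hit(q_start=s, q_end=min(L, s + w), identity=0.99, aligned_len=max(300, w))
        for s, w in intervals
    ]
    records, _ = validate_contigs(hits, {"c1": L}, PARAMS)
    marked = np.zeros(L, dtype=bool)
    for s, w in intervals:
        marked[s : min(L, s + w)] = True
    assert records[0].covered_fraction == pytest.approx(marked.sum() / L)


@pytest.mark.parametrize(
    "strict,loose",
    [
        (ValidationParams(min_identity=0.95), PARAMS),
        (ValidationParams(min_coverage=0.90), PARAMS),
        (ValidationParams(min_aln_len=400), PARAMS),
    ],
)
def test_validated_fraction_monotone_in_thresholds(strict, loose):
    rng = np.random.default_rng(9)
    hits, lengths = [], {}
    for i in range(30):
        cid = f"c{i}"
        L = int(rng.integers(320, 1500))
        lengths[cid] = L
        hits.append(
            _hit(
                q=cid,
                q_start=0,
                q_end=int(L * rng.uniform(0.5, 1.0)),
                identity=float(rng.uniform(0.85, 1.0)),
            )
        )
    _, f_loose = validate_contigs(hits, lengths, loose)
    _, f_strict = validate_contigs(hits, lengths, strict)
    assert f_strict <= f_loose


# ---------------------------------------------------------------------------
# flank concordance
# ---------------------------------------------------------------------------

def _placement(contig="c1", chrom="chr1", start=10000, end=11000):
    return Placement(contig, "unique", [Locus(chrom, start, end, 12)])


def _flank(contig="c1", chrom="chr1", t_start=9200):
    return AlignmentHit(contig, chrom, 0, 1000, t_start, t_start + 1000, 1.0, 1000)


def test_flank_within_tolerance_concordant():
    records, acc = flank_concordance([_placement()], [_flank(t_start=9200)], PARAMS)
    assert records[0].concordant and acc == 1.0


def test_flank_wrong_chromosome_discordant():
    records, acc = flank_concordance([_placement()], [_flank(chrom="chr7")], PARAMS)
    assert records[0].evaluable and not records[0].concordant and acc == 0.0


def test_flank_beyond_tolerance_discordant():
    _, acc = flank_concordance([_placement()], [_flank(t_start=14000)], PARAMS)
    assert acc == 0.0


def test_placement_without_flank_hit_non_evaluable():
    records, acc = flank_concordance([_placement()], [], PARAMS)
    assert not records[0].evaluable and acc == 0.0


def test_verbatim_flanks_are_fully_concordant():
    # flanks copied straight from the reference land exactly at the locus
    placements = [_placement(f"c{i}", start=1000 * i + 5000, end=1000 * i + 5600) for i in range(5)]
    flanks = [_flank(f"c{i}", t_start=1000 * i + 5000 - 1000) for i in range(5)]
    _, acc = flank_concordance(placements, flanks, PARAMS)
    assert acc == 1.0
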