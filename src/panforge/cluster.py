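"""Greedy identity clustering of contigs across individuals.

Mirrors the incremental greedy algorithm of CD-HIT-EST at options
``-c 0.80 -s 0.95``: contigs are processed in decreasing length order and
each one joins the FIRST existing cluster representative for which

* candidate length / representative length >= ``min_len_ratio`` (the ``-s``
  gate), and
* alignment identity >= ``min_identity``, identity being matches over the
  shorter sequence length under the best placement of the shorter inside the
  longer, evaluated on both strands,

otherwise it founds a new cluster.  The representative — the longest member —
is what survives into the non-redundant set.

A shared-k-mer prefilter (default 8-mers) skips comparisons that cannot
reach the identity gate; correctness tests disable it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .align import best_strand_identity
from .records import SequenceRecord, revcomp


@dataclass
class Cluster:
    rep_id: str
    member_ids: list[str] = field(default_factory=list)  # rep first
    rep_len: int = 0


@dataclass(frozen=True)
class ClusterStats:
    n_clusters: int
    n_members: int
    singleton_fraction: float
    rep_length_histogram: dict[int, int]  # binned by 500 bp


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    both = seq + "#" + revcomp(seq)
    return frozenset(
        both[i : i + k] for i in range(len(both) - k + 1) if "#" not in both[i : i + k]
    )


def cluster_greedy(
    contigs: Sequence[SequenceRecord],
    min_identity: float = 0.80,
    min_len_ratio: float = 0.95,
    prefilter_k: int | None = 8,
) -> list[Cluster]:
    """Cluster contigs greedily by identity; returns clusters in founding order."""
    if not (0 < min_identity <= 1 and 0 < min_len_ratio <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    by_id = {c.id: c for c in contigs}
    if len(by_id) != len(contigs):
        raise ValueError("duplicate contig ids")
    order = sorted(contigs, key=lambda c: (-len(c), c.id))
    clusters: list[Cluster] = []
    rep_words: list[frozenset[str]] = []
    for cand in order:
        cand_words = _kmer_set(cand.seq, prefilter_k) if prefilter_k else None
        placed = False
        for idx, cl in enumerate(clusters):
            if len(cand) / cl.rep_len < min_len_ratio:
                continue
            if cand_words is not None and not (cand_words & rep_words[idx]):
                continue
            if best_strand_identity(cand.seq, by_id[cl.rep_id].seq) >= min_identity:
                cl.member_ids.append(cand.id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(rep_id=cand.id, member_ids=[cand.id], rep_len=len(cand)))
            rep_words.append(cand_words if cand_words is not None else frozenset())
    return clusters


def representatives(
    clusters: Sequence[Cluster], contigs: Sequence[SequenceRecord]
) -> list[SequenceRecord]:
    """The non-redundant set: one (longest) sequence per cluster, longest first."""
    by_id = {c.id: c for c in contigs}
    reps = [by_id[cl.rep_id] for cl in clusters]
    return sorted(reps, key=lambda r: (-len(r), r.id))


def cluster_stats(clusters: Sequence[Cluster], bin_width: int = 500) -> ClusterStats:
    n = len(clusters)
    singletons = sum(1 for cl in clusters if len(cl.member_ids) == 1)
    hist: dict[int, int] = {}
    for cl in clusters:
        b = (cl.rep_len // bin_width) * bin_width
        hist[b] = hist.get(b, 0) + 1
    return ClusterStats(
        n_clusters=n,
        n_members=sum(len(cl.member_ids) for cl in clusters),
        singleton_fraction=singletons / n if n else 0.0,
        rep_length_histogram=dict(sorted(hist.items())),
    )
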