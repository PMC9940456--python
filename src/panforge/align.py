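"""Pairwise-alignment helpers shared by vector screening and clustering.

Identity between two sequences uses the edit-distance convention of greedy
clustering tools: align the shorter sequence against the longer in infix
mode and define identity = 1 - edit_distance / len(shorter).  The backend is
edlib; the definition, not the backend, is the contract.
"""

from __future__ import annotations

import edlib

from .records import revcomp


def infix_identity(a: str, b: str) -> float:
    """Identity of the shorter of ``a``/``b`` aligned anywhere inside the longer."""
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    d = edlib.align(query, target, mode="HW", task="distance")["editDistance"]
    return 1.0 - d / len(query)


def best_strand_identity(a: str, b: str) -> float:
    """Infix identity over both strands (the better of forward and reverse)."""
    fwd = infix_identity(a, b)
    if fwd == 1.0:
        return fwd
    return max(fwd, infix_identity(revcomp(a), b))


def locate_infix(query: str, target: str) -> tuple[int, int, int]:
    """Best infix placement of ``query`` in ``target``.

    Returns (edit_distance, t_start, t_end) with a 0-based half-open target
    interval.  Raises ValueError if query is longer than target.
    """
    if len(query) > len(target):
        raise ValueError("query longer than target in infix alignment")
    res = edlib.align(query, target, mode="HW", task="locations")
    start, end = res["locations"][0]
    return res["editDistance"], start, end + 1


def ungapped_local_match(
    query: str,
    target: str,
    min_identity: float,
    min_match_len: int,
    seed_len: int = 12,
) -> bool:
    """Is there an ungapped local match of length >= min_match_len at >= min_identity?

    Seed-and-extend: exact ``seed_len``-mers shared between query and target
    seed an ungapped extension in both directions; the extension keeps the
    longest window whose identity stays above the threshold.  Suited to
    adapter/vector contamination, which is near-exact and indel-free.
    """
    if min(len(query), len(target)) < min_match_len:
        return False
    seeds: dict[str, list[int]] = {}
    for i in range(len(query) - seed_len + 1):
        seeds.setdefault(query[i : i + seed_len], []).append(i)
    checked: set[tuple[int, int]] = set()
    for j in range(len(target) - seed_len + 1):
        word = target[j : j + seed_len]
        for i in seeds.get(word, ()):  # diagonal = j - i
            diag = j - i
            # one extension per diagonal is enough for ungapped matches
            lo = max(0, -diag)
            if (diag, lo) in checked:
                continue
            checked.add((diag, lo))
            if _extend_diagonal(query, target, diag, min_identity, min_match_len):
                return True
    return False


def _extend_diagonal(
    query: str, target: str, diag: int, min_identity: float, min_match_len: int
) -> bool:
    """Scan one diagonal for a window meeting the identity/length gates.

    Uses the maximal-scoring-window trick: with score +1 per match and
    -min_identity/(1-min_identity) per mismatch, a window has identity >=
    threshold iff its score >= min_match_len * identity-weighted floor; we
    simply test every Kadane-style positive run against both gates.
    """
    q_lo = max(0, -diag)
    q_hi = min(len(query), len(target) - diag)
    if q_hi - q_lo < min_match_len:
        return False
    mismatch_cost = min_identity / (1.0 - min_identity) if min_identity < 1.0 else None
    start = q_lo
    score = 0.0
    matches = 0
    length = 0
    for q in range(q_lo, q_hi):
        hit = query[q] == target[q + diag]
        if mismatch_cost is None:
            if hit:
                length += 1
                if length >= min_match_len:
                    return True
            else:
                length = 0
            continue
        score += 1.0 if hit else -mismatch_cost
        matches += int(hit)
        length += 1
        if score < 0:
            score, matches, length = 0.0, 0, 0
            start = q + 1
        elif length >= min_match_len and matches / length >= min_identity:
            return True
    return False
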