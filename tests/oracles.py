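"""Independent oracles used by the test suite.

Each oracle is a straightforward, brute-force or third-party
implementation kept deliberately separate from the package code paths it
checks.
"""

from __future__ import annotations

import math
from itertools import permutations

from Bio import Align


def sw_aligner(match=1, mismatch=-1, gap_open=2, gap_extend=1):
    """Biopython local aligner with the package's gap convention
    (a gap of length g costs gap_open + g * gap_extend)."""
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = -(gap_open + gap_extend)
    a.extend_gap_score = -gap_extend
    return a


def sw_best_score(query: str, subject: str, **scores) -> int:
    """Best local-alignment score over both subject strands."""
    comp = str.maketrans("ACGTN", "TGCAN")
    rc = subject.translate(comp)[::-1]
    a = sw_aligner(**scores)
    return int(max(a.score(query, subject), a.score(query, rc)))


def brute_force_overlaps(intervals, start, end):
    """All (start, end, payload) triples overlapping [start, end)."""
    return [iv for iv in intervals if iv[0] < end and start < iv[1]]


def interval_union_bp(region_start, region_end, intervals) -> int:
    """Covered bp of [region_start, region_end) by a union, by marking."""
    covered = [False] * (region_end - region_start)
    for s, e in intervals:
        for p in range(max(s, region_start), min(e, region_end)):
            covered[p - region_start] = True
    return sum(covered)


def enumerate_dinuc_arrangements(seq: str) -> set[str]:
    """All distinct sequences with identical dinucleotide counts, same
    first base, via exhaustive search over edge orderings (small inputs)."""
    edges = list(zip(seq, seq[1:]))
    results: set[str] = set()
    n = len(edges)

    def walk(cur: str, remaining: list[tuple[str, str]], acc: str):
        if not remaining:
            results.add(acc)
            return
        seen_next = set()
        for i, (a, b) in enumerate(remaining):
            if a != cur or b in seen_next:
                continue
            seen_next.add(b)
            walk(b, remaining[:i] + remaining[i + 1:], acc + b)

    walk(seq[0], edges, seq[0])
    return results


def binomial_tail_gt(k: int, n: int, p: float) -> float:
    """P(X > k) for X ~ Binomial(n, p), by direct summation."""
    total = 0.0
    for i in range(k + 1, n + 1):
        total += math.comb(n, i) * p ** i * (1 - p) ** (n - i)
    return total


def selection_oracle(candidates, min_species_support=2):
    """Step-by-step application of the cross-species selection rules to a
    list of (species, anchor_pair, evalue, chrom, start) tuples; returns
    {species: (anchor_pair, evalue, chrom, start)}.
    """
    # rule 1: locus groups are keyed by the anchor pair
    support: dict[tuple, set] = {}
    for sp, ap, ev, chrom, start in candidates:
        support.setdefault(ap, set()).add(sp)
    # rule 2: drop single-species groups
    alive = {ap for ap, sps in support.items()
             if len(sps) >= min_species_support}
    out = {}
    species = {c[0] for c in candidates}
    for sp in species:
        mine = [c for c in candidates if c[0] == sp and c[1] in alive]
        if not mine:
            continue
        # rule 3: most supporting species; rule 4: lowest evalue;
        # rule 5: smallest (chrom, start)
        best = min(mine, key=lambda c: (-len(support[c[1]]), c[2], c[3], c[4]))
        out[sp] = (best[1], best[2], best[3], best[4])
    return out
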