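"""Independent brute-force oracles used across the test suite.

These deliberately reimplement, from first principles and with different
libraries/data structures than the package, the quantities the package
computes: an exhaustive affine-gap local-alignment DP, a transitive-closure
partitioner, and small group-by reducers.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal Smith-Waterman score, affine gaps (gap of length g costs
    gap_open + g * gap_extend), plain Gotoh recurrences in pure Python."""
    first_gap = gap_open + gap_extend
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - first_gap, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first_gap, Y[i][j - 1] - gap_extend)
            s = _BLOSUM62[a[i - 1]][b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            best = max(best, M[i][j])
    return int(best)


def closure_partition(nodes, edges) -> set[frozenset]:
    """Connected components by repeated pairwise block merging (transitive
    closure), independent of any graph library."""
    blocks = [{n} for n in nodes]
    for u, v in edges:
        bu = next(b for b in blocks if u in b)
        bv = next(b for b in blocks if v in b)
        if bu is not bv:
            bu |= bv
            blocks.remove(bv)
    return {frozenset(b) for b in blocks}


def group_min_evalue(hits):
    """Best hit per unordered pair: (min evalue, max bit) via plain dicts."""
    best = {}
    for h in hits:
        key = frozenset((h.query_id, h.subject_id))
        cur = best.get(key)
        if cur is None or (h.evalue, -h.bit_score) < (cur.evalue, -cur.bit_score):
            best[key] = h
    return best
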