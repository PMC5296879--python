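"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: alignment scores by
exhaustive path enumeration, binomial tails by enumerating outcomes,
clustering by recomputing cluster distances from raw points at every step.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Exhaustive global alignment
# ---------------------------------------------------------------------------

def exhaustive_alignment_optima(seq_a, seq_b, scoring):
    """All optimal global alignments by depth-first path enumeration.

    Returns (best_score, list of aligned-pair tuples), one tuple of
    (pos_a, pos_b) residue pairs per optimal alignment. Affine gaps: a run
    of length L costs gap_open + (L-1)*gap_extend.
    """
    match, mismatch, gap_open, gap_extend = scoring
    n, m = len(seq_a), len(seq_b)
    best = [-math.inf]
    optima = []

    def step(i, j, prev, score, pairs):
        if i == n and j == m:
            if score > best[0]:
                best[0] = score
                optima.clear()
            if score == best[0]:
                optima.append(tuple(pairs))
            return
        if i < n and j < m:
            s = match if seq_a[i] == seq_b[j] else mismatch
            pairs.append((i + 1, j + 1))
            step(i + 1, j + 1, "D", score + s, pairs)
            pairs.pop()
        if i < n:
            cost = gap_extend if prev == "U" else gap_open
            step(i + 1, j, "U", score + cost, pairs)
        if j < m:
            cost = gap_extend if prev == "L" else gap_open
            step(i, j + 1, "L", score + cost, pairs)

    step(0, 0, None, 0.0, [])
    return best[0], optima


# ---------------------------------------------------------------------------
# Binomial tail by outcome enumeration
# ---------------------------------------------------------------------------

def enumerated_binomial_tail(observed, n, p):
    """Directional tail by summing exact pmf terms via math.comb."""
    def pmf(k):
        return math.comb(n, k) * p**k * (1 - p) ** (n - k)

    upper = sum(pmf(k) for k in range(observed, n + 1))
    lower = sum(pmf(k) for k in range(0, observed + 1))
    expected = n * p
    if observed > expected:
        return min(upper, 1.0)
    if observed < expected:
        return min(lower, 1.0)
    return min(upper, lower, 1.0)


# ---------------------------------------------------------------------------
# Brute-force complete-linkage agglomeration
# ---------------------------------------------------------------------------

def brute_force_complete_linkage(points):
    """Nearest-pair agglomeration recomputing distances from raw points.

    ``points`` maps label -> 1-D numpy array. Cluster-to-cluster distance
    is the max pairwise euclidean distance between members (recomputed from
    scratch each step, no update formula). Ties break on the
    lexicographically smallest (rep_a, rep_b). Returns a list of
    (members_a, members_b, height).
    """
    clusters = {lab: (lab,) for lab in points}

    def cluster_distance(members_a, members_b):
        return max(
            float(np.linalg.norm(points[x] - points[y]))
            for x, y in itertools.product(members_a, members_b)
        )

    merges = []
    while len(clusters) > 1:
        reps = sorted(clusters)
        best = None
        for a, b in itertools.combinations(reps, 2):
            d = cluster_distance(clusters[a], clusters[b])
            cand = (d, a, b)
            if best is None or cand < best:
                best = cand
        d, a, b = best
        members_a, members_b = clusters.pop(a), clusters.pop(b)
        merges.append((members_a, members_b, d))
        clusters[min(a, b)] = members_a + members_b
    return merges


# ---------------------------------------------------------------------------
# Sequon truth table
# ---------------------------------------------------------------------------

def sequon_ok(triplet):
    return triplet[0] == "N" and triplet[1] != "P" and triplet[2] in "ST"
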