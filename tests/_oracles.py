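"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own algorithms: costs come from
exhaustive enumeration, never from the code under test.
"""

from collections import Counter
from itertools import permutations, product


def exhaustive_kmodes_cost(rows, k):
    """Minimum total Hamming cost over every assignment of the patterns to
    at most k clusters, with each cluster's mode chosen optimally
    (per-position majority symbol)."""
    n, length = len(rows), len(rows[0])
    best = None
    for assign in product(range(k), repeat=n):
        cost = 0
        for j in range(k):
            members = [rows[i] for i in range(n) if assign[i] == j]
            if not members:
                continue
            for pos in range(length):
                counts = Counter(m[pos] for m in members)
                cost += len(members) - max(counts.values())
        if best is None or cost < best:
            best = cost
    return best


def brute_force_matched_count(contingency):
    """Maximum matched sum over injective row-to-column correspondences of a
    contingency matrix, by enumerating permutations of the larger side."""
    n_rows = len(contingency)
    n_cols = len(contingency[0])
    best = 0
    if n_rows <= n_cols:
        for cols in permutations(range(n_cols), n_rows):
            best = max(best, sum(contingency[i][c] for i, c in enumerate(cols)))
    else:
        for rows in permutations(range(n_rows), n_cols):
            best = max(best, sum(contingency[r][j] for j, r in enumerate(rows)))
    return best
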