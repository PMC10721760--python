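"""Independent brute-force oracles used only by the tests.

These re-derive the quantities the package computes by direct definition:
Ward agglomeration by exhaustively minimizing the within-cluster
sum-of-squares increase over all merge candidates, and the hypergeometric
upper tail by enumerating every possible query draw from the universe.
"""

from itertools import combinations

import numpy as np


def ward_merge_partitions(points: np.ndarray) -> list[list[frozenset]]:
    """Agglomerate by exhaustive search over merges.

    At each step, merge the pair of clusters whose union minimizes the
    increase in total within-cluster sum of squared distances to the
    centroid (Ward's criterion).  Returns the partition after every merge
    as sets of point-index frozensets.
    """
    clusters = [frozenset([i]) for i in range(len(points))]
    partitions = []
    while len(clusters) > 1:
        best = None
        best_cost = np.inf
        for a, b in combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            pa = points[list(ca)]
            pb = points[list(cb)]
            na, nb = len(ca), len(cb)
            delta = (na * nb / (na + nb)) * np.sum(
                (pa.mean(axis=0) - pb.mean(axis=0)) ** 2
            )
            if delta < best_cost:
                best_cost = delta
                best = (a, b)
        a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
        partitions.append(sorted(clusters, key=lambda c: sorted(c)))
    return partitions


def linkage_partitions(Z: np.ndarray, n: int) -> list[list[frozenset]]:
    """Replay a scipy linkage matrix into the same partition sequence."""
    clusters = {i: frozenset([i]) for i in range(n)}
    partitions = []
    for step, (a, b, _, _) in enumerate(Z):
        merged = clusters.pop(int(a)) | clusters.pop(int(b))
        clusters[n + step] = merged
        partitions.append(sorted(clusters.values(), key=lambda c: sorted(c)))
    return partitions


def hypergeom_tail_by_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by enumerating all C(N, n) query draws.

    The universe is range(N); the first K elements carry the term.
    """
    term = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(term.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0
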