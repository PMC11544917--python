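"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: the Ward oracle
evaluates the explicit within-cluster variance-increase definition for every
candidate pair at every step; the medoid oracle enumerates distance sums with
plain loops; the Holt grid oracle runs the scalar recursion per grid point.
"""

from __future__ import annotations

import numpy as np


def ward_oracle_partitions(series: np.ndarray) -> list[list[frozenset]]:
    """Greedy Ward merge sequence by exhaustive variance-increase evaluation.

    Returns the partition (list of frozensets of leaf indices) after every
    merge. Ties break to the first candidate pair in scan order (ties have
    probability zero for continuous random input).
    """
    series = np.asarray(series, dtype=float)
    clusters: list[set[int]] = [{i} for i in range(series.shape[0])]

    def ess(members: set[int]) -> float:
        pts = series[sorted(members)]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    partitions = []
    while len(clusters) > 1:
        best, best_cost = None, np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                cost = ess(clusters[i] | clusters[j]) - ess(clusters[i]) - ess(clusters[j])
                if cost < best_cost:
                    best, best_cost = (i, j), cost
        i, j = best
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
        partitions.append([frozenset(c) for c in clusters])
    return partitions


def linkage_partitions(merges, n_leaves: int) -> list[list[frozenset]]:
    """Partition after every merge of a linkage history (scipy id convention)."""
    members = {i: frozenset([i]) for i in range(n_leaves)}
    partitions = []
    for step, (a, b, _) in enumerate(merges):
        members[n_leaves + step] = members.pop(a) | members.pop(b)
        partitions.append(list(members.values()))
    return partitions


def same_partition(p: list[frozenset], q: list[frozenset]) -> bool:
    return set(p) == set(q)


def medoid_oracle(series: np.ndarray, member_idx: np.ndarray) -> int:
    """Exhaustive argmin of summed Euclidean distances within one cluster."""
    best_idx, best_sum = None, np.inf
    for i in member_idx:
        total = 0.0
        for j in member_idx:
            total += float(np.sqrt(((series[i] - series[j]) ** 2).sum()))
        if total < best_sum:
            best_idx, best_sum = i, total
    return int(best_idx)


def holt_sse_oracle(y: np.ndarray, alpha: float, beta: float) -> float:
    """Scalar one-step-ahead SSE of the Holt recursion on one series."""
    level, trend = y[0], y[1] - y[0]
    sse = 0.0
    for t in range(1, len(y)):
        forecast = level + trend
        sse += (y[t] - forecast) ** 2
        new_level = alpha * y[t] + (1 - alpha) * forecast
        trend = beta * (new_level - level) + (1 - beta) * trend
        level = new_level
    return sse
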