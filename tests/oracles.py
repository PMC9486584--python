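"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the production code:
exhaustive permutation enumeration for path scores, exhaustive label
enumeration for the exact Mann-Whitney p-value, and dense power iteration
for weighted PageRank.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np


def bruteforce_integrated_score(graph, u, v, L: int) -> float:
    """Eq.-style score by enumerating every ordered tuple of intermediates."""
    others = [n for n in graph.nodes if n not in (u, v)]
    total = 0.0
    for l in range(1, L + 1):
        prods = []
        for mids in permutations(others, l - 1):
            path = (u, *mids, v)
            if all(graph.has_edge(a, b) for a, b in zip(path, path[1:])):
                prods.append(
                    math.prod(
                        graph.edges[a, b]["weight"] for a, b in zip(path, path[1:])
                    )
                )
        if prods:
            total += sum(prods) / len(prods)
    return total


def exact_mwu_p_two_sided(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Assumes no ties across the pooled sample. The U statistic of group `a`
    is compared against its exhaustive permutation distribution.
    """
    a, b = list(a), list(b)
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n_a = len(a)

    def u_of(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_of(a, b)
    n_ab = n_a * len(b)
    # two-sided: distance of U from its mean
    d_obs = abs(u_obs - n_ab / 2)
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        d = abs(u_of(ga, gb) - n_ab / 2)
        total += 1
        if d >= d_obs - 1e-12:
            count += 1
    return count / total


def power_iteration_pagerank(graph, damping: float = 0.85, tol: float = 1e-12):
    """Weighted PageRank by dense power iteration on the undirected graph."""
    nodes = list(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        W[idx[u], idx[v]] = w
        W[idx[v], idx[u]] = w
    out = W.sum(axis=1)
    P = np.zeros((n, n))
    dangling = out == 0
    for i in range(n):
        if not dangling[i]:
            P[i] = W[i] / out[i]
    p = np.full(n, 1 / n)
    while True:
        p_new = (1 - damping) / n + damping * (
            P.T @ p + p[dangling].sum() / n
        )
        if np.abs(p_new - p).max() < tol:
            break
        p = p_new
    return {v: p[idx[v]] for v in nodes}
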