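"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive exhaustive enumeration rather than any code
path from the package's algorithms.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def ssd(values) -> float:
    v = np.asarray(values, dtype=float)
    return float(((v - v.mean()) ** 2).sum())


def brute_force_jenks(values, k):
    """Optimal k-class SSD and upper break values by trying every contiguous
    split of the sorted data."""
    x = sorted(float(v) for v in values)
    n = len(x)
    best = (np.inf, None)
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        parts = [x[i:j] for i, j in zip(bounds, bounds[1:])]
        total = sum(ssd(p) for p in parts)
        if total < best[0] - 1e-12:
            best = (total, [p[-1] for p in parts[:-1]])
    return best


def all_partitions_into_k(nodes, k):
    """Every set partition of ``nodes`` into exactly k non-empty blocks
    (restricted-growth-string enumeration)."""
    nodes = list(nodes)
    n = len(nodes)

    def rec(i, blocks):
        if i == n:
            if len(blocks) == k:
                yield [list(b) for b in blocks]
            return
        if len(blocks) + (n - i) < k:
            return
        for b in blocks:
            b.append(nodes[i])
            yield from rec(i + 1, blocks)
            b.pop()
        if len(blocks) < k:
            blocks.append([nodes[i]])
            yield from rec(i + 1, blocks)
            blocks.pop()

    yield from rec(0, [])


def contiguous_partitions(graph: nx.Graph, k: int):
    """All partitions of the graph's nodes into k connected blocks."""
    for blocks in all_partitions_into_k(graph.nodes, k):
        if all(nx.is_connected(graph.subgraph(b)) for b in blocks):
            yield blocks


def partition_cost(blocks, mos, h, a, mean_mos, tol, hw=1.0, mw=100.0):
    """Same penalized objective the solver reports, computed independently."""
    total = 0.0
    for b in blocks:
        hv = np.array([h[u] for u in b])
        av = np.array([a[u] for u in b])
        total += hw * (hv.var() + av.var())
        rel = abs(sum(mos[u] for u in b) - mean_mos) / mean_mos
        total += mw * max(0.0, rel - tol) ** 2
    return total
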