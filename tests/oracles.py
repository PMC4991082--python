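"""Independent brute-force oracles used by the test-suite.

Everything here is written for clarity at tiny problem sizes and stays
independent of the implementation paths it checks: shortest paths by
explicit enumeration, graphlet orbits by exhaustive induced-subgraph
enumeration, the JT null by exhaustive permutation, and hypergeometric
probabilities by big-integer binomial arithmetic.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from math import comb

import networkx as nx
import numpy as np


# ---------------------------------------------------------------- rhythm ----


def jt_statistic_brute(y, ref) -> int:
    s = 0
    n = len(y)
    for i in range(n):
        for j in range(i + 1, n):
            if ref[i] == ref[j]:
                continue
            s += int(np.sign(ref[j] - ref[i]) * np.sign(y[j] - y[i]))
    return s


def jt_null_by_permutation(ref) -> dict[int, float]:
    """Exact P(S = s) by enumerating all n! arrangements of distinct data."""
    n = len(ref)
    base = list(range(n))
    counts: dict[int, int] = defaultdict(int)
    total = 0
    for perm in itertools.permutations(base):
        counts[jt_statistic_brute(perm, ref)] += 1
        total += 1
    return {s: c / total for s, c in counts.items()}


def two_sided_p_from_null(null: dict[int, float], s_obs: int) -> float:
    return sum(p for s, p in null.items() if abs(s) >= abs(s_obs))


def bh_brute(p):
    """Step-up BH by direct definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


# ---------------------------------------------------------------- graphs ----


def all_pairs_distances_brute(g: nx.Graph, nodes):
    """BFS-free Floyd-Warshall distances."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    for u, v in g.edges():
        d[idx[u], idx[v]] = 1
        d[idx[v], idx[u]] = 1
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k][None, :])
    return d


def betweenness_brute(g: nx.Graph, nodes):
    """Fractional shortest-path counts by enumerating all simple paths."""
    d = all_pairs_distances_brute(g, nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    bw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        ds_t = d[idx[s], idx[t]]
        if not np.isfinite(ds_t):
            continue
        shortest = [
            p
            for p in nx.all_simple_paths(g, s, t, cutoff=int(ds_t))
            if len(p) - 1 == ds_t
        ]
        for p in shortest:
            for v in p[1:-1]:
                bw[v] += 1.0 / len(shortest)
    return bw

def clustering_brute(g: nx.Graph, nodes):
    out = {}
    for v in nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def kcore_brute(g: nx.Graph, nodes):
    """Largest k such that the node survives iterative k-degree pruning."""
    out = {}
    for v in nodes:
        k = 0
        while True:
            h = g.copy()
            changed = True
            while changed:
                changed = False
                low = [u for u in h.nodes if h.degree(u) < k + 1]
                if low:
                    h.remove_nodes_from(low)
                    changed = True
            if v in h.nodes:
                k += 1
            else:
                break
        out[v] = float(k)
    return out


# 15-orbit classification: (sorted degree sequence of the induced subgraph,
# node's own degree within it) identifies the orbit for 2-4-node graphlets.
_ORBIT_BY_SIGNATURE = {
    ((1, 1), 1): 0,
    ((1, 1, 2), 1): 1,
    ((1, 1, 2), 2): 2,
    ((2, 2, 2), 2): 3,
    ((1, 1, 2, 2), 1): 4,
    ((1, 1, 2, 2), 2): 5,
    ((1, 1, 1, 3), 1): 6,
    ((1, 1, 1, 3), 3): 7,
    ((2, 2, 2, 2), 2): 8,
    ((1, 2, 2, 3), 1): 9,
    ((1, 2, 2, 3), 2): 10,
    ((1, 2, 2, 3), 3): 11,
    ((2, 2, 3, 3), 2): 12,
    ((2, 2, 3, 3), 3): 13,
    ((3, 3, 3, 3), 3): 14,
}


def graphlet_orbits_brute(g: nx.Graph, nodes):
    """Exhaustive enumeration of connected induced 2-4-node subgraphs."""
    counts = np.zeros((len(nodes), 15), dtype=int)
    idx = {v: i for i, v in enumerate(nodes)}
    for size in (2, 3, 4):
        for combo in itertools.combinations(nodes, size):
            sub = g.subgraph(combo)
            if not nx.is_connected(sub):
                continue
            degs = tuple(sorted(d for _, d in sub.degree()))
            for v in combo:
                orbit = _ORBIT_BY_SIGNATURE[(degs, sub.degree(v))]
                counts[idx[v], orbit] += 1
    return counts


# --------------------------------------------------------- combinatorics ----


def hypergeom_upper_tail_exact(overlap, universe, n_a, n_b):
    """P(X >= overlap) with big-integer binomials."""
    total = comb(universe, n_b)
    hi = min(n_a, n_b)
    num = sum(comb(n_a, k) * comb(universe - n_a, n_b - k) for k in range(overlap, hi + 1))
    from fractions import Fraction

    return float(Fraction(num, total))


def mutual_information_brute(joint):
    """MI in bits from a joint count table, by the definition."""
    joint = np.asarray(joint, dtype=float)
    n = joint.sum()
    mi = 0.0
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            pij = joint[i, j] / n
            if pij == 0:
                continue
            pi = joint[i].sum() / n
            pj = joint[:, j].sum() / n
            mi += pij * np.log2(pij / (pi * pj))
    return mi
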