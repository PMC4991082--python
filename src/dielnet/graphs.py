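"""Node centralities, graphlet degree, and Markov clustering.

Seven centrality measures are exposed: betweenness (unnormalized
shortest-path pair counts), closeness ((n-1)/sum of distances), clustering
coefficient, degree, eccentricity, graphlet degree, and k-coreness.  All
assume a connected input (use ``largest_component`` first); betweenness is
delegated to igraph and distance-based measures to scipy's C BFS, while
graphlet orbit counting and MCL are implemented here.

Graphlet degree centrality summarizes a node's 15 automorphism-orbit counts
over the connected 2-4-node graphlets (edge; 3-path; triangle; 4-path;
claw; 4-cycle; paw; diamond; K4):

    GDC(v) = sum_i w_i * log(d_i(v) + 1),   w_i = 1 - log(o_i)/log(15),

where d_i is the count of orbit i at v and o_i is the number of orbits that
orbit i depends on (the distinct orbits a node at orbit i necessarily
touches within that graphlet, itself included).

Orbit counts are exact and computed combinatorially: triangle-anchored
quantities by an edge-at-a-time sweep over common-neighbour bitsets, the
remaining orbits by inclusion-exclusion identities on walk counts; a
brute-force subgraph-enumeration oracle in the test-suite checks every
connected graph on <= 7 nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph

from .networks import CoexpressionNetwork

__all__ = [
    "CENTRALITY_MEASURES",
    "ORBIT_DEPENDENCIES",
    "centrality",
    "centrality_table",
    "graphlet_orbit_counts",
    "graphlet_degree",
    "Clustering",
    "mcl_cluster",
]

CENTRALITY_MEASURES = (
    "betweenness",
    "closeness",
    "clustering_coefficient",
    "degree",
    "eccentricity",
    "graphlet_degree",
    "k_coreness",
)

# o_i: orbits a node at orbit i necessarily touches within its own graphlet
# (derived by enumerating induced subgraphs of each graphlet; see methods).
ORBIT_DEPENDENCIES = np.array([1, 2, 2, 2, 3, 4, 3, 3, 4, 3, 4, 4, 4, 4, 3])
ORBIT_WEIGHTS = 1.0 - np.log(ORBIT_DEPENDENCIES) / np.log(15.0)


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, CoexpressionNetwork) else net


def _require_connected(g: nx.Graph) -> None:
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(g):
        raise ValueError(
            "network is disconnected; extract the largest connected component "
            "first (largest_component)"
        )


def _distance_matrix(g: nx.Graph, nodes: list) -> np.ndarray:
    adj = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr", dtype=np.float64)
    return csgraph.shortest_path(adj, method="D", unweighted=True)


def centrality(net, measure: str) -> dict:
    """One centrality measure for every node of a connected network."""
    g = _as_graph(net)
    _require_connected(g)
    nodes = sorted(g.nodes)
    n = len(nodes)
    if measure == "degree":
        return {v: float(g.degree(v)) for v in nodes}
    if measure == "clustering_coefficient":
        cc = nx.clustering(g)
        return {v: float(cc[v]) for v in nodes}
    if measure == "k_coreness":
        core = nx.core_number(g)
        return {v: float(core[v]) for v in nodes}
    if measure == "betweenness":
        index = {v: i for i, v in enumerate(nodes)}
        h = ig.Graph(n=n, edges=[(index[u], index[v]) for u, v in g.edges()])
        bw = h.betweenness(directed=False)
        return {v: float(b) for v, b in zip(nodes, bw)}
    if measure in ("closeness", "eccentricity"):
        d = _distance_matrix(g, nodes)
        if measure == "closeness":
            vals = (n - 1) / d.sum(axis=1) if n > 1 else np.ones(1)
        else:
            vals = d.max(axis=1)
        return {v: float(x) for v, x in zip(nodes, vals)}
    if measure == "graphlet_degree":
        counts = graphlet_orbit_counts(g, nodes)
        gdc = (ORBIT_WEIGHTS * np.log(counts + 1.0)).sum(axis=1)
        return {v: float(x) for v, x in zip(nodes, gdc)}
    raise ValueError(f"unknown centrality measure {measure!r}")


def centrality_table(net, measures=CENTRALITY_MEASURES) -> pd.DataFrame:
    """All requested measures as a nodes x measures DataFrame."""
    g = _as_graph(net)
    _require_connected(g)
    nodes = sorted(g.nodes)
    data = {m: centrality(g, m) for m in measures}
    return pd.DataFrame({m: [data[m][v] for v in nodes] for m in measures},
                        index=pd.Index(nodes, name="gene"))


def _pack_bits(adj_bool: np.ndarray) -> np.ndarray:
    n = adj_bool.shape[0]
    w = (n + 63) // 64
    packed = np.zeros((n, w), dtype=np.uint64)
    idx = np.arange(n)
    words = idx // 64
    bits = (idx % 64).astype(np.uint64)
    for v in range(n):
        nbrs = np.flatnonzero(adj_bool[v])
        np.bitwise_or.at(packed[v], words[nbrs], np.uint64(1) << bits[nbrs])
    return packed


def graphlet_orbit_counts(g: nx.Graph, nodes: list | None = None) -> np.ndarray:
    """Exact per-node counts of the 15 orbits of 2-4-node graphlets.

    Returns an (n, 15) integer array aligned with ``nodes`` (default:
    sorted node order).
    """
    if nodes is None:
        nodes = sorted(g.nodes)
    n = len(nodes)
    counts = np.zeros((n, 15), dtype=np.int64)
    if n == 0 or g.number_of_edges() == 0:
        return counts
    adj_bool = nx.to_numpy_array(g, nodelist=nodes, dtype=bool)
    np.fill_diagonal(adj_bool, False)
    a = adj_bool.astype(np.float32)
    d = adj_bool.sum(axis=1).astype(np.int64)
    cn = np.rint(a @ a).astype(np.int64)  # common-neighbour counts
    iu, ju = np.nonzero(np.triu(adj_bool, k=1))
    c_e = cn[iu, ju]

    # triangles per node: each edge carries c_e triangles, two edges per triangle
    t = np.zeros(n, dtype=np.int64)
    np.add.at(t, iu, c_e)
    np.add.at(t, ju, c_e)
    t //= 2

    counts[:, 0] = d
    counts[:, 1] = a @ (d - 1) - 2 * t
    counts[:, 2] = d * (d - 1) // 2 - t
    counts[:, 3] = t

    packed = _pack_bits(adj_bool)
    orbit10 = np.zeros(n, dtype=np.int64)
    orbit12 = np.zeros(n, dtype=np.int64)
    orbit13 = np.zeros(n, dtype=np.int64)
    ssum_node = np.zeros(n, dtype=np.int64)
    sum_c2 = np.zeros(n, dtype=np.float64)
    np.add.at(sum_c2, iu, c_e.astype(np.float64) ** 2)
    np.add.at(sum_c2, ju, c_e.astype(np.float64) ** 2)

    for e in range(len(iu)):
        u, v = int(iu[e]), int(ju[e])
        if c_e[e] == 0:
            continue
        cnb = packed[u] & packed[v]
        w_idx = np.flatnonzero(adj_bool[u] & adj_bool[v])
        s_w = np.bitwise_count(packed[w_idx] & cnb).sum(axis=1).astype(np.int64)
        ke = int(s_w.sum())
        ssum_node[u] += ke
        ssum_node[v] += ke
        # diamonds: w sits opposite the hub edge (u, v)
        np.add.at(orbit12, w_idx, c_e[e] - 1 - s_w)
        # K4s on this hub edge = adjacent pairs among common neighbours
        k4_on_e = ke // 2
        orbit13[u] += c_e[e] * (c_e[e] - 1) // 2 - k4_on_e
        orbit13[v] += c_e[e] * (c_e[e] - 1) // 2 - k4_on_e
        # paw attribution: w receives the pendant counts hanging at u and v
        pend = (
            (d[u] + d[v] - 2 * c_e[e])
            - cn[u, w_idx]
            - cn[v, w_idx]
            + 2 * s_w
        )
        np.add.at(orbit10, w_idx, pend)

    orbit14 = ssum_node // 6
    counts[:, 14] = orbit14
    counts[:, 12] = orbit12
    counts[:, 13] = orbit13
    counts[:, 10] = orbit10
    counts[:, 11] = t * (d - 2) - (sum_c2.astype(np.int64) - 2 * t) + 3 * orbit14

    # pendant-of-paw via triangle-at-neighbour walks
    tp = (a @ t.astype(np.float32)).astype(np.int64) - 2 * t
    orbit9 = tp - 2 * orbit12 - 3 * orbit14
    counts[:, 9] = orbit9

    # claw orbits
    sum_cc2 = np.zeros(n, dtype=np.int64)  # sum over edges of C(c_e, 2), per node
    ce_pairs = c_e * (c_e - 1) // 2
    np.add.at(sum_cc2, iu, ce_pairs)
    np.add.at(sum_cc2, ju, ce_pairs)
    counts[:, 7] = (
        d * (d - 1) * (d - 2) // 6 - t * (d - 2) + sum_cc2 - orbit14
    )
    cl = (a @ ((d - 1) * (d - 2) // 2).astype(np.float32)).astype(np.int64)
    counts[:, 6] = (
        cl - orbit9 - orbit10 - 2 * orbit12 - orbit13 - 3 * orbit14
    )

    # 4-cycle from common-neighbour pairs over non-adjacent node pairs
    cn_pairs = cn * (cn - 1) // 2
    nonadj = ~adj_bool
    np.fill_diagonal(nonadj, False)
    counts[:, 8] = (cn_pairs * nonadj).sum(axis=1) - orbit12

    # 4-path orbits via vertex-distinct 3-walk identities
    s1 = (a @ (d - 1).astype(np.float32)).astype(np.int64)
    dp = (a @ s1.astype(np.float32)).astype(np.int64) - 2 * t - d * (d - 1)
    counts[:, 4] = (
        dp
        - 2 * counts[:, 8]
        - 2 * orbit9
        - orbit10
        - 4 * orbit12
        - 2 * orbit13
        - 6 * orbit14
    )
    pm = (d - 1) * s1 - 2 * t
    counts[:, 5] = (
        pm
        - orbit10
        - 2 * counts[:, 11]
        - 2 * counts[:, 8]
        - 2 * orbit12
        - 4 * orbit13
        - 6 * orbit14
    )
    return counts


def graphlet_degree(g: nx.Graph, nodes: list | None = None) -> np.ndarray:
    """Weighted-orbit graphlet degree centrality per node."""
    counts = graphlet_orbit_counts(g, nodes)
    return (ORBIT_WEIGHTS * np.log(counts + 1.0)).sum(axis=1)


@dataclass
class Clustering:
    """A partition of network nodes."""

    nodes: list
    labels: np.ndarray  # cluster id per node
    clusters: list[set]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": self.labels}, index=pd.Index(self.nodes, name="gene")
        )


def mcl_cluster(
    net,
    inflation: float = 2.0,
    tol: float = 1e-6,
    prune: float = 1e-8,
    max_iter: int = 200,
) -> Clustering:
    """Markov clustering on the binary self-loop-augmented adjacency matrix.

    Alternates expansion (matrix squaring) and inflation (elementwise power
    + column renormalization) until the maximum entry change drops below
    ``tol``; clusters are the connected components of the attractor
    structure.  Deterministic; edge weights are ignored.
    """
    g = _as_graph(net)
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    index = {v: i for i, v in enumerate(nodes)}
    rows, cols = [], []
    for u, v in g.edges():
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
    rows += list(range(n))
    cols += list(range(n))
    m = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    m = _normalize_columns(m)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = m.power(inflation)
        m = _normalize_columns(m)
        m.data[m.data < prune] = 0.0
        m.eliminate_zeros()
        m = _normalize_columns(m)
        delta = abs(m - prev).max() if (m - prev).nnz else 0.0
        if delta < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn("MCL did not converge; interpreting the current matrix")
    keep = m.tocoo()
    mask = keep.data >= tol
    attractor = sparse.csr_matrix(
        (np.ones(mask.sum()), (keep.row[mask], keep.col[mask])), shape=(n, n)
    )
    n_comp, labels = csgraph.connected_components(attractor, directed=False)
    # relabel deterministically by smallest member index
    first = {}
    for i, lab in enumerate(labels):
        first.setdefault(lab, i)
    order = sorted(first, key=lambda lab: first[lab])
    remap = {lab: k for k, lab in enumerate(order)}
    labels = np.array([remap[lab] for lab in labels])
    clusters = [set() for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        clusters[lab].add(nodes[i])
    return Clustering(nodes, labels, clusters)


def _normalize_columns(m: sparse.csr_matrix) -> sparse.csr_matrix:
    col_sums = np.asarray(m.sum(axis=0)).ravel()
    col_sums[col_sums == 0] = 1.0
    d = sparse.diags(1.0 / col_sums)
    return (m @ d).tocsr()
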