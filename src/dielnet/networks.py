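"""Co-expression network construction.

Nodes are genes; an edge links two genes whose temporal expression profiles
score highly under one of three similarity measures: signed Pearson
correlation, absolute Pearson correlation, or mutual information of the
binned profiles.  A network keeps the top K = multiplier x N scoring pairs
(N = number of scored genes); the standard set of five networks is
SIGN_N, ABS_N, MI_N and the intersections ABS_MI_10N and ABS_MI_25N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionNetwork",
    "ScoredPairs",
    "score_pairs",
    "mutual_information",
    "build_topk_network",
    "intersect_networks",
    "largest_component",
    "network_summary",
    "build_standard_networks",
    "STANDARD_TAGS",
]

STANDARD_TAGS = ("SIGN_N", "ABS_N", "MI_N", "ABS_MI_10N", "ABS_MI_25N")


@dataclass
class CoexpressionNetwork:
    """Simple undirected weighted graph over gene ids."""

    graph: nx.Graph
    method_tag: str
    k_multiplier: float | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tweight\n")
            for a, b, w in sorted(
                (min(u, v), max(u, v), d.get("weight", 1.0))
                for u, v, d in self.graph.edges(data=True)
            ):
                fh.write(f"{a}\t{b}\t{w:.6g}\n")

    @classmethod
    def read_edgelist(cls, path, method_tag: str = "") -> "CoexpressionNetwork":
        g = nx.Graph()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("gene_a"):
                raise ValueError("expected 'gene_a\\tgene_b\\tweight' header")
            for line in fh:
                a, b, w = line.rstrip("\n").split("\t")
                g.add_edge(a, b, weight=float(w))
        return cls(g, method_tag)


@dataclass
class ScoredPairs:
    """Condensed upper-triangle scores over a gene list (i < j)."""

    gene_ids: list[str]
    i: np.ndarray
    j: np.ndarray
    score: np.ndarray
    method: str

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def mutual_information(x, y, bins: int = 3) -> float:
    """Plug-in mutual information (bits) after per-vector equal-width binning."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if len(x) < bins:
        raise ValueError("need at least `bins` samples")
    bx = _equal_width_bins(x, bins)
    by = _equal_width_bins(y, bins)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (bx, by), 1.0)
    return _mi_from_joint(joint[None, :, :])[0]


def _equal_width_bins(x: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.zeros(len(x), dtype=np.int64)
    b = np.floor((x - lo) / (hi - lo) * bins).astype(np.int64)
    return np.minimum(b, bins - 1)


def _mi_from_joint(joint: np.ndarray) -> np.ndarray:
    """MI (bits) for a stack of joint count tables (m, B, B)."""
    n = joint.sum(axis=(1, 2), keepdims=True)
    p = joint / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return np.nansum(terms, axis=(1, 2))


def score_pairs(
    profiles: np.ndarray,
    gene_ids,
    method: str,
    mi_bins: int = 3,
) -> ScoredPairs:
    """Score all unordered gene pairs of a genes x points profile matrix.

    ``method`` is one of ``signed_pearson``, ``abs_pearson``,
    ``mutual_information``.  Zero-variance genes are excluded from Pearson
    scoring (logged); self-pairs are never scored.
    """
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[0] != len(gene_ids):
        raise ValueError("profiles must be genes x points matching gene_ids")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 profile points per gene")
    gene_ids = list(gene_ids)

    if method in ("signed_pearson", "abs_pearson"):
        centred = x - x.mean(axis=1, keepdims=True)
        ss = (centred * centred).sum(axis=1)
        keep = ss > 0
        if not keep.all():
            dropped = [g for g, k in zip(gene_ids, keep) if not k]
            logger.warning(
                "excluding %d zero-variance gene(s) from Pearson scoring: %s",
                len(dropped),
                dropped[:5],
            )
        idx = np.flatnonzero(keep)
        sub = centred[idx] / np.sqrt(ss[idx])[:, None]
        r = np.clip(sub @ sub.T, -1.0, 1.0)
        iu, ju = np.triu_indices(len(idx), k=1)
        score = r[iu, ju]
        if method == "abs_pearson":
            score = np.abs(score)
        return ScoredPairs(gene_ids, idx[iu], idx[ju], score, method)

    if method == "mutual_information":
        n, t = x.shape
        binned = np.stack([_equal_width_bins(row, mi_bins) for row in x])
        onehot = np.zeros((n, mi_bins, t), dtype=np.float32)
        for b in range(mi_bins):
            onehot[:, b, :] = binned == b
        i_list, j_list, s_list = [], [], []
        for g in range(n - 1):
            rest = onehot[g + 1 :]
            joint = np.einsum("bt,hct->hbc", onehot[g], rest)
            mi = _mi_from_joint(joint)
            i_list.append(np.full(n - g - 1, g))
            j_list.append(np.arange(g + 1, n))
            s_list.append(mi)
        return ScoredPairs(
            gene_ids,
            np.concatenate(i_list),
            np.concatenate(j_list),
            np.concatenate(s_list),
            method,
        )

    raise ValueError(f"unknown method {method!r}")


def build_topk_network(
    scores: ScoredPairs, k_multiplier: float, method_tag: str = ""
) -> CoexpressionNetwork:
    """Keep the K = multiplier x N highest-scoring pairs as edges.

    Ties at the K-th score are broken by lexicographic (gene_a, gene_b) pair
    id so the edge count is exactly K (unless K exceeds the number of scored
    pairs, in which case the complete graph is returned with a warning).
    """
    n = scores.n_genes
    k = int(round(k_multiplier * n))
    n_pairs = len(scores.score)
    # lexicographic pair identity for deterministic tie-breaks
    names = np.asarray(scores.gene_ids, dtype=object)
    lex_rank = np.empty(n, dtype=np.int64)
    lex_rank[np.argsort(names)] = np.arange(n)
    ra, rb = lex_rank[scores.i], lex_rank[scores.j]
    a = np.minimum(ra, rb)
    b = np.maximum(ra, rb)
    order = np.lexsort((b, a, -scores.score))
    if k >= n_pairs:
        if k > n_pairs:
            logger.warning(
                "K=%d exceeds the %d scored pairs; returning the complete graph",
                k,
                n_pairs,
            )
        take = order
    else:
        take = order[:k]
    g = nx.Graph()
    for idx in take:
        u = scores.gene_ids[scores.i[idx]]
        v = scores.gene_ids[scores.j[idx]]
        g.add_edge(u, v, weight=float(scores.score[idx]))
    tag = method_tag or f"{scores.method}_top{k_multiplier:g}N"
    return CoexpressionNetwork(g, tag, k_multiplier)


def intersect_networks(
    a: CoexpressionNetwork, b: CoexpressionNetwork, method_tag: str = ""
) -> CoexpressionNetwork:
    """Edge-set intersection; isolated nodes are dropped.

    Edge weights are taken from ``a``.
    """
    g = nx.Graph()
    for u, v, d in a.graph.edges(data=True):
        if b.graph.has_edge(u, v):
            g.add_edge(u, v, weight=d.get("weight", 1.0))
    tag = method_tag or f"({a.method_tag})&({b.method_tag})"
    return CoexpressionNetwork(g, tag, a.k_multiplier)


def largest_component(net: CoexpressionNetwork) -> CoexpressionNetwork:
    """Induced subgraph on the largest connected component.

    Size ties are broken toward the component containing the
    lexicographically smallest node id.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = list(nx.connected_components(net.graph))
    max_size = max(len(c) for c in comps)
    tied = [c for c in comps if len(c) == max_size]
    best = min(tied, key=lambda c: min(c))
    sub = net.graph.subgraph(best).copy()
    return CoexpressionNetwork(sub, net.method_tag, net.k_multiplier)


def network_summary(net: CoexpressionNetwork) -> dict:
    """Non-isolated nodes, edges, components, largest-component size, density."""
    g = net.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 0:
        return {
            "method": net.method_tag,
            "n_nodes": 0,
            "n_edges": 0,
            "n_components": 0,
            "lcc_nodes": 0,
            "lcc_edges": 0,
            "density": 0.0,
        }
    comps = list(nx.connected_components(g))
    lcc = max(comps, key=len)
    lcc_g = g.subgraph(lcc)
    return {
        "method": net.method_tag,
        "n_nodes": n,
        "n_edges": e,
        "n_components": len(comps),
        "lcc_nodes": lcc_g.number_of_nodes(),
        "lcc_edges": lcc_g.number_of_edges(),
        "density": 2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
    }


def pairwise_edge_overlaps(nets: dict[str, CoexpressionNetwork]):
    """Edge-set overlap counts between every pair of networks."""
    import pandas as pd

    tags = list(nets)
    edges = {
        t: {frozenset(e) for e in nets[t].graph.edges()} for t in tags
    }
    table = pd.DataFrame(0, index=tags, columns=tags, dtype=int)
    for a in tags:
        for b in tags:
            table.loc[a, b] = len(edges[a] & edges[b])
    return table


def build_standard_networks(
    profiles: np.ndarray,
    gene_ids,
    mi_bins: int = 3,
    intersect_multipliers: tuple[float, float] = (10.0, 25.0),
) -> dict[str, CoexpressionNetwork]:
    """The five standard networks: SIGN_N, ABS_N, MI_N, ABS_MI_10N, ABS_MI_25N."""
    signed = score_pairs(profiles, gene_ids, "signed_pearson")
    absolute = score_pairs(profiles, gene_ids, "abs_pearson")
    mi = score_pairs(profiles, gene_ids, "mutual_information", mi_bins=mi_bins)
    nets = {
        "SIGN_N": build_topk_network(signed, 1.0, "SIGN_N"),
        "ABS_N": build_topk_network(absolute, 1.0, "ABS_N"),
        "MI_N": build_topk_network(mi, 1.0, "MI_N"),
    }
    for mult in intersect_multipliers:
        tag = f"ABS_MI_{mult:g}N"
        nets[tag] = intersect_networks(
            build_topk_network(absolute, mult),
            build_topk_network(mi, mult),
            tag,
        )
    return nets
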