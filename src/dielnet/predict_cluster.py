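"""Predicting rhythmic genes from Markov clusters.

Meaningful clusters (size >= 2 with >= 2 statistically-identified rhythmic
members) enter a sweep over K = 1..100 %: at each K the clusters whose
rhythmic fraction is at least K% and whose rhythmic enrichment passes a
Bonferroni-corrected hypergeometric gate pool their genes as predictions,
scored by precision/recall/F against the rhythmic set.  A null distribution
from 100 random clusterings that preserve the real cluster-size multiset
decides whether the F-optimal K is significantly better than chance; only
then does the network contribute predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .graphs import Clustering
from .predict_centrality import PredictionSet, prf

__all__ = [
    "ClusterSweepResult",
    "cluster_enrichment_sweep",
    "randomized_null",
    "predict_from_clusters",
]


@dataclass
class ClusterSweepResult:
    network_tag: str
    sweep: pd.DataFrame  # per K: n_clusters, n_predicted, precision, recall, f_score
    predictions_by_k: dict[int, set[str]]
    clusters_by_k: dict[int, list[int]]
    null_f: np.ndarray | None = None  # (n_rand, 100)
    chosen_k: int | None = None
    novel_genes: set = field(default_factory=set)


def _meaningful_clusters(
    clusters: list[set[str]], rhythmic: set[str]
) -> list[tuple[int, set[str]]]:
    return [
        (i, c)
        for i, c in enumerate(clusters)
        if len(c) >= 2 and len(c & rhythmic) >= 2
    ]


def _sweep_clusters(
    clusters: list[set[str]],
    rhythmic: set[str],
    universe: set[str],
    alpha: float,
) -> tuple[pd.DataFrame, dict[int, set[str]], dict[int, list[int]]]:
    meaningful = _meaningful_clusters(clusters, rhythmic)
    n_tests = max(len(meaningful), 1)
    n_univ = len(universe)
    n_rhy = len(rhythmic)
    sizes = np.array([len(c) for _, c in meaningful], dtype=int)
    overlaps = np.array([len(c & rhythmic) for _, c in meaningful], dtype=int)
    if len(meaningful):
        p_raw = stats.hypergeom.sf(overlaps - 1, n_univ, n_rhy, sizes)
        p_adj_all = np.minimum(p_raw * n_tests, 1.0)
    else:
        p_adj_all = np.array([])
    enriched = [
        (i, c, float(p_adj_all[k]), overlaps[k] / sizes[k])
        for k, (i, c) in enumerate(meaningful)
    ]
    rows = []
    preds: dict[int, set[str]] = {}
    clus: dict[int, list[int]] = {}
    for k in range(1, 101):
        thr = k / 100.0
        passing = [
            (i, c) for i, c, p_adj, frac in enriched if frac >= thr and p_adj < alpha
        ]
        pooled: set[str] = set()
        for _, c in passing:
            pooled |= c
        p, r, f = prf(pooled, rhythmic)
        rows.append((k, len(passing), len(pooled), p, r, f))
        preds[k] = pooled
        clus[k] = [i for i, _ in passing]
    sweep = pd.DataFrame(
        rows,
        columns=["k_pct", "n_clusters", "n_predicted", "precision", "recall", "f_score"],
    ).set_index("k_pct")
    return sweep, preds, clus


def cluster_enrichment_sweep(
    clustering: Clustering,
    rhythmic: set[str],
    universe: set[str] | None = None,
    alpha: float = 0.05,
    network_tag: str = "",
) -> ClusterSweepResult:
    """The real-data part of the sweep (no null yet)."""
    universe = universe if universe is not None else set(clustering.nodes)
    rhythmic = rhythmic & universe
    sweep, preds, clus = _sweep_clusters(
        clustering.clusters, rhythmic, universe, alpha
    )
    return ClusterSweepResult(network_tag, sweep, preds, clus)


def randomized_null(
    clustering: Clustering,
    rhythmic: set[str],
    universe: set[str] | None = None,
    n_rand: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> np.ndarray:
    """F-score curves of ``n_rand`` random clusterings with the real sizes.

    Genes are shuffled among clusters, preserving the cluster-size multiset
    exactly.  Returns an (n_rand, 100) array of F-scores.
    """
    universe = universe if universe is not None else set(clustering.nodes)
    rhythmic = rhythmic & universe
    sizes = sorted(len(c) for c in clustering.clusters)
    nodes = sorted(clustering.nodes)
    rng = np.random.default_rng(seed)
    out = np.zeros((n_rand, 100))
    for rep in range(n_rand):
        perm = rng.permutation(len(nodes))
        clusters = []
        start = 0
        for s in sizes:
            clusters.append({nodes[i] for i in perm[start : start + s]})
            start += s
        sweep, _, _ = _sweep_clusters(clusters, rhythmic, universe, alpha)
        out[rep] = sweep["f_score"].to_numpy()
    return out


def predict_from_clusters(
    sweeps: dict[str, ClusterSweepResult],
    rhythmic: set[str],
    null_quantile: float = 0.95,
) -> tuple[PredictionSet, dict[str, ClusterSweepResult]]:
    """Pool predictions across networks whose optimum beats its null.

    For each network: K* = argmax-F (smallest on ties); the network
    contributes its K* predictions only when the real F at K* exceeds the
    ``null_quantile`` quantile of the randomized F-scores at that K.
    Support counts the contributing networks per gene.
    """
    predictions = PredictionSet()
    for tag in sorted(sweeps):
        res = sweeps[tag]
        f = res.sweep["f_score"].to_numpy()
        if f.max() <= 0 or res.null_f is None:
            res.chosen_k = None
            continue
        k_star = int(res.sweep.index[int(np.argmax(f))])
        threshold = float(np.quantile(res.null_f[:, k_star - 1], null_quantile))
        if f[k_star - 1] > threshold:
            res.chosen_k = k_star
            pooled = res.predictions_by_k[k_star]
            res.novel_genes = pooled - rhythmic
            for gene in pooled:
                predictions.add(gene, tag)
        else:
            res.chosen_k = None
    return predictions, sweeps
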