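"""Predicting rhythmic genes from network position.

For every (network, centrality measure) combination: test whether the
statistically-identified rhythmic genes occupy distinctive network
positions (two-sided Mann-Whitney, alpha 0.01); if so, sweep the top K%
most (or least) central genes for K = 1..100, score precision/recall/F
against the rhythmic set, and at the F-optimal K apply a
Bonferroni-corrected hypergeometric enrichment gate (alpha 0.05 over all 35
combinations).  Combinations passing both gates contribute their top-K%
non-rhythmic genes as novel predictions, with per-gene support counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .graphs import CENTRALITY_MEASURES

__all__ = [
    "CombinationResult",
    "PredictionSet",
    "separation_test",
    "sweep_threshold",
    "enrichment_gate",
    "predict_from_centrality",
]


@dataclass
class CombinationResult:
    network_tag: str
    measure: str
    direction: str  # most_central | least_central
    separation_p: float
    optimal_k_pct: int | None = None
    precision: float = 0.0
    recall: float = 0.0
    f_score: float = 0.0
    enrichment_p: float = 1.0
    passed: bool = False
    predicted_genes: set = field(default_factory=set)
    novel_genes: set = field(default_factory=set)


@dataclass
class PredictionSet:
    """gene -> support count, with per-gene provenance."""

    support: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def add(self, gene: str, source: str) -> None:
        self.support[gene] = self.support.get(gene, 0) + 1
        self.provenance.setdefault(gene, []).append(source)

    @property
    def genes(self) -> set[str]:
        return set(self.support)

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.support)
        return pd.DataFrame(
            {
                "support": [self.support[g] for g in genes],
                "combinations": [",".join(self.provenance[g]) for g in genes],
            },
            index=pd.Index(genes, name="gene"),
        )


def separation_test(values_rhythmic, values_other) -> tuple[float, str]:
    """Two-sided Mann-Whitney U p-value and which group is more central.

    Returns (p, direction): ``most_central`` when the rhythmic group has the
    larger median.
    """
    a = np.asarray(values_rhythmic, dtype=float)
    b = np.asarray(values_other, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    direction = "most_central" if np.median(a) >= np.median(b) else "least_central"
    return float(res.pvalue), direction


def _ranked_genes(values: pd.Series, direction: str) -> list[str]:
    """Genes best-first; ties broken by gene id for determinism."""
    ascending = direction == "least_central"
    order = sorted(
        values.index, key=lambda g: ((values[g] if ascending else -values[g]), g)
    )
    return order


def prf(top: set[str], rhythmic: set[str]) -> tuple[float, float, float]:
    tp = len(top & rhythmic)
    p = tp / len(top) if top else 0.0
    r = tp / len(rhythmic) if rhythmic else 0.0
    f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f


def sweep_threshold(
    values: pd.Series, rhythmic: set[str], direction: str
) -> pd.DataFrame:
    """P/R/F over K = 1..100 % of genes taken best-first by centrality.

    The rhythmic set must be a subset of the scored genes.  Returns a frame
    indexed by K with columns n_top, precision, recall, f_score.
    """
    genes = set(values.index)
    if not rhythmic:
        raise ValueError("empty rhythmic set")
    if not rhythmic <= genes:
        raise ValueError("rhythmic set must be within the scored genes")
    ranked = _ranked_genes(values, direction)
    n = len(ranked)
    rows = []
    for k in range(1, 101):
        m = math.ceil(k / 100.0 * n)
        top = set(ranked[:m])
        p, r, f = prf(top, rhythmic)
        rows.append((k, m, p, r, f))
    return pd.DataFrame(
        rows, columns=["k_pct", "n_top", "precision", "recall", "f_score"]
    ).set_index("k_pct")


def optimal_k(sweep: pd.DataFrame) -> int:
    """Argmax-F K; the smallest K on ties."""
    f = sweep["f_score"].to_numpy()
    return int(sweep.index[int(np.argmax(f))])


def enrichment_gate(
    top: set[str],
    rhythmic: set[str],
    universe: set[str],
    n_tests: int = 35,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Bonferroni-adjusted upper-tail hypergeometric enrichment of the top set."""
    if not (top <= universe and rhythmic <= universe):
        raise ValueError("sets must lie within the universe")
    overlap = len(top & rhythmic)
    p = float(
        stats.hypergeom.sf(overlap - 1, len(universe), len(rhythmic), len(top))
    )
    p_adj = min(p * n_tests, 1.0)
    return p_adj, p_adj < alpha


def predict_from_centrality(
    centrality_tables: dict[str, pd.DataFrame],
    rhythmic: set[str],
    separation_alpha: float = 0.01,
    enrichment_alpha: float = 0.05,
    measures=CENTRALITY_MEASURES,
) -> tuple[PredictionSet, list[CombinationResult]]:
    """Run the full (network x measure) screen.

    ``centrality_tables`` maps network tags to per-node centrality frames
    (computed on each network's largest connected component).  The
    Bonferroni scope of the enrichment gate is the total number of
    combinations screened.
    """
    n_tests = len(centrality_tables) * len(measures)
    results: list[CombinationResult] = []
    predictions = PredictionSet()
    for tag in sorted(centrality_tables):
        table = centrality_tables[tag]
        nodes = set(table.index)
        rhythmic_here = rhythmic & nodes
        others = nodes - rhythmic_here
        for measure in measures:
            if measure not in table.columns:
                continue
            if not rhythmic_here or not others:
                continue
            vals = table[measure]
            p_sep, direction = separation_test(
                vals.loc[sorted(rhythmic_here)], vals.loc[sorted(others)]
            )
            combo = CombinationResult(tag, measure, direction, p_sep)
            results.append(combo)
            if p_sep >= separation_alpha:
                continue
            sweep = sweep_threshold(vals, rhythmic_here, direction)
            k = optimal_k(sweep)
            ranked = _ranked_genes(vals, direction)
            top = set(ranked[: sweep.loc[k, "n_top"]])
            p_enr, passed = enrichment_gate(
                top, rhythmic_here, nodes, n_tests=n_tests, alpha=enrichment_alpha
            )
            combo.optimal_k_pct = k
            combo.precision = float(sweep.loc[k, "precision"])
            combo.recall = float(sweep.loc[k, "recall"])
            combo.f_score = float(sweep.loc[k, "f_score"])
            combo.enrichment_p = p_enr
            combo.passed = passed
            if not passed:
                continue
            combo.predicted_genes = top
            combo.novel_genes = top - rhythmic_here
            for gene in top:
                predictions.add(gene, f"{tag}:{measure}")
    return predictions, results


def combination_frame(results: list[CombinationResult]) -> pd.DataFrame:
    rows = []
    for c in results:
        rows.append(
            (
                c.network_tag,
                c.measure,
                c.direction,
                c.separation_p,
                c.optimal_k_pct if c.optimal_k_pct is not None else "",
                c.precision,
                c.recall,
                c.f_score,
                c.enrichment_p,
                c.passed,
                len(c.predicted_genes),
                len(c.novel_genes),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "network",
            "measure",
            "direction",
            "separation_p",
            "optimal_k_pct",
            "precision",
            "recall",
            "f_score",
            "enrichment_p",
            "passed",
            "n_predicted",
            "n_novel",
        ],
    )
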