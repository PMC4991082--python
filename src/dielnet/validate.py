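"""Overlap and enrichment validations of network-based predictions.

Set overlaps are scored with the exact upper-tail hypergeometric test
against a stated gene universe; functional validation compares the enriched
term sets of positive controls (statistically-identified rhythmic genes),
novel network predictions, and negative controls (network genes predicted
by no approach); condition overlaps report the count and percentage of an
external differentially-expressed set that is also rhythmic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .predict_function import AnnotationMap, group_term_enrichment

__all__ = [
    "OverlapTest",
    "overlap_significance",
    "reference_set_validation",
    "enriched_term_overlap",
    "condition_overlap",
]


@dataclass
class OverlapTest:
    set_a_size: int
    set_b_size: int
    universe_size: int
    overlap: int
    raw_p: float
    percent_overlap: float


def overlap_significance(a: set, b: set, universe: set) -> OverlapTest:
    """Exact upper-tail hypergeometric p for the overlap of two gene sets."""
    if not (a <= universe and b <= universe):
        raise ValueError("sets must lie within the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))
    pct = k / len(a) if a else 0.0
    return OverlapTest(len(a), len(b), len(universe), k, p, pct)


def reference_set_validation(
    prediction_sets: dict[str, set],
    reference: set,
    universe: set,
) -> pd.DataFrame:
    """Overlap of each prediction set with an external reference rhythmic list.

    The reference is restricted to the universe (network genes); empty
    restrictions are skipped with a warning row.
    """
    ref = reference & universe
    rows = []
    for name in sorted(prediction_sets):
        genes = prediction_sets[name] & universe
        if not ref:
            rows.append((name, len(genes), 0, 0, float("nan"), "empty reference"))
            continue
        t = overlap_significance(genes, ref, universe)
        rows.append((name, t.set_a_size, t.set_b_size, t.overlap, t.raw_p, ""))
    return pd.DataFrame(
        rows, columns=["set", "n_genes", "n_reference", "overlap", "p_value", "note"]
    ).set_index("set")


def enriched_term_overlap(
    positive: set,
    predicted: set,
    negative: set,
    ann: AnnotationMap,
    universe: set,
    alpha: float = 0.05,
) -> dict:
    """Pairwise overlap of enriched-term sets of three disjoint gene sets.

    Each set's enriched terms come from the Bonferroni-corrected
    hypergeometric group test; term-set overlaps are then scored
    hypergeometrically over the universe of terms tested in either set.
    """
    if positive & predicted or positive & negative or predicted & negative:
        raise ValueError("input gene sets must be disjoint")
    named = {"positive": positive, "predicted": predicted, "negative": negative}
    enriched: dict[str, set] = {}
    tested: dict[str, set] = {}
    for name, genes in named.items():
        g = genes & universe
        tested[name] = {t for x in g for t in ann.terms_of(x)}
        enriched[name] = (
            set(group_term_enrichment(g, ann, universe, alpha=alpha)) if g else set()
        )
    out: dict = {"enriched_terms": {k: sorted(v) for k, v in enriched.items()}}
    pairs = [("positive", "predicted"), ("positive", "negative"), ("predicted", "negative")]
    for x, y in pairs:
        term_universe = tested[x] | tested[y]
        if not term_universe:
            out[f"{x}_vs_{y}"] = None
            continue
        t = overlap_significance(
            enriched[x] & term_universe, enriched[y] & term_universe, term_universe
        )
        out[f"{x}_vs_{y}"] = t
    return out


def condition_overlap(de_set: set, rhythmic: set, universe: set) -> dict:
    """Count and percentage of a differentially-expressed set also rhythmic."""
    if not de_set:
        raise ValueError("empty differentially-expressed set")
    if not (de_set <= universe and rhythmic <= universe):
        raise ValueError("sets must lie within the universe")
    k = len(de_set & rhythmic)
    return {
        "n_overlap": k,
        "percent": round(100.0 * k / len(de_set)),
    }
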