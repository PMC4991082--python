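"""Guilt-by-association prediction of gene-function (GO) annotations.

Gene groups produced by the network analyses (Markov clusters; top-K%
centrality bands) are tested for functional-term enrichment; group members
inherit a term when every informative group containing them supports it
(consensus within a source), with clusters additionally requiring the term
to cover a majority of their annotated members.  High-confidence pairs are
those predicted by both the clustering and the centrality grouping.
Accuracy is estimated with leave-one-out cross-validation: hide one gene's
annotations, re-run the group enrichment, and score the predictions made for
that gene against its hidden truth.  Terms are used as given (no ontology
propagation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

__all__ = [
    "AnnotationMap",
    "group_term_enrichment",
    "predict_annotations",
    "loocv_precision",
]


@dataclass
class AnnotationMap:
    """gene -> set of term ids, with the inverse index kept consistent."""

    gene_to_terms: dict[str, set[str]] = field(default_factory=dict)
    term_to_genes: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs) -> "AnnotationMap":
        ann = cls()
        for gene, term in pairs:
            ann.add(gene, term)
        return ann

    @classmethod
    def read(cls, path) -> "AnnotationMap":
        """Two-column tab-separated (gene, term) file."""
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"expected two tab-separated columns: {line!r}")
                pairs.append((parts[0], parts[1]))
        return cls.from_pairs(pairs)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for gene in sorted(self.gene_to_terms):
                for term in sorted(self.gene_to_terms[gene]):
                    fh.write(f"{gene}\t{term}\n")

    def add(self, gene: str, term: str) -> None:
        if not term:
            raise ValueError("term ids must be non-empty")
        self.gene_to_terms.setdefault(gene, set()).add(term)
        self.term_to_genes.setdefault(term, set()).add(gene)

    def terms_of(self, gene: str) -> set[str]:
        return self.gene_to_terms.get(gene, set())

    def genes_of(self, term: str) -> set[str]:
        return self.term_to_genes.get(term, set())

    @property
    def universe(self) -> set[str]:
        """All annotated genes."""
        return set(self.gene_to_terms)

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self.gene_to_terms.values())

    def without_gene(self, gene: str) -> "AnnotationMap":
        """Copy with one gene's annotations hidden (for LOOCV)."""
        return AnnotationMap.from_pairs(
            (g, t)
            for g, ts in self.gene_to_terms.items()
            if g != gene
            for t in ts
        )


def group_term_enrichment(
    group: set[str],
    ann: AnnotationMap,
    universe: set[str],
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> dict[str, float]:
    """Bonferroni-adjusted hypergeometric enrichment of terms in a gene group.

    Only terms annotating at least one group member are tested; the
    Bonferroni factor defaults to the number of terms tested for this group.
    Returns {term: adjusted_p} for terms with adjusted p < ``alpha``.
    """
    if not group:
        raise ValueError("empty gene group")
    if not group <= universe:
        raise ValueError("group must be a subset of the universe")
    terms = sorted({t for g in group for t in ann.terms_of(g)})
    if not terms:
        return {}
    m = n_tests if n_tests is not None else len(terms)
    n_univ = len(universe)
    n_group = len(group)
    out: dict[str, float] = {}
    for term in terms:
        carriers = ann.genes_of(term) & universe
        overlap = len(carriers & group)
        p = float(stats.hypergeom.sf(overlap - 1, n_univ, len(carriers), n_group))
        p_adj = min(p * m, 1.0)
        if p_adj < alpha:
            out[term] = p_adj
    return out


DEFAULT_MIN_COVERAGE = {"clustering": 0.5}


def _coverage_for(source: str, min_coverage) -> float:
    """Per-source majority-coverage threshold (default: clusters only).

    Co-expression clusters are cohesive groups where a transferred term
    should describe most members; centrality bands are broad rankings whose
    role in the source intersection is positional confirmation, so they are
    filtered by enrichment alone.
    """
    if min_coverage is None:
        min_coverage = DEFAULT_MIN_COVERAGE
    if isinstance(min_coverage, dict):
        return float(min_coverage.get(source, 0.0))
    return float(min_coverage)


def _coverage_filter(
    enriched: dict[str, float],
    group: set[str],
    ann: AnnotationMap,
    min_coverage: float,
) -> dict[str, float]:
    """Keep terms carried by a majority of the group's annotated members.

    Enrichment alone lets a large group that mixes several coherent
    sub-programs transfer every sub-program's term to every member; the
    coverage rule (cf. neighbourhood majority-voting in guilt-by-association
    annotation) restricts transfer to terms that describe the group as a
    whole.
    """
    if min_coverage <= 0:
        return enriched
    annotated = [g for g in group if ann.terms_of(g)]
    if not annotated:
        return {}
    return {
        t: p
        for t, p in enriched.items()
        if sum(1 for g in annotated if t in ann.terms_of(g)) / len(annotated)
        > min_coverage
    }


def _pairs_from_groups(
    groups: list[set[str]],
    ann: AnnotationMap,
    universe: set[str],
    alpha: float,
    min_coverage: float = 0.5,
) -> dict[tuple[str, str], float]:
    """(gene, term) predictions supported by every group containing the gene.

    Each significantly enriched (group, term) proposes the term for all
    group members; within a source a term is kept for a gene only if every
    group the gene belongs to supports it (consensus over overlapping
    groups), and only if the gene does not already carry it.  The reported
    p is the least significant supporting adjusted p.
    """
    enriched_per_group = []
    for group in groups:
        g = group & universe
        if not g:
            continue
        enriched = group_term_enrichment(g, ann, universe, alpha=alpha)
        enriched = _coverage_filter(enriched, g, ann, min_coverage)
        enriched_per_group.append((g, enriched))
    membership: dict[str, list[int]] = {}
    for k, (g, _) in enumerate(enriched_per_group):
        for gene in g:
            membership.setdefault(gene, []).append(k)
    pairs: dict[tuple[str, str], float] = {}
    for gene, idxs in membership.items():
        # groups left with no transferable term abstain from the consensus
        idxs = [k for k in idxs if enriched_per_group[k][1]]
        if not idxs:
            continue
        term_sets = [set(enriched_per_group[k][1]) for k in idxs]
        terms = set.intersection(*term_sets)
        for term in terms:
            if term in ann.terms_of(gene):
                continue
            pairs[(gene, term)] = max(
                enriched_per_group[k][1][term] for k in idxs
            )
    return pairs


def predict_annotations(
    groups_by_source: dict[str, list[set[str]]],
    ann: AnnotationMap,
    universe: set[str],
    alpha: float = 0.05,
    min_coverage: float | dict[str, float] | None = None,
) -> pd.DataFrame:
    """Predict novel (gene, term) associations per source and in intersection.

    ``groups_by_source`` maps source names (e.g. ``centrality`` and
    ``clustering``) to lists of gene groups.  Returns a table with columns
    gene, term, source ('both' rows are duplicated from the single-source
    sets), adjusted_p, gene_status (characterized/uncharacterized).
    """
    per_source = {
        src: _pairs_from_groups(
            groups, ann, universe, alpha, _coverage_for(src, min_coverage)
        )
        for src, groups in groups_by_source.items()
    }
    rows = []
    for src, pairs in per_source.items():
        for (gene, term), p in sorted(pairs.items()):
            rows.append((gene, term, src, p))
    if len(per_source) >= 2:
        sources = list(per_source)
        common = set.intersection(*(set(p) for p in per_source.values()))
        for gene, term in sorted(common):
            p = max(per_source[s][(gene, term)] for s in sources)
            rows.append((gene, term, "both", p))
    df = pd.DataFrame(rows, columns=["gene", "term", "source", "adjusted_p"])
    df["gene_status"] = [
        "characterized" if ann.terms_of(g) else "uncharacterized" for g in df["gene"]
    ]
    return df


def loocv_precision(
    groups_by_source: dict[str, list[set[str]]],
    ann: AnnotationMap,
    universe: set[str],
    alpha: float = 0.05,
    min_coverage: float | dict[str, float] | None = None,
    require_intersection: bool = True,
) -> dict:
    """Leave-one-out precision of group-based annotation transfer.

    For each annotated gene: hide its annotations, recompute enrichment of
    the groups containing it, take the predictions made for it (intersection
    across sources by default), and score them against the hidden truth.
    Precision is pooled over all predicted associations.
    """
    annotated = sorted(ann.universe & universe)
    if len(annotated) < 2:
        raise ValueError("need at least two annotated genes")
    n_predicted = 0
    n_correct = 0
    n_evaluated = 0
    for gene in annotated:
        hidden = ann.without_gene(gene)
        predicted_terms: list[set[str]] = []
        for src, groups in groups_by_source.items():
            term_sets = []
            for group in groups:
                if gene not in group:
                    continue
                g = group & universe
                enriched = group_term_enrichment(g, hidden, universe, alpha=alpha)
                enriched = _coverage_filter(
                    enriched, g, hidden, _coverage_for(src, min_coverage)
                )
                if enriched:
                    term_sets.append(set(enriched))
            # consensus across the informative groups of this source
            terms = set.intersection(*term_sets) if term_sets else set()
            predicted_terms.append(terms)
        if require_intersection and len(predicted_terms) >= 2:
            terms = set.intersection(*predicted_terms)
        else:
            terms = set.union(*predicted_terms) if predicted_terms else set()
        if not terms:
            continue
        n_evaluated += 1
        truth = ann.terms_of(gene)
        n_predicted += len(terms)
        n_correct += len(terms & truth)
    precision = n_correct / n_predicted if n_predicted else float("nan")
    return {
        "n_genes_evaluated": n_evaluated,
        "n_predicted_pairs": n_predicted,
        "n_correct_pairs": n_correct,
        "precision": precision,
    }
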