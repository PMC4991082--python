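"""End-to-end pipeline: simulate/read -> preprocess -> rhythm scan ->
networks -> centrality & cluster prediction -> function prediction ->
validation.

Each stage reads its inputs from, and writes its outputs to, a run
directory, so any stage can be re-run from saved intermediates and
reproduce the end-to-end result exactly.  All file outputs are plain
tab-separated text or JSON with deterministic ordering; all randomness
derives from the single global seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocess import (
    read_expression,
    write_expression,
    quantile_normalize,
    filter_background,
    collapse_replicates,
)
from .simulate import (
    SimConfig,
    GroundTruth,
    generate_expression,
    generate_annotations,
    generate_reference_rhythmic_set,
)
from .rhythm import JtkConfig, jtk_scan_matrix, classify_rhythmic, rhythm_summaries
from .networks import (
    CoexpressionNetwork,
    build_standard_networks,
    largest_component,
    network_summary,
    pairwise_edge_overlaps,
    STANDARD_TAGS,
)
from .graphs import centrality_table, mcl_cluster, CENTRALITY_MEASURES
from .predict_centrality import predict_from_centrality, combination_frame
from .predict_cluster import (
    cluster_enrichment_sweep,
    randomized_null,
    predict_from_clusters,
)
from .predict_function import AnnotationMap, predict_annotations, loocv_precision
from .validate import (
    overlap_significance,
    reference_set_validation,
    enriched_term_overlap,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline settings; defaults follow the analysis this package models."""

    outdir: str = "run"
    seed: int = 0
    # either simulate ...
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    annotation_terms: int = 20
    annotation_signal: float = 0.9
    annotation_noise: float = 0.02
    reference_size: int = 50
    reference_contamination: float = 0.0
    # ... or read user files
    expression_path: str | None = None
    annotation_path: str | None = None
    reference_path: str | None = None
    # preprocessing
    background_cutoff: float = 136.5
    # rhythm detection
    jtk: JtkConfig = field(default_factory=JtkConfig)
    # networks
    network_profile: str = "replicates"  # or "means"
    mi_bins: int = 3
    # prediction
    measures: tuple = CENTRALITY_MEASURES
    mcl_inflation: float = 2.0
    separation_alpha: float = 0.01
    enrichment_alpha: float = 0.05
    n_rand: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        jtk = JtkConfig(**raw.pop("jtk", {}))
        cfg = cls(sim=sim, jtk=jtk, **raw)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        # the run directory is implied by the file's location; leaving it out
        # keeps run directories byte-identical across output locations
        d.pop("outdir", None)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def _read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    sim = SimConfig(**{**asdict(cfg.sim), "seed": cfg.seed})
    matrix, truth = generate_expression(sim)
    write_expression(matrix, outdir / "expression.tsv")
    truth.write(outdir / "ground_truth.tsv")
    ann = generate_annotations(
        truth,
        n_terms=cfg.annotation_terms,
        signal=cfg.annotation_signal,
        noise_rate=cfg.annotation_noise,
        seed=cfg.seed + 1,
    )
    ann.write(outdir / "annotations.tsv")
    ref = generate_reference_rhythmic_set(
        truth,
        n=cfg.reference_size,
        contamination=cfg.reference_contamination,
        seed=cfg.seed + 2,
    )
    _write_gene_list(ref, outdir / "reference_rhythmic.txt")


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> dict:
    src = (
        Path(cfg.expression_path)
        if not cfg.simulate and cfg.expression_path
        else outdir / "expression.tsv"
    )
    m = read_expression(src)
    m = quantile_normalize(m)
    m, report = filter_background(m, cfg.background_cutoff)
    write_expression(m, outdir / "expression_filtered.tsv")
    _write_json(report, outdir / "preprocess_report.json")
    return report


def stage_detect(cfg: PipelineConfig, outdir: Path) -> dict:
    m = read_expression(outdir / "expression_filtered.tsv")
    results = jtk_scan_matrix(
        m.values.to_numpy(), m.zt, cfg.jtk, gene_ids=m.gene_ids
    )
    results.to_csv(outdir / "rhythm_results.tsv", sep="\t", float_format="%.6g")
    rhythmic = classify_rhythmic(results, cfg.jtk)
    _write_gene_list(rhythmic, outdir / "rhythmic_genes.txt")
    summary = (
        rhythm_summaries(results, rhythmic) if rhythmic else {"n_rhythmic": 0}
    )
    _write_json(summary, outdir / "rhythm_summary.json")
    return summary


def _profiles(cfg: PipelineConfig, outdir: Path):
    m = read_expression(outdir / "expression_filtered.tsv")
    if cfg.network_profile == "means":
        m, _ = collapse_replicates(m)
    elif cfg.network_profile != "replicates":
        raise ValueError("network_profile must be 'replicates' or 'means'")
    logm = m.to_log2()
    return logm.values.to_numpy(), logm.gene_ids


def stage_network(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    profiles, gene_ids = _profiles(cfg, outdir)
    nets = build_standard_networks(profiles, gene_ids, mi_bins=cfg.mi_bins)
    rows = []
    for tag in STANDARD_TAGS:
        net = nets[tag]
        net.write_edgelist(outdir / f"network_{tag}.tsv")
        rows.append(network_summary(net))
    df = pd.DataFrame(rows).set_index("method")
    df.to_csv(outdir / "network_summary.tsv", sep="\t")
    pairwise_edge_overlaps(nets).to_csv(outdir / "network_edge_overlaps.tsv", sep="\t")
    return df


def _load_components(outdir: Path) -> dict[str, CoexpressionNetwork]:
    comps = {}
    for tag in STANDARD_TAGS:
        path = outdir / f"network_{tag}.tsv"
        net = CoexpressionNetwork.read_edgelist(path, tag)
        if net.graph.number_of_nodes() == 0:
            continue
        comps[tag] = largest_component(net)
    return comps


def stage_predict_centrality(cfg: PipelineConfig, outdir: Path) -> dict:
    rhythmic = _read_gene_list(outdir / "rhythmic_genes.txt")
    comps = _load_components(outdir)
    tables = {}
    for tag, comp in comps.items():
        table = centrality_table(comp, cfg.measures)
        table.to_csv(outdir / f"centrality_{tag}.tsv", sep="\t", float_format="%.6g")
        tables[tag] = table
    predictions, results = predict_from_centrality(
        tables,
        rhythmic,
        separation_alpha=cfg.separation_alpha,
        enrichment_alpha=cfg.enrichment_alpha,
        measures=cfg.measures,
    )
    combination_frame(results).to_csv(
        outdir / "centrality_combinations.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    predictions.to_frame().to_csv(outdir / "centrality_predictions.tsv", sep="\t")
    bands = {
        f"{c.network_tag}:{c.measure}": sorted(c.predicted_genes)
        for c in results
        if c.passed
    }
    _write_json(bands, outdir / "centrality_bands.json")
    novel = predictions.genes - rhythmic
    _write_gene_list(novel, outdir / "centrality_novel.txt")
    return {
        "n_combinations_passed": sum(c.passed for c in results),
        "n_predicted": len(predictions.genes),
        "n_novel": len(novel),
    }


def _load_networks(outdir: Path) -> dict[str, CoexpressionNetwork]:
    nets = {}
    for tag in STANDARD_TAGS:
        net = CoexpressionNetwork.read_edgelist(outdir / f"network_{tag}.tsv", tag)
        if net.graph.number_of_nodes() > 0:
            nets[tag] = net
    return nets


def stage_predict_cluster(cfg: PipelineConfig, outdir: Path) -> dict:
    rhythmic = _read_gene_list(outdir / "rhythmic_genes.txt")
    # MCL factorizes over connected components, so it runs on each full
    # network (all non-isolated nodes), unlike the centrality analysis
    nets = _load_networks(outdir)
    sweeps = {}
    clusterings = {}
    for i, (tag, comp) in enumerate(sorted(nets.items())):
        clustering = mcl_cluster(comp, inflation=cfg.mcl_inflation)
        clustering.to_frame().to_csv(outdir / f"mcl_{tag}.tsv", sep="\t")
        clusterings[tag] = clustering
        res = cluster_enrichment_sweep(
            clustering, rhythmic, alpha=cfg.enrichment_alpha, network_tag=tag
        )
        res.null_f = randomized_null(
            clustering,
            rhythmic,
            n_rand=cfg.n_rand,
            seed=cfg.seed + 10 + i,
            alpha=cfg.enrichment_alpha,
        )
        sweeps[tag] = res
    predictions, sweeps = predict_from_clusters(sweeps, rhythmic)
    for tag, res in sweeps.items():
        out = res.sweep.copy()
        out["null_f_q95"] = np.quantile(res.null_f, 0.95, axis=0)
        out.to_csv(outdir / f"cluster_sweep_{tag}.tsv", sep="\t", float_format="%.6g")
    predictions.to_frame().to_csv(outdir / "cluster_predictions.tsv", sep="\t")
    novel = predictions.genes - rhythmic
    _write_gene_list(novel, outdir / "cluster_novel.txt")
    # groups for annotation transfer: every meaningful cluster (size >= 2,
    # >= 2 rhythmic members) of every network; the randomized-null gate
    # above concerns rhythmic-gene prediction only
    groups = {}
    for tag, res in sweeps.items():
        meaningful = [
            sorted(c)
            for c in clusterings[tag].clusters
            if len(c) >= 2 and len(c & rhythmic) >= 2
        ]
        groups[tag] = {"chosen_k": res.chosen_k, "clusters": meaningful}
    _write_json(groups, outdir / "cluster_groups.json")
    return {
        "n_networks_contributing": sum(
            1 for r in sweeps.values() if r.chosen_k is not None
        ),
        "n_predicted": len(predictions.genes),
        "n_novel": len(novel),
    }


def _load_groups(outdir: Path) -> dict[str, list[set[str]]]:
    with open(outdir / "centrality_bands.json") as fh:
        bands = json.load(fh)
    with open(outdir / "cluster_groups.json") as fh:
        cluster_groups = json.load(fh)
    groups = {
        "centrality": [set(v) for _, v in sorted(bands.items())],
        "clustering": [
            set(c)
            for _, d in sorted(cluster_groups.items())
            for c in d["clusters"]
        ],
    }
    return groups


def stage_predict_function(cfg: PipelineConfig, outdir: Path) -> dict:
    ann_path = (
        Path(cfg.annotation_path)
        if not cfg.simulate and cfg.annotation_path
        else outdir / "annotations.tsv"
    )
    if not ann_path.exists():
        _write_json({"skipped": "no annotation file"}, outdir / "function_summary.json")
        return {"skipped": True}
    ann = AnnotationMap.read(ann_path)
    groups = _load_groups(outdir)
    universe = set()
    for net in _load_networks(outdir).values():
        universe |= net.nodes
    if not any(groups.values()) or not universe:
        _write_json({"skipped": "no groups"}, outdir / "function_summary.json")
        return {"skipped": True}
    preds = predict_annotations(groups, ann, universe, alpha=cfg.enrichment_alpha)
    preds.sort_values(["source", "gene", "term"]).to_csv(
        outdir / "function_predictions.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    loocv = loocv_precision(groups, ann, universe, alpha=cfg.enrichment_alpha)
    both = preds[preds["source"] == "both"]
    summary = {
        "n_predicted_pairs_both": int(len(both)),
        "n_uncharacterized_genes": int(
            both[both["gene_status"] == "uncharacterized"]["gene"].nunique()
        ),
        "loocv": loocv,
    }
    _write_json(summary, outdir / "function_summary.json")
    return summary


def stage_validate(cfg: PipelineConfig, outdir: Path) -> dict:
    rhythmic = _read_gene_list(outdir / "rhythmic_genes.txt")
    universe = set()
    for net in _load_networks(outdir).values():
        universe |= net.nodes
    centrality_novel = _read_gene_list(outdir / "centrality_novel.txt")
    cluster_novel = _read_gene_list(outdir / "cluster_novel.txt")
    both_novel = centrality_novel & cluster_novel
    jtk_in_networks = rhythmic & universe
    report: dict = {"universe_size": len(universe)}

    def _ov(a, b):
        if not a or not b:
            return None
        t = overlap_significance(a & universe, b & universe, universe)
        return {
            "n_a": t.set_a_size,
            "n_b": t.set_b_size,
            "overlap": t.overlap,
            "p": t.raw_p,
        }

    def _pred_set(name):
        path = outdir / name
        if not path.exists():
            return set()
        df = pd.read_csv(path, sep="\t")
        return set(df["gene"]) if "gene" in df.columns else set()

    centrality_pred = _pred_set("centrality_predictions.tsv")
    cluster_pred = _pred_set("cluster_predictions.tsv")
    report["centrality_pred_vs_jtk"] = _ov(centrality_pred, jtk_in_networks)
    report["cluster_pred_vs_jtk"] = _ov(cluster_pred, jtk_in_networks)
    report["centrality_pred_vs_cluster_pred"] = _ov(centrality_pred, cluster_pred)
    report["n_high_confidence"] = len(centrality_pred & cluster_pred)
    report["n_high_confidence_novel"] = len(both_novel)

    ref_path = (
        Path(cfg.reference_path)
        if not cfg.simulate and cfg.reference_path
        else outdir / "reference_rhythmic.txt"
    )
    if ref_path.exists():
        reference = _read_gene_list(ref_path)
        negative = universe - centrality_novel - cluster_novel - rhythmic
        sets = {
            "centrality_novel": centrality_novel,
            "cluster_novel": cluster_novel,
            "both_novel": both_novel,
            "jtk_in_networks": jtk_in_networks,
            "negative_control": negative,
        }
        ref_table = reference_set_validation(sets, reference, universe)
        ref_table.to_csv(outdir / "reference_validation.tsv", sep="\t",
                         float_format="%.6g")
        report["reference_validation"] = {
            name: (None if pd.isna(row["p_value"]) else float(row["p_value"]))
            for name, row in ref_table.iterrows()
        }

    ann_path = (
        Path(cfg.annotation_path)
        if not cfg.simulate and cfg.annotation_path
        else outdir / "annotations.tsv"
    )
    if ann_path.exists():
        ann = AnnotationMap.read(ann_path)
        predicted = (centrality_novel | cluster_novel) & universe
        positive = jtk_in_networks - predicted
        negative = universe - predicted - positive
        try:
            terms = enriched_term_overlap(
                positive, predicted, negative, ann, universe,
                alpha=cfg.enrichment_alpha,
            )
            report["term_overlap"] = {
                k: (
                    {
                        "n_a": v.set_a_size,
                        "n_b": v.set_b_size,
                        "overlap": v.overlap,
                        "p": v.raw_p,
                    }
                    if v is not None and not isinstance(v, dict)
                    else v
                )
                for k, v in terms.items()
                if k != "enriched_terms"
            }
        except ValueError as exc:
            report["term_overlap"] = {"skipped": str(exc)}
    _write_json(report, outdir / "validation.json")
    return report


STAGES = (
    "simulate",
    "preprocess",
    "detect",
    "network",
    "predict-centrality",
    "predict-cluster",
    "predict-function",
    "validate",
)


def run_stage(name: str, cfg: PipelineConfig, outdir: Path):
    fn = {
        "simulate": stage_simulate,
        "preprocess": stage_preprocess,
        "detect": stage_detect,
        "network": stage_network,
        "predict-centrality": stage_predict_centrality,
        "predict-cluster": stage_predict_cluster,
        "predict-function": stage_predict_function,
        "validate": stage_validate,
    }[name]
    logger.info("stage %s", name)
    try:
        return fn(cfg, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages; returns the run directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    summary: dict = {"version": __version__, "seed": cfg.seed}
    stages = STAGES if cfg.simulate else STAGES[1:]
    for name in stages:
        out = run_stage(name, cfg, outdir)
        if isinstance(out, dict):
            summary[name.replace("-", "_")] = out
        elif isinstance(out, pd.DataFrame):
            summary[name.replace("-", "_")] = {
                str(k): {kk: int(vv) if isinstance(vv, (int, np.integer)) else vv
                         for kk, vv in row.items() if kk != "method"}
                for k, row in out.to_dict(orient="index").items()
            }
    _write_json(summary, outdir / "summary.json")
    return outdir
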