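"""End-to-end orchestration: classify, relate, shuffle, enrich, report.

All stages compose through files in the formats of :mod:`interleave.io`,
so each can also be run on its own (see :mod:`interleave.cli`).  A fixed
seed makes the whole report byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from functools import partial
from pathlib import Path

import pandas as pd

from . import antisense as anti_mod
from . import neighborhood as nb
from .factors import FactorOccupancyMatrix, factor_enrichment_test
from .io import FeatureTable, read_coverage, read_features
from .shuffle import ShuffleConfig, ShuffleNullModel
from .switching import classify_switch, set_overlap, switch_counts

logger = logging.getLogger("interleave")


@dataclass
class PipelineConfig:
    features: str
    out_dir: str
    features_format: str = "tsv"
    coverage_plus: str | None = None
    coverage_minus: str | None = None
    factor_matrix: str | None = None
    gene_set_phase: str = "RC"      # phase whose genes feed factor tests
    cond_a: str = "glu"
    cond_b: str = "gal"
    threshold: float = 3.0
    pseudocount: float = 0.5
    max_gap: int = 1000
    n_iter: int = 1000
    seed: int = 0
    alpha: float = 0.01
    adjacency_classes: tuple[str, ...] = ("ORF_T",)

    def __post_init__(self):
        if self.threshold <= 1:
            raise ValueError("fold-change threshold must be > 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


def canned_statistics(max_gap: int = 1000,
                      classes=None) -> dict:
    """The architecture statistics the shuffle stage evaluates by default."""
    return {
        "orientation_count": partial(nb.orientation_counts,
                                     max_gap=max_gap, classes=classes),
        "convergent_overlap_count": partial(nb.count_convergent_overlaps,
                                            classes=classes),
        "median_convergent_overlap_bp": partial(nb.median_convergent_overlap,
                                                classes=classes),
        "ymc_adjacency_count": partial(nb.ymc_adjacency_counts,
                                       max_gap=max_gap),
    }


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-12s %6.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = time.perf_counter()

    table = read_features(config.features, config.features_format)
    t = _stage("read", t)
    summary: dict = {"n_features": len(table),
                     "conditions": table.conditions,
                     "seed": config.seed}

    # switch classification -------------------------------------------------
    switches = classify_switch(table, config.cond_a, config.cond_b,
                               config.threshold, config.pseudocount)
    switches.to_csv(out / "switch_classes.tsv", sep="\t", index=False,
                    float_format="%.6g")
    counts = switch_counts(switches)
    summary["switch_counts"] = counts
    orf_ids = set(table.df.loc[table.df["feature_class"] == "ORF_T",
                               "feature_id"])
    sw = switches.set_index("feature_id")["switch"]
    changed = {g for g in orf_ids if sw[g] != "UNCHANGED"}
    oxrc = set(table.df.loc[table.df["ymc_phase"].isin(["OX", "RC"])
                            & (table.df["feature_class"] == "ORF_T"),
                            "feature_id"])
    if orf_ids:
        summary["oxrc_vs_switched"] = set_overlap(
            oxrc, changed, orf_ids, "OX+RC", ">3-fold changed")
    t = _stage("classify", t)

    # neighbourhood ---------------------------------------------------------
    relations = nb.assign_neighbors(table, config.max_gap)
    relations.to_csv(out / "neighbor_relations.tsv", sep="\t", index=False)
    adjacency = nb.ymc_adjacency(table, config.max_gap,
                                 config.adjacency_classes)
    adjacency.to_csv(out / "ymc_adjacency.tsv", sep="\t", index=False)
    adj_counts = nb.ymc_adjacency_counts(table, config.max_gap,
                                         config.adjacency_classes)
    summary["ymc_adjacency_counts"] = adj_counts
    summary["orientation_counts"] = nb.orientation_counts(table,
                                                          config.max_gap)
    cats = []
    for cond in (config.cond_a, config.cond_b):
        cats.append(nb.summarize_categories(table, relations, "ymc_phase",
                                            cond))
    pd.concat(cats, ignore_index=True).to_csv(
        out / "category_summary.tsv", sep="\t", index=False,
        float_format="%.6g")
    summary["median_convergent_overlap_bp"] = nb.median_convergent_overlap(
        table)
    t = _stage("neighbors", t)

    # antisense -------------------------------------------------------------
    if config.coverage_plus and config.coverage_minus:
        cov_p = read_coverage(config.coverage_plus, "+")
        cov_m = read_coverage(config.coverage_minus, "-")
        counts_df = anti_mod.count_antisense(cov_p, cov_m, table)
        counts_df.to_csv(out / "antisense_counts.tsv", sep="\t",
                         index=False, float_format="%.6g")
        summary["mean_antisense_fraction"] = round(
            anti_mod.mean_antisense_fraction(counts_df), 6)
        t = _stage("antisense", t)

    # shuffle null ----------------------------------------------------------
    model = ShuffleNullModel(
        table, canned_statistics(config.max_gap),
        ShuffleConfig(n_iter=config.n_iter, seed=config.seed))
    res = model.fit()
    res.to_tsv(out / "shuffle_results.tsv")
    key = "convergent_overlap_count"
    summary["convergent_overlap"] = {
        "observed": float(res.observed[key]),
        "null_mean": round(float(res.null_mean[key]), 6),
        "enrichment_ratio": round(float(res.enrichment_ratio[key]), 6),
        "p_greater": round(float(res.p_greater[key]), 8),
        "n_iter": res.n_iter,
    }
    summary["shuffle_p_greater"] = {
        k: round(float(v), 8) for k, v in res.p_greater.items()}
    t = _stage("shuffle", t)

    # factor enrichment -----------------------------------------------------
    if config.factor_matrix:
        matrix = FactorOccupancyMatrix.read_tsv(config.factor_matrix)
        phase = table.df.set_index("feature_id")["ymc_phase"]
        gene_set = [g for g in matrix.genes
                    if phase.get(g) == config.gene_set_phase]
        if gene_set:
            enr = factor_enrichment_test(matrix, gene_set, config.alpha)
            enr.to_csv(out / "factor_enrichment.tsv", sep="\t",
                       index=False, float_format="%.6g")
            summary["n_significant_factors"] = int(enr["significant"].sum())
            summary["factor_gene_set"] = {
                "phase": config.gene_set_phase, "n_genes": len(gene_set)}
        t = _stage("factors", t)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return summary


def _jsonify(obj):
    if isinstance(obj, set):
        return sorted(obj)
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
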