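"""End-to-end orchestration: preprocess → graphical model → layers →
per-layer SAM / node-activity comparisons / survival, with a reproducible
run manifest.

Every stage is a pure function of (inputs, config, seeds); re-running with
the same config and seed reproduces every output file byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import (ExpressionMatrix, filter_by_variability,
                         read_clinical_table, read_expression_matrix,
                         remove_batch_effect, write_expression_matrix)
from .groupstats import hypergeometric_enrichment, kruskal_wallis_dunn, read_gmt, sam_test
from .layers import PeelConfig, merge_layers, peel_layers
from .pgm import (forward_edge_search, likelihood_spanning_tree,
                  node_activity_matrix, pairwise_association,
                  split_into_branches)
from .simulate import CohortConfig, generate_cohort
from .survival import SurvivalInput, hazard_ratio, km_estimate, km_table, log_rank_test

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    # either a simulate block or paths to expression/clinical inputs
    simulate: dict | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    gene_sets_path: str | None = None
    sd_threshold: float = 1.0
    batch_correct: bool = True
    pgm: dict = field(default_factory=lambda: {
        "max_edges": 50, "candidate_scope": "distance2",
        "target_count": 13, "min_branch_size": 2})
    layers: dict = field(default_factory=lambda: {
        "k_range": [2, 3, 4], "n_resamples": 100, "pac_threshold": 0.3,
        "min_genes": 20, "max_layers": 9, "n_perms": 5,
        "ari_merge_threshold": 0.6})
    sam: dict = field(default_factory=lambda: {
        "n_perms": 200, "fdr_target": 0.05})
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    out_dir: Path
    manifest: dict
    layer_set: object | None = None
    nodes: list | None = None
    activities: pd.DataFrame | None = None


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_pipeline(cfg: RunConfig, out_dir) -> ReportBundle:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": asdict(cfg),
                "config_hash": cfg.config_hash(), "seed": cfg.seed,
                "stages": {}, "artifacts": []}
    stage = "input"
    try:
        truth = None
        if cfg.simulate is not None:
            sim_cfg = CohortConfig(**{**cfg.simulate, "seed": cfg.seed})
            expr, clinical, truth = generate_cohort(sim_cfg)
            write_expression_matrix(expr, out / "expression.tsv")
            clinical.table.to_csv(out / "clinical.csv", index=False,
                                  float_format="%.10g")
            _truth_json(truth, out / "truth.json")
            manifest["artifacts"] += ["expression.tsv", "clinical.csv", "truth.json"]
        else:
            if not cfg.expression_path or not cfg.clinical_path:
                raise ValueError("config needs a simulate block or "
                                 "expression_path + clinical_path")
            expr = read_expression_matrix(cfg.expression_path)
            clinical = read_clinical_table(cfg.clinical_path)
            if "batch" in clinical.table.columns:
                expr.batch = clinical.table.set_index("sample_id")["batch"] \
                    .reindex(expr.data.columns)
        manifest["stages"]["input"] = {"genes": expr.n_genes,
                                       "samples": expr.n_samples}

        stage = "preprocess"
        if cfg.batch_correct and expr.batch.nunique() > 1:
            expr = remove_batch_effect(expr)
        expr = filter_by_variability(expr, cfg.sd_threshold)
        manifest["stages"]["preprocess"] = {"genes": expr.n_genes,
                                            "samples": expr.n_samples,
                                            "sd_threshold": cfg.sd_threshold}

        stage = "pgm"
        assoc = pairwise_association(expr)
        tree = likelihood_spanning_tree(assoc)
        graph = forward_edge_search(
            tree, expr, max_edges=cfg.pgm.get("max_edges"),
            candidate_scope=cfg.pgm.get("candidate_scope", "distance2"))
        nodes = split_into_branches(
            graph, target_count=cfg.pgm.get("target_count", 13),
            min_size=cfg.pgm.get("min_branch_size", 2))
        activities = node_activity_matrix(expr, nodes)
        _write_tsv(pd.DataFrame(graph.edges, columns=["gene_a", "gene_b"]),
                   out / "network_edges.tsv", index=False)
        _write_tsv(pd.DataFrame(
            [(g, nd.label) for nd in nodes for g in nd.genes],
            columns=["gene", "node"]), out / "branches.tsv", index=False)
        _write_tsv(activities, out / "node_activities.tsv")
        manifest["stages"]["pgm"] = {
            "edges": graph.graph.number_of_edges(), "bic": graph.bic,
            "n_branches": len(nodes)}
        manifest["artifacts"] += ["network_edges.tsv", "branches.tsv",
                                  "node_activities.tsv"]

        stage = "layers"
        lcfg = PeelConfig(
            k_range=tuple(cfg.layers.get("k_range", (2, 3, 4))),
            n_resamples=cfg.layers.get("n_resamples", 100),
            pac_threshold=cfg.layers.get("pac_threshold", 0.3),
            min_genes=cfg.layers.get("min_genes", 20),
            max_layers=cfg.layers.get("max_layers", 9),
            n_perms=cfg.layers.get("n_perms", 5),
            gap_threshold=cfg.layers.get("gap_threshold", 0.5),
            seed=cfg.seed)
        ls = peel_layers(expr, lcfg)
        gene_sets = read_gmt(cfg.gene_sets_path) if cfg.gene_sets_path else None
        if ls.layers:
            ls = merge_layers(
                ls, ari_threshold=cfg.layers.get("ari_merge_threshold", 0.6),
                k_range=lcfg.k_range, n_resamples=lcfg.n_resamples,
                expression=expr, seed=cfg.seed)
            if gene_sets:
                for ly in ls.layers + ls.merged:
                    enr = hypergeometric_enrichment(
                        ly.genes, gene_sets, expr.gene_ids)
                    if enr.winning_label is not None:
                        ly.enrichment_label = enr.winning_label
        assignments = pd.DataFrame(index=expr.data.columns)
        for ly in ls.layers:
            _write_tsv(ly.gene_weights.rename("weight").to_frame(),
                       out / f"layer_{ly.index}_genes.tsv")
            assignments[f"layer_{ly.index}"] = ly.labels
        for ly in ls.merged:
            assignments[f"merged_{ly.index}"] = ly.labels
        _write_tsv(assignments, out / "sample_assignments.tsv")
        manifest["stages"]["layers"] = {
            "n_raw_layers": len(ls.layers),
            "n_merged_layers": len(ls.merged),
            "merge_map": {str(k): v for k, v in ls.merge_map.items()},
            "merged_labels": {f"merged_{ly.index}": ly.enrichment_label
                              for ly in ls.merged},
            "per_layer": [{"index": ly.index, "n_genes": len(ly.genes),
                           "k": ly.k, "pac": ly.pac} for ly in ls.layers]}
        manifest["artifacts"] += ["sample_assignments.tsv"]

        stage = "group_statistics"
        sam_summary = {}
        kw_summary = {}
        for ly in ls.merged:
            name = f"merged_{ly.index}"
            res = sam_test(expr.subset_genes(ly.genes), ly.labels,
                           n_perms=cfg.sam.get("n_perms", 200),
                           fdr_target=cfg.sam.get("fdr_target", 0.05),
                           seed=cfg.seed)
            _write_tsv(res.significant, out / f"sam_{name}.tsv", index=False)
            sam_summary[name] = {"delta": res.delta, "s0": res.s0,
                                 "fdr": res.fdr,
                                 "n_significant": len(res.significant)}
            kw_rows = []
            for _, node_act in activities.iterrows():
                mc = kruskal_wallis_dunn(node_act.to_numpy(),
                                         ly.labels.to_numpy())
                kw_rows.append((node_act.name, mc.h, mc.p))
            kw = pd.DataFrame(kw_rows, columns=["node", "H", "p"])
            _write_tsv(kw, out / f"node_activity_kw_{name}.tsv", index=False)
            kw_summary[name] = int((kw["p"] < 0.05).sum())
        manifest["stages"]["group_statistics"] = {
            "sam": sam_summary, "kw_significant_nodes": kw_summary}

        stage = "survival"
        surv_summary = {}
        clin = clinical.aligned_to(expr.sample_ids)
        for ly in ls.merged:
            name = f"merged_{ly.index}"
            s = SurvivalInput.from_clinical(clin, ly.labels)
            curves = km_estimate(s)
            _write_tsv(km_table(curves), out / f"km_{name}.tsv", index=False)
            chi2, p = log_rank_test(s)
            entry = {"chi_square": chi2, "p": p, "k": ly.k}
            if ly.k == 2:
                hr = hazard_ratio(s)
                entry.update({"hr": hr.hr, "ci": [hr.ci_low, hr.ci_high]})
            surv_summary[name] = entry
        manifest["stages"]["survival"] = surv_summary

        stage = "crosstab"
        label_cols = [c for c in ("cms", "stage", "location")
                      if c in clin.columns]
        crosstabs = {}
        for ly in ls.merged:
            name = f"merged_{ly.index}"
            for col in label_cols:
                ct = pd.crosstab(ly.labels, clin[col])
                ct_pct = pd.crosstab(ly.labels, clin[col], normalize="columns")
                _write_tsv(ct, out / f"crosstab_{name}_{col}.tsv")
                _write_tsv((100 * ct_pct).round(1),
                           out / f"crosstab_{name}_{col}_colpct.tsv")
                crosstabs[f"{name}_vs_{col}"] = ct.to_dict()
        if truth is not None:
            for layer_name in ("adhesion", "immune", "molecular"):
                tl = truth.layer_labels(layer_name)
                for ly in ls.merged:
                    name = f"merged_{ly.index}"
                    ct = pd.crosstab(ly.labels, tl)
                    crosstabs[f"{name}_vs_truth_{layer_name}"] = \
                        {str(k): {str(kk): int(vv) for kk, vv in v.items()}
                         for k, v in ct.to_dict().items()}
        manifest["stages"]["crosstab"] = {"tables": sorted(crosstabs)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    manifest["artifacts"].append("manifest.json")
    return ReportBundle(out_dir=out, manifest=manifest, layer_set=ls,
                        nodes=nodes, activities=activities)


def _truth_json(truth, path: Path) -> None:
    payload = {
        "adhesion": truth.adhesion.to_dict(),
        "immune": truth.immune.to_dict(),
        "molecular": {k: int(v) for k, v in truth.molecular.to_dict().items()},
        "gene_block": truth.gene_block.to_dict(),
        "beta_surv": truth.beta_surv,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
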