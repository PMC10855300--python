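"""End-to-end orchestration: explore -> cluster -> train -> score -> signature.

`run_discovery_pipeline` executes every stage on a validated expression matrix
and writes a deterministic bundle of TSV tables plus a JSON run summary;
rerunning with the same config and seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import consensus_signature, intersect_selected_features, unsupervised_contributors
from .datatypes import ExpressionMatrix, GroupAnnotation, RunConfig, ValidationError
from .explore import correlation_report, ecdf_table, group_difference_tests, zscore_profile
from .io import write_run_summary, write_table
from .scoring import ModelScore, mlcps_score, rank_models
from .supervised import (
    EvaluationResult,
    build_pairwise_tasks,
    default_model_configs,
    evaluate_model_grid,
    nested_cv_evaluate,
    results_table,
    rfecv_select_per_core,
)
from .unsupervised import clustree_transitions, elbow_profile, pca_decompose

__all__ = ["PipelineResult", "run_discovery_pipeline"]


@dataclass
class PipelineResult:
    tasks: list[str]
    evaluations: list[EvaluationResult]
    task_selections: dict[str, dict[str, tuple[str, ...]]]  # task -> core -> genes
    task_pools: dict[str, tuple[str, ...]]          # union over cores
    task_intersections: dict[str, tuple[str, ...]]  # strict intersection over cores
    contributors: tuple[str, ...]
    consensus: tuple[str, ...]
    consensus_report: dict = field(default_factory=dict)
    suggested_k: int | None = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise ValidationError(f"[stage:{name}] {exc}") from exc
        return inner
    return wrap


def run_discovery_pipeline(matrix: ExpressionMatrix, annotation: GroupAnnotation,
                           panel_genes=None, config: RunConfig | None = None,
                           out_dir: str | Path | None = None,
                           schemes: tuple[str, ...] = ("repeated", "nested"),
                           disease: str = "BPS") -> PipelineResult:
    """Run the full discovery pipeline and (optionally) write the bundle.

    Stages: exploratory statistics, unsupervised clustering/PCA, per-task
    RFE-CV selection, model-grid evaluation under the requested schemes,
    MLcps scoring and ranking, and the supervised/unsupervised consensus
    signature for ``disease``.
    """
    config = config or RunConfig()
    seed = config.random_seed
    if panel_genes:
        matrix = matrix.subset_genes(panel_genes)
    annotation.labels_for(matrix.sample_ids)  # completeness check
    annotation.require_min_per_group(2)
    tables: dict[str, pd.DataFrame] = {}

    # --- explore ------------------------------------------------------------
    explore_err = _stage("explore")
    zp = explore_err(zscore_profile)(matrix).to_frame()
    zp["group"] = [annotation[s] for s in zp["sample"]]
    tables["zscore_deviation"] = zp
    tables["ecdf"] = explore_err(ecdf_table)(matrix, annotation)
    tables["correlation"] = explore_err(correlation_report)(matrix).to_frame()
    tables["tests"] = explore_err(group_difference_tests)(matrix, annotation)

    # --- cluster ------------------------------------------------------------
    cluster_err = _stage("cluster")
    pca = cluster_err(pca_decompose)(matrix)
    tables["pca_scores"] = pca.scores_frame().reset_index(names="sample")
    tables["pca_contributions"] = pca.contributions_frame().reset_index(names="gene")
    tables["pca_variance"] = pd.DataFrame({
        "PC": [f"PC{i+1}" for i in range(len(pca.explained_variance_pct))],
        "explained_variance_pct": pca.explained_variance_pct,
    })
    kmax = min(7, matrix.n_samples)
    km_result, suggested_k, low_conf = cluster_err(elbow_profile)(
        matrix, range(1, kmax + 1), seed=seed, n_init=config.kmeans_restarts)
    tables["wss"] = pd.DataFrame({
        "k": sorted(km_result.wss), "wss": [km_result.wss[k] for k in sorted(km_result.wss)],
        "suggested": [k == suggested_k for k in sorted(km_result.wss)],
        "low_confidence": low_conf,
    })
    tables["assignments"] = pd.DataFrame(
        {"sample": list(matrix.sample_ids),
         **{f"k{k}": km_result.assignments[k] for k in sorted(km_result.assignments)}})
    tables["transitions"] = cluster_err(clustree_transitions)(km_result)

    # --- train --------------------------------------------------------------
    train_err = _stage("train")
    tasks = train_err(build_pairwise_tasks)(matrix, annotation, cv_folds=None)
    configs = default_model_configs(config)
    evaluations: list[EvaluationResult] = []
    task_selections: dict[str, dict[str, tuple[str, ...]]] = {}
    task_pools: dict[str, tuple[str, ...]] = {}
    task_intersections: dict[str, tuple[str, ...]] = {}
    audit: list = []
    for task in tasks:
        per_core = train_err(rfecv_select_per_core)(task, config, seed)
        task_selections[task.name] = {c: s.genes for c, s in per_core.items()}
        core_sets = [set(s.genes) for s in per_core.values()]
        task_pools[task.name] = tuple(sorted(set().union(*core_sets)))
        inter = intersect_selected_features(core_sets)
        task_intersections[task.name] = tuple(sorted(inter))
        best_core = max(per_core.values(), key=lambda s: max(s.cv_scores.values()))
        sub = task.subset_features(best_core.genes)
        if "repeated" in schemes:
            evaluations.extend(train_err(evaluate_model_grid)(
                sub, configs, config, seed, audit))
        if "nested" in schemes:
            evaluations.extend(train_err(nested_cv_evaluate)(
                sub, configs, config, seed, audit))
    for e in evaluations:
        e.selected_features = task_pools[e.task]

    # --- score --------------------------------------------------------------
    score_err = _stage("score")
    for task_name in {e.task for e in evaluations}:
        for scheme in {e.scheme for e in evaluations}:
            block = [e for e in evaluations
                     if e.task == task_name and e.scheme == scheme]
            scores = []
            for e in block:
                e.mlcps = score_err(mlcps_score)(e.metrics_mean)
                scores.append(ModelScore(e.config.model_id, e.metrics_mean,
                                         e.mlcps, e.metrics_mean[config.primary_metric]))
            ranked = {s.model_id: s.rank for s in rank_models(scores)}
            for e in block:
                e.rank = ranked[e.config.model_id]
    tables["metrics"] = results_table(evaluations)

    # --- signature ----------------------------------------------------------
    sig_err = _stage("signature")
    contributors = sig_err(unsupervised_contributors)(pca, config.contributor_top_n)
    disease_sets = [set(task_pools[t]) for t in task_pools
                    if t.startswith(f"{disease}_vs_") or t.endswith(f"_vs_{disease}")]
    if not disease_sets:
        disease_sets = [set(v) for v in task_pools.values()]
    consensus, report = sig_err(consensus_signature)(
        disease_sets, contributors, matrix=matrix, annotation=annotation,
        disease=disease, direction_filter=config.direction_filter)
    sel_rows = []
    for t, cores in task_selections.items():
        for core, genes in cores.items():
            sel_rows.append((t, core, ",".join(genes)))
        sel_rows.append((t, "pool", ",".join(task_pools[t])))
        sel_rows.append((t, "intersection", ",".join(task_intersections[t])))
    tables["selected_features"] = pd.DataFrame(
        sel_rows, columns=["task", "selector", "genes"])
    tables["signature"] = pd.DataFrame({
        "gene": sorted(consensus) or [""],
        "evidence": "supervised+unsupervised" if consensus else "EMPTY",
    })

    result = PipelineResult(
        tasks=[t.name for t in tasks], evaluations=evaluations,
        task_selections=task_selections, task_pools=task_pools,
        task_intersections=task_intersections,
        contributors=tuple(sorted(contributors)), consensus=tuple(sorted(consensus)),
        consensus_report=report, suggested_k=suggested_k, tables=tables,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            write_table(df, out_dir / f"{name}.tsv")
        with open(out_dir / "audit.json", "w") as fh:
            json.dump(audit, fh, indent=1, sort_keys=True)
            fh.write("\n")
        write_run_summary(out_dir / "summary.json", seed=seed, config=config,
                          extra={"tasks": result.tasks,
                                 "suggested_k": suggested_k,
                                 "consensus": sorted(consensus),
                                 "contributors": sorted(contributors),
                                 "consensus_report": report})
    return result
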