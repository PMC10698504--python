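"""Orchestration of the analysis stages with reproducible outputs.

Each stage is a plain function over in-memory objects; passing an
``out_dir`` additionally writes the stage's tables (TSV/JSON) and a
provenance record (model/config hashes, seeds, versions) so a run can
be reproduced from its outputs. The numbered scripts under ``analysis/``
are thin drivers around these functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from gemeval import evaluation, flux_ml, network_distance
from gemeval.fba_core import (
    GROWTH_CUTOFF,
    find_unconditional_essentials,
    knockout_grid,
)
from gemeval.model_io import FitnessDataset, MetabolicModel, match_dataset_to_model
from gemeval.scenarios import ScenarioSpec, remove_strain_genes

logger = logging.getLogger(__name__)

__all__ = [
    "run_simulation",
    "evaluate_predictions",
    "compare_models",
    "run_distance",
    "run_ml",
    "write_provenance",
]


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_provenance(out_dir: Path, **info) -> None:
    import gemeval

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {"gemeval_version": gemeval.__version__,
           "numpy_version": np.__version__, **info}
    (out_dir / "provenance.json").write_text(json.dumps(doc, indent=1,
                                                        default=str))


def run_simulation(model: MetabolicModel, dataset: FitnessDataset | None,
                   scenario: ScenarioSpec, genes=None, carbons=None,
                   record_fluxes: bool = False,
                   growth_cutoff: float = GROWTH_CUTOFF,
                   filter_unconditional: bool = True,
                   carbon_overrides: dict | None = None,
                   out_dir=None) -> dict:
    """Match the dataset to the model, drop unconditionally essential
    genes, and simulate the knockout grid.

    ``genes``/``carbons`` override the matched sets (used when
    re-simulating a corrected model on the experiment set fixed by the
    baseline run).
    """
    unmatched = pd.DataFrame(columns=["id", "kind", "reason"])
    if genes is None or carbons is None:
        if dataset is None:
            raise ValueError("either a dataset or explicit genes+carbons required")
        mg, mc, unmatched = match_dataset_to_model(model, dataset, carbon_overrides)
        genes = mg if genes is None else list(genes)
        carbons = mc if carbons is None else list(carbons)
    strain_removed = remove_strain_genes(model, scenario.removed_genes)
    excluded = set()
    if filter_unconditional:
        unconditional = find_unconditional_essentials(strain_removed, growth_cutoff)
        excluded = unconditional & set(genes)
        if excluded:
            logger.info("excluding %d unconditionally essential genes",
                        len(excluded))
    genes_eval = [g for g in genes if g not in excluded]
    table, fluxes = knockout_grid(
        model, genes_eval, carbons, scenario, fitness=dataset,
        record_fluxes=record_fluxes, growth_cutoff=growth_cutoff,
        carbon_overrides=carbon_overrides,
    )
    result = {"table": table, "fluxes": fluxes, "genes": genes_eval,
              "carbons": list(carbons), "excluded_unconditional": sorted(excluded),
              "unmatched_report": unmatched}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "predictions.tsv", sep="\t", index=False)
        unmatched.to_csv(out_dir / "unmatched.tsv", sep="\t", index=False)
        if record_fluxes and fluxes:
            keys = sorted(fluxes)
            mat = pd.DataFrame(
                np.vstack([fluxes[k] for k in keys]),
                columns=[r.id for r in model.reactions],
            )
            meta = pd.DataFrame(keys, columns=["gene", "carbon"])
            mat.to_csv(out_dir / "flux_matrix.tsv", sep="\t", index=False)
            meta.to_csv(out_dir / "flux_matrix_rows.tsv", sep="\t", index=False)
        write_provenance(
            out_dir, stage="simulate", model_id=model.id,
            model_hash=_hash([r.id for r in model.reactions]),
            scenario_hash=_hash(scenario.to_dict()),
            scenario=scenario.to_dict(), growth_cutoff=growth_cutoff,
            n_genes=len(genes_eval), n_carbons=len(carbons),
            excluded_unconditional=sorted(excluded),
        )
    return result


def evaluate_predictions(table: pd.DataFrame,
                         fitness_threshold: float = evaluation.FITNESS_THRESHOLD,
                         out_dir=None):
    """Full evaluation report plus per-carbon AUCs and error rankings."""
    report = evaluation.pr_auc(table, fitness_threshold)
    report.per_carbon = evaluation.per_carbon_auc(table)
    ranking = evaluation.rank_errors(table)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=1, default=float))
        report.pr_points.to_csv(out_dir / "pr_points.tsv", sep="\t", index=False)
        ranking.false_negatives.to_csv(out_dir / "false_negative_ranking.tsv",
                                       sep="\t", index=False)
        ranking.false_positives.to_csv(out_dir / "false_positive_ranking.tsv",
                                       sep="\t", index=False)
    return report, ranking


def compare_models(tables: dict,
                   fitness_threshold: float = evaluation.FITNESS_THRESHOLD,
                   out_dir=None) -> pd.DataFrame:
    """Evaluate several models' prediction tables on a shared dataset,
    raw and under the null model (each table padded with nonfunctional
    genes to the largest experiment count).

    ``tables`` maps model name -> prediction table, ordered small to
    large (the progression of model versions).
    """
    sizes = {name: len(evaluation._experiment_rows(t))
             for name, t in tables.items()}
    target = max(sizes.values())
    rows = []
    for name, t in tables.items():
        raw = evaluation.pr_auc(t, fitness_threshold)
        padded = evaluation.pr_auc(evaluation.pad_null(t, target),
                                   fitness_threshold)
        rows.append({
            "model": name, "n_experiments": sizes[name],
            "auc_pr": raw.auc_pr, "auc_roc": raw.auc_roc,
            "balanced_accuracy": raw.balanced_accuracy,
            "overall_accuracy": raw.overall_accuracy,
            "null_auc_pr": padded.auc_pr, "null_auc_roc": padded.auc_roc,
            "null_balanced_accuracy": padded.balanced_accuracy,
            "null_overall_accuracy": padded.overall_accuracy,
        })
    out = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out.to_csv(out_dir / "model_comparison.tsv", sep="\t", index=False)
    return out


def run_distance(model: MetabolicModel, table: pd.DataFrame,
                 carbon_specific_fraction: float = 0.8,
                 degree_threshold: int = network_distance.HUB_DEGREE_THRESHOLD,
                 keep=(), carbon_overrides: dict | None = None, out_dir=None):
    """Carbon-to-gene network distance distributions for the three
    experiment subsets."""
    dt = network_distance.distance_distributions(
        model, table, carbon_specific_fraction, degree_threshold, keep,
        carbon_overrides,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        dt.rows.to_csv(out_dir / "distances.tsv", sep="\t", index=False)
        summary = pd.DataFrame([
            {"subset": "all", "mean_distance": dt.mean_all},
            {"subset": "model_no_growth", "mean_distance": dt.mean_no_growth},
            {"subset": "carbon_specific_no_growth",
             "mean_distance": dt.mean_carbon_specific},
        ])
        summary.to_csv(out_dir / "distance_summary.tsv", sep="\t", index=False)
    return dt


def run_ml(table: pd.DataFrame, fluxes: dict, reaction_ids, labels=None,
           fitness_threshold: float = evaluation.FITNESS_THRESHOLD,
           n_splits: int = flux_ml.N_SPLITS, base_seed: int = 0,
           num_leaves: int = 5, out_dir=None) -> dict:
    """Flux-based misprediction analysis: assemble the flux matrix,
    reduce features, run the repeated-split classifier harness and the
    wild-type distance analysis."""
    matrix = flux_ml.assemble_matrix(table, fluxes, reaction_ids)
    cluster_map = flux_ml.filter_and_cluster(matrix.values)
    if labels is None:
        labels = flux_ml.fp_labels(matrix.fitness, fitness_threshold)
    dists, dist_stats = flux_ml.wildtype_distance(matrix)
    results, attribution, per_split_abs = flux_ml.run_cv_harness(
        matrix, labels, cluster_map, n_splits=n_splits, base_seed=base_seed,
        num_leaves=num_leaves,
    )
    out = {"matrix": matrix, "cluster_map": cluster_map, "labels": labels,
           "wt_distance": dists, "wt_distance_stats": dist_stats,
           "cv_results": results, "attribution": attribution,
           "per_split_abs_shap": per_split_abs}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_csv(out_dir / "cv_results.tsv", sep="\t", index=False)
        attribution.to_frame().to_csv(out_dir / "feature_importance.tsv",
                                      sep="\t", index=False)
        flux_ml.pca_coordinates(matrix).to_csv(out_dir / "pca.tsv", sep="\t",
                                               index=False)
        (out_dir / "ml_summary.json").write_text(json.dumps({
            "n_samples": len(matrix.samples),
            "n_reactions": len(matrix.reaction_ids),
            "n_retained": cluster_map.n_retained,
            "n_clusters": cluster_map.n_clusters,
            "fp_rate": float(np.mean(labels)),
            "auc_full_mean": float(results["auc_full"].mean()),
            "auc_unseen_mean": float(np.nanmean(results["auc_unseen"])),
            "auc_permuted_mean": float(results["auc_permuted"].mean()),
            "wt_distance_stats": dist_stats,
        }, indent=1))
    return out
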