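"""Score growth/no-growth predictions against gene fitness values.

The headline metric is the fitness-thresholded precision-recall AUC:
the positive class is model-predicted essentiality (simulated
no-growth), and a sliding threshold t on the fitness value calls an
experiment "experimentally essential" when fitness <= t. Lower fitness
is stronger evidence of essentiality. Precision and recall are traced
over the unique fitness values and integrated by the trapezoid rule
with the conventional (recall 0, precision 1) anchor.

PR-AUC is preferred here over overall accuracy or ROC AUC because the
data are heavily imbalanced (most knockouts have no phenotype); the
``pad_null`` helper quantifies that robustness by appending
nonfunctional genes (fitness 0, predicted growth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from gemeval.fba_core import WILDTYPE

logger = logging.getLogger(__name__)

FITNESS_THRESHOLD = -2.0  # experimental no-growth when fitness < -2

__all__ = [
    "FITNESS_THRESHOLD",
    "EvaluationReport",
    "ErrorRanking",
    "pr_curve",
    "pr_auc_scores",
    "pr_auc",
    "pad_null",
    "per_carbon_auc",
    "rank_errors",
]


def _experiment_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Knockout rows with a fitness value (wild-type rows carry none)."""
    rows = table[table["gene"] != WILDTYPE]
    return rows[rows["fitness"].notna()]


def pr_curve(y_true, scores):
    """Precision-recall points over the unique score values.

    ``y_true`` flags the positive class; an instance is predicted
    positive at threshold s when its score >= s. Thresholds run from the
    highest score down, so recall is non-decreasing. Ties collapse to a
    single threshold.
    """
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    n_pred = np.arange(1, len(y) + 1)
    # last index of each tied score block
    boundary = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    thresholds = s_sorted[boundary]
    precision = tp[boundary] / n_pred[boundary]
    recall = tp[boundary] / tp[-1] if tp[-1] > 0 else np.full(len(boundary), np.nan)
    return thresholds, recall, precision


def pr_auc_scores(y_true, scores) -> float:
    """Area under the precision-recall curve of :func:`pr_curve`,
    trapezoidal, anchored at (recall 0, precision 1). NaN when there are
    no positives."""
    y = np.asarray(y_true, dtype=bool)
    if len(y) == 0 or not y.any():
        return float("nan")
    _, recall, precision = pr_curve(y, scores)
    r = np.r_[0.0, recall]
    p = np.r_[1.0, precision]
    return float(np.trapezoid(p, r))


@dataclass
class EvaluationReport:
    auc_pr: float
    auc_roc: float
    balanced_accuracy: float
    overall_accuracy: float
    confusion: tuple  # (TP, FP, TN, FN) at the fitness threshold
    n_records: int
    fitness_threshold: float = FITNESS_THRESHOLD
    pr_points: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    per_carbon: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc_pr": self.auc_pr,
            "auc_roc": self.auc_roc,
            "balanced_accuracy": self.balanced_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "confusion": {k: int(v) for k, v in
                          zip(("TP", "FP", "TN", "FN"), self.confusion)},
            "n_records": self.n_records,
            "fitness_threshold": self.fitness_threshold,
            "per_carbon_auc": dict(self.per_carbon),
        }


def pr_auc(table: pd.DataFrame,
           fitness_threshold: float = FITNESS_THRESHOLD) -> EvaluationReport:
    """Full evaluation of a prediction table.

    The table needs columns gene, carbon, grows, fitness; wild-type rows
    and rows without fitness are excluded. The confusion matrix and the
    threshold-dependent accuracies call an experiment "experimentally
    essential" when fitness < ``fitness_threshold`` (strict).
    """
    rows = _experiment_rows(table)
    n = len(rows)
    essential = ~rows["grows"].to_numpy(dtype=bool)
    fitness = rows["fitness"].to_numpy(dtype=float)

    if n == 0 or not essential.any():
        logger.warning("no model-essential predictions; PR-AUC undefined (NaN)")
        auc = float("nan")
        points = pd.DataFrame(columns=["threshold", "recall", "precision"])
    else:
        thresholds, recall, precision = pr_curve(essential, -fitness)
        points = pd.DataFrame(
            {"threshold": -thresholds, "recall": recall, "precision": precision}
        )
        auc = float(np.trapezoid(np.r_[1.0, precision], np.r_[0.0, recall]))

    if n == 0 or essential.all() or not essential.any():
        roc = float("nan")
    else:
        roc = float(roc_auc_score(essential, -fitness))

    exp_ess = fitness < fitness_threshold
    tp = int(np.sum(essential & exp_ess))
    fp = int(np.sum(essential & ~exp_ess))
    fn = int(np.sum(~essential & exp_ess))
    tn = int(np.sum(~essential & ~exp_ess))
    tpr = tp / (tp + fn) if tp + fn else float("nan")
    tnr = tn / (tn + fp) if tn + fp else float("nan")
    balanced = (tpr + tnr) / 2
    overall = (tp + tn) / n if n else float("nan")
    return EvaluationReport(
        auc_pr=auc, auc_roc=roc, balanced_accuracy=balanced,
        overall_accuracy=overall, confusion=(tp, fp, tn, fn), n_records=n,
        fitness_threshold=fitness_threshold, pr_points=points,
    )


def pad_null(table: pd.DataFrame, target_n_experiments: int) -> pd.DataFrame:
    """Append nonfunctional-gene null rows (fitness exactly 0, predicted
    growth) until the experiment count reaches ``target_n_experiments``.

    Models of different sizes are compared on equal footing this way: a
    nonfunctional gene yields a correct growth prediction on every
    carbon, inflating accuracy metrics that reward true positives.
    """
    current = len(_experiment_rows(table))
    if target_n_experiments < current:
        raise ValueError(
            f"target {target_n_experiments} below current count {current}"
        )
    n_new = target_n_experiments - current
    if n_new == 0:
        return table.copy()
    carbons = sorted(table["carbon"].unique())
    rows = [
        {"gene": f"null_{i}", "carbon": carbons[i % len(carbons)],
         "biomass_flux": float("nan"), "grows": True, "fitness": 0.0}
        for i in range(n_new)
    ]
    return pd.concat([table, pd.DataFrame(rows)], ignore_index=True)


def per_carbon_auc(table: pd.DataFrame) -> dict:
    """PR-AUC restricted to each carbon source's rows; NaN (with a
    warning) for carbons without any model-essential prediction."""
    out = {}
    for carbon, sub in _experiment_rows(table).groupby("carbon"):
        essential = ~sub["grows"].to_numpy(dtype=bool)
        if not essential.any():
            logger.warning("carbon %s has no essential predictions; AUC NaN", carbon)
            out[carbon] = float("nan")
        else:
            out[carbon] = pr_auc_scores(essential, -sub["fitness"].to_numpy(float))
    return out


@dataclass
class ErrorRanking:
    """Candidate mispredictions ranked by mean fitness within their
    prediction class.

    ``false_negative_genes``: genes with model-essential predictions,
    highest mean fitness first (a high-fitness "essential" gene is a
    likely false negative). ``false_positive_genes``: genes with
    model-growth predictions, lowest mean fitness first.
    """

    false_negatives: pd.DataFrame
    false_positives: pd.DataFrame

    @property
    def false_negative_genes(self) -> list:
        return self.false_negatives["gene"].tolist()

    @property
    def false_positive_genes(self) -> list:
        return self.false_positives["gene"].tolist()


def rank_errors(table: pd.DataFrame) -> ErrorRanking:
    rows = _experiment_rows(table)
    ess = rows[~rows["grows"].astype(bool)]
    grow = rows[rows["grows"].astype(bool)]

    def _agg(sub: pd.DataFrame, ascending: bool) -> pd.DataFrame:
        if sub.empty:
            return pd.DataFrame(columns=["gene", "mean_fitness", "n"])
        agg = (sub.groupby("gene")["fitness"]
               .agg(mean_fitness="mean", n="size").reset_index())
        return (agg.sort_values(["mean_fitness", "gene"],
                                ascending=[ascending, True])
                .reset_index(drop=True))

    return ErrorRanking(
        false_negatives=_agg(ess, ascending=False),
        false_positives=_agg(grow, ascending=True),
    )
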