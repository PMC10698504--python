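"""Flux-space analysis of growth-predicted simulations.

Growth-predicted knockouts carry a full parsimonious flux vector. This
module assembles those vectors into a samples x reactions matrix,
reduces it (variance filter, then single-linkage clustering of columns
with |Pearson correlation| above a cutoff, one representative per
cluster), and trains a gradient-boosted tree classifier (LightGBM,
5 leaves, 100 trees, learning rate 0.1) to separate false positives
(experimental fitness below the threshold despite predicted growth)
from true positives. Accuracy is summarized as the precision-recall AUC
for the false-positive class over repeated 80%-carbon x 80%-gene
train/test splits, on the full held-out set and on the "unseen" subset
whose genes AND carbons never appear in training, plus a permuted-label
baseline.

Feature attribution uses exact TreeSHAP as implemented natively by
LightGBM (``pred_contrib``); values are reported for the true-positive
class and averaged across splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from gemeval.evaluation import FITNESS_THRESHOLD, pr_auc_scores
from gemeval.fba_core import GROWTH_CUTOFF, WILDTYPE

logger = logging.getLogger(__name__)

VARIANCE_MIN = 1e-7
CORRELATION_MIN = 0.99
N_SPLITS = 100

__all__ = [
    "FluxMatrix",
    "ClusterMap",
    "SplitSpec",
    "AttributionTable",
    "assemble_matrix",
    "filter_and_cluster",
    "wildtype_distance",
    "make_split",
    "fp_labels",
    "train_classifier",
    "evaluate_classifier",
    "shap_values",
    "attribute_features",
    "run_cv_harness",
    "pca_coordinates",
]


@dataclass
class FluxMatrix:
    samples: list  # (gene, carbon) pairs, growth-predicted knockouts
    values: np.ndarray  # len(samples) x len(reaction_ids)
    reaction_ids: list
    wild_type_rows: dict  # carbon -> flux vector
    fitness: np.ndarray  # aligned with samples; NaN when unmeasured

    @property
    def genes(self) -> list:
        return sorted({g for g, _ in self.samples})

    @property
    def carbons(self) -> list:
        return sorted({c for _, c in self.samples})


def assemble_matrix(predictions: pd.DataFrame, fluxes: dict,
                    reaction_ids=None) -> FluxMatrix:
    """Collect parsimonious flux vectors for every growth-predicted
    knockout, plus the per-carbon wild-type vectors."""
    grow = predictions[(predictions["gene"] != WILDTYPE)
                       & predictions["grows"].astype(bool)]
    samples, rows, fitness = [], [], []
    for rec in grow.itertuples(index=False):
        key = (rec.gene, rec.carbon)
        if key not in fluxes:
            raise KeyError(f"no recorded fluxes for growth row {key}")
        samples.append(key)
        rows.append(np.asarray(fluxes[key], dtype=float))
        fitness.append(rec.fitness)
    if not samples:
        raise ValueError("no growth-predicted samples to assemble")
    wt = {c: np.asarray(v, dtype=float) for (g, c), v in fluxes.items()
          if g == WILDTYPE}
    values = np.vstack(rows)
    if reaction_ids is None:
        reaction_ids = [f"rxn_{j}" for j in range(values.shape[1])]
    return FluxMatrix(samples=samples, values=values,
                      reaction_ids=list(reaction_ids), wild_type_rows=wt,
                      fitness=np.asarray(fitness, dtype=float))


@dataclass
class ClusterMap:
    retained_columns: list  # column indices passing the variance filter
    clusters: list  # partition of retained_columns (lists of indices)
    representatives: list  # lowest-index member of each cluster

    @property
    def n_retained(self) -> int:
        return len(self.retained_columns)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def filter_and_cluster(values: np.ndarray, var_min: float = VARIANCE_MIN,
                       corr_min: float = CORRELATION_MIN) -> ClusterMap:
    """Drop columns with variance < ``var_min``; group the rest into
    connected components of the |Pearson correlation| > ``corr_min``
    graph (sign-agnostic, so exactly counter-running fluxes such as a
    proton/sodium symporter pair share a cluster)."""
    X = np.asarray(values, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to filter and cluster")
    retained = np.flatnonzero(X.var(axis=0) >= var_min)
    if len(retained) == 0:
        return ClusterMap([], [], [])
    corr = np.corrcoef(X[:, retained], rowvar=False)
    if corr.ndim == 0:  # single retained column
        corr = np.array([[1.0]])
    adj = np.abs(corr) > corr_min
    # union-find over the adjacency
    parent = list(range(len(retained)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(retained)):
        for j in range(i + 1, len(retained)):
            if adj[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list] = {}
    for i in range(len(retained)):
        groups.setdefault(find(i), []).append(int(retained[i]))
    clusters = [sorted(v) for _, v in sorted(groups.items())]
    return ClusterMap(
        retained_columns=[int(c) for c in retained],
        clusters=clusters,
        representatives=[c[0] for c in clusters],
    )


def wildtype_distance(matrix: FluxMatrix):
    """Euclidean distance of each knockout flux vector from the same
    carbon's wild-type vector, with its Pearson correlation and linear
    fit against fitness."""
    dists = np.array([
        float(np.linalg.norm(matrix.values[i] - matrix.wild_type_rows[c]))
        for i, (_, c) in enumerate(matrix.samples)
    ])
    ok = ~np.isnan(matrix.fitness)
    if ok.sum() >= 3 and np.std(dists[ok]) > 0:
        r, p = stats.pearsonr(dists[ok], matrix.fitness[ok])
        fit = stats.linregress(dists[ok], matrix.fitness[ok])
        slope, intercept = fit.slope, fit.intercept
    else:  # degenerate: constant distances or too few points
        r = p = slope = intercept = float("nan")
    return dists, {"pearson_r": float(r), "p_value": float(p),
                   "slope": float(slope), "intercept": float(intercept)}


@dataclass(frozen=True)
class SplitSpec:
    seed: int
    train_carbons: frozenset
    train_genes: frozenset
    train_rows: np.ndarray
    test_rows_full: np.ndarray
    test_rows_unseen: np.ndarray


def make_split(matrix: FluxMatrix, seed: int,
               carbon_fraction: float = 0.8,
               gene_fraction: float = 0.8) -> SplitSpec:
    """Uniform random 80% of carbons and 80% of genes for training
    (floor rounding, at least 1 each). Train rows have both gene and
    carbon in training; the unseen test subset has neither."""
    carbons, genes = matrix.carbons, matrix.genes
    if len(carbons) < 2 or len(genes) < 2:
        raise ValueError("need at least 2 carbons and 2 genes to split")
    rng = np.random.default_rng(seed)
    n_c = max(1, int(np.floor(carbon_fraction * len(carbons))))
    n_g = max(1, int(np.floor(gene_fraction * len(genes))))
    train_c = frozenset(rng.choice(carbons, size=n_c, replace=False))
    train_g = frozenset(rng.choice(genes, size=n_g, replace=False))
    in_c = np.array([c in train_c for _, c in matrix.samples])
    in_g = np.array([g in train_g for g, _ in matrix.samples])
    return SplitSpec(
        seed=seed, train_carbons=train_c, train_genes=train_g,
        train_rows=np.flatnonzero(in_c & in_g),
        test_rows_full=np.flatnonzero(~(in_c & in_g)),
        test_rows_unseen=np.flatnonzero(~in_c & ~in_g),
    )


def fp_labels(fitness: np.ndarray,
              threshold: float = FITNESS_THRESHOLD) -> np.ndarray:
    """False-positive labels for growth-predicted samples: 1 when the
    experimental fitness contradicts the growth prediction (< threshold,
    strict)."""
    return (np.asarray(fitness, dtype=float) < threshold).astype(int)


def _named(features: np.ndarray) -> pd.DataFrame:
    X = np.asarray(features, dtype=float)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def train_classifier(features: np.ndarray, labels: np.ndarray, seed: int = 0,
                     num_leaves: int = 5, n_estimators: int = 100,
                     learning_rate: float = 0.1):
    """Gradient-boosted decision trees for FP (label 1) vs TP (label 0)."""
    import lightgbm as lgb

    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = lgb.LGBMClassifier(
        boosting_type="gbdt", num_leaves=num_leaves, max_depth=-1,
        learning_rate=learning_rate, n_estimators=n_estimators,
        random_state=seed, n_jobs=1, verbose=-1, deterministic=True,
    )
    clf.fit(_named(features), y)
    return clf


def evaluate_classifier(clf, features: np.ndarray, labels: np.ndarray) -> float:
    """PR-AUC for the false-positive class, scored by the predicted FP
    probability; NaN when the evaluation set has no false positives."""
    prob_fp = clf.predict_proba(_named(features))[:, 1]
    return pr_auc_scores(np.asarray(labels, dtype=int) == 1, prob_fp)


def shap_values(clf, features: np.ndarray):
    """Exact TreeSHAP values for the true-positive class.

    Returns (values, base) where for each sample the base value plus the
    per-feature values reconstructs the model's raw margin for the TP
    class (the negative of the FP-class margin in binary LightGBM).
    """
    contrib = clf.booster_.predict(_named(features), pred_contrib=True)
    # columns: per-feature contributions to the FP raw score, then base
    return -contrib[:, :-1], -contrib[:, -1]


@dataclass
class AttributionTable:
    feature_names: list
    mean_shap: np.ndarray  # samples x features, averaged across splits
    mean_abs_shap: np.ndarray  # per-feature mean |SHAP|
    ranking: list  # feature indices sorted by mean |SHAP|, descending

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": [self.feature_names[i] for i in self.ranking],
            "mean_abs_shap": self.mean_abs_shap[self.ranking],
        })


def attribute_features(shap_sum: np.ndarray, n_splits: int,
                       feature_names) -> AttributionTable:
    mean_shap = shap_sum / n_splits
    mean_abs = np.abs(mean_shap).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    return AttributionTable(
        feature_names=list(feature_names), mean_shap=mean_shap,
        mean_abs_shap=mean_abs, ranking=[int(i) for i in order],
    )


def run_cv_harness(matrix: FluxMatrix, labels: np.ndarray,
                   cluster_map: ClusterMap, n_splits: int = N_SPLITS,
                   base_seed: int = 0, num_leaves: int = 5,
                   n_estimators: int = 100, learning_rate: float = 0.1):
    """Repeated train/test splits with full, unseen and permuted-label
    PR-AUCs, plus TP-class SHAP values averaged across splits.

    A draw whose training rows are single-class is replaced by a
    deterministic redraw (seed offset 1_000_000); with realistic base
    rates this is rare.
    """
    feats = matrix.values[:, cluster_map.representatives]
    names = [matrix.reaction_ids[j] for j in cluster_map.representatives]
    y = np.asarray(labels, dtype=int)
    records = []
    shap_sum = np.zeros_like(feats)
    per_split_abs = np.zeros((n_splits, feats.shape[1]))
    for k in range(n_splits):
        seed = base_seed + k
        split = make_split(matrix, seed)
        tries = 0
        while len(np.unique(y[split.train_rows])) < 2:
            tries += 1
            split = make_split(matrix, seed + tries * 1_000_000)
        clf = train_classifier(feats[split.train_rows], y[split.train_rows],
                               seed=seed, num_leaves=num_leaves,
                               n_estimators=n_estimators,
                               learning_rate=learning_rate)
        full = evaluate_classifier(clf, feats[split.test_rows_full],
                                   y[split.test_rows_full])
        unseen = (evaluate_classifier(clf, feats[split.test_rows_unseen],
                                      y[split.test_rows_unseen])
                  if len(split.test_rows_unseen) else float("nan"))
        rng = np.random.default_rng(seed)
        permuted = evaluate_classifier(
            clf, feats[split.test_rows_full],
            rng.permutation(y[split.test_rows_full]),
        )
        sv, _ = shap_values(clf, feats)
        shap_sum += sv
        per_split_abs[k] = np.abs(sv).mean(axis=0)
        records.append({"seed": seed, "auc_full": full, "auc_unseen": unseen,
                        "auc_permuted": permuted,
                        "fp_rate_test": float(np.mean(y[split.test_rows_full])),
                        "n_train": len(split.train_rows),
                        "n_test_full": len(split.test_rows_full),
                        "n_test_unseen": len(split.test_rows_unseen)})
    results = pd.DataFrame(records)
    attribution = attribute_features(shap_sum, n_splits, names)
    return results, attribution, per_split_abs


def pca_coordinates(matrix: FluxMatrix, n_components: int = 2,
                    standardize: bool = False) -> pd.DataFrame:
    """2-D principal-component projection of the flux vectors (knockouts
    plus wild-type rows), on raw fluxes by default."""
    from sklearn.decomposition import PCA

    wt_carbons = sorted(matrix.wild_type_rows)
    X = np.vstack([matrix.values]
                  + [matrix.wild_type_rows[c] for c in wt_carbons])
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    coords = PCA(n_components=n_components, random_state=0).fit_transform(X)
    genes = [g for g, _ in matrix.samples] + [WILDTYPE] * len(wt_carbons)
    carbons = [c for _, c in matrix.samples] + wt_carbons
    fitness = list(matrix.fitness) + [float("nan")] * len(wt_carbons)
    return pd.DataFrame({"gene": genes, "carbon": carbons,
                         "pc1": coords[:, 0], "pc2": coords[:, 1],
                         "fitness": fitness})
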