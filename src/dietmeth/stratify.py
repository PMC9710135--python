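"""Fibrosis-grade stratification from a CpG panel.

Two complementary evaluations of how well methylation at a called CpG panel
separates liver profiles by fibrosis grade:

* unsupervised — agglomerative (Ward, Euclidean) clustering of the sample
  profiles, then a Pearson Chi² test of independence between cluster
  membership and pathologist grade;
* supervised — a fixed-seed gradient-boosted tree ensemble classifying
  grade 0 vs grade 3+ under stratified k-fold cross-validation, reported as
  per-fold ROC AUC and pooled accuracy.

A two-way clustering helper returns deterministic sample/probe leaf orders
for heatmap rendering of combined blood + liver panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import chi2_contingency
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClusterGradeResult",
    "ClassifierReport",
    "HeatmapOrder",
    "cluster_and_test",
    "classify_grades",
    "cross_tissue_heatmap_order",
]

#: Fixed hyperparameters of the grade classifier (no AutoML search: the
#: panel, not the model, is the object under evaluation).  Capacity is kept
#: modest — stumps-plus-one boosting — because typical panels have ~10^2
#: features against ~10^2 samples and deeper ensembles overfit CV folds.
CLASSIFIER_PARAMS = dict(
    n_estimators=100,
    learning_rate=0.1,
    max_depth=2,
    subsample=1.0,
)


@dataclass
class ClusterGradeResult:
    linkage_method: str
    clusters: pd.Series            # cluster id per sample
    contingency: pd.DataFrame      # cluster × grade counts
    chi2_statistic: float
    degrees_of_freedom: int
    p_value: float
    min_expected_count: float


@dataclass
class ClassifierReport:
    fold_auc: np.ndarray
    mean_auc: float
    accuracy: float
    n_folds: int
    seed: int
    labels: tuple
    scores: pd.Series              # pooled held-out P(positive) per sample


def _graded_matrix(betas: pd.DataFrame, sheet: pd.DataFrame):
    """Samples × probes matrix and fibrosis grades for graded liver samples."""
    graded = sheet[sheet["fibrosis_grade"].notna()]
    cols = [s for s in graded["sample_id"] if s in betas.columns]
    grades = graded.set_index("sample_id").loc[cols, "fibrosis_grade"].astype(int)
    x = betas[cols].dropna(axis=0, how="any").to_numpy(dtype=float).T
    return x, grades, cols


def cluster_and_test(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    k: int | str = "auto",
    method: str = "ward",
    metric: str = "euclidean",
) -> ClusterGradeResult:
    """Ward clustering of liver profiles and a Chi² cluster-vs-grade test.

    ``k="auto"`` cuts the dendrogram into as many clusters as there are
    distinct grades.  The Chi² statistic is the continuity-free Pearson
    statistic; a warning is emitted when any expected cell count is < 5.
    """
    x, grades, cols = _graded_matrix(betas, sheet)
    n_grades = grades.nunique()
    if n_grades < 2:
        raise ValueError("need at least 2 distinct fibrosis grades")
    if k == "auto":
        k = n_grades
    if k > len(cols):
        raise ValueError(f"k={k} exceeds the {len(cols)} graded samples")
    z = linkage(x, method=method, metric=metric)
    clusters = pd.Series(
        fcluster(z, t=k, criterion="maxclust"), index=cols, name="cluster"
    )
    contingency = pd.crosstab(clusters, grades)
    chi2, p, dof, expected = chi2_contingency(contingency.to_numpy(), correction=False)
    min_expected = float(expected.min())
    if min_expected < 5:
        warnings.warn(
            f"minimum expected cell count {min_expected:.2f} < 5; "
            "the Chi2 approximation may be poor"
        )
    return ClusterGradeResult(
        linkage_method=method,
        clusters=clusters,
        contingency=contingency,
        chi2_statistic=float(chi2),
        degrees_of_freedom=int(dof),
        p_value=float(p),
        min_expected_count=min_expected,
    )


def classify_grades(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    positive: set = frozenset({3}),
    negative: set = frozenset({0}),
    n_folds: int = 5,
    seed: int = 0,
) -> ClassifierReport:
    """Cross-validated grade classification on the panel.

    Gradient-boosted trees with fixed hyperparameters, stratified k-fold CV;
    per-fold ROC AUC from held-out scores, pooled accuracy at a 0.5
    probability threshold.  Fully seeded: identical inputs and seed give
    identical per-fold AUCs.
    """
    x, grades, cols = _graded_matrix(betas, sheet)
    keep = grades.isin(list(positive) + list(negative)).to_numpy()
    x, cols = x[keep], [c for c, k_ in zip(cols, keep) if k_]
    y = grades[keep].isin(list(positive)).to_numpy().astype(int)
    for cls, name in ((1, "positive"), (0, "negative")):
        if (y == cls).sum() < n_folds:
            raise ValueError(
                f"{name} class has {(y == cls).sum()} samples < {n_folds} folds; "
                "reduce n_folds"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_auc = []
    scores = np.empty(len(y))
    for train, test in skf.split(x, y):
        model = GradientBoostingClassifier(random_state=seed, **CLASSIFIER_PARAMS)
        model.fit(x[train], y[train])
        prob = model.predict_proba(x[test])[:, 1]
        scores[test] = prob
        fold_auc.append(roc_auc_score(y[test], prob))
    fold_auc = np.asarray(fold_auc)
    accuracy = float(((scores >= 0.5).astype(int) == y).mean())
    return ClassifierReport(
        fold_auc=fold_auc,
        mean_auc=float(fold_auc.mean()),
        accuracy=accuracy,
        n_folds=n_folds,
        seed=seed,
        labels=(tuple(sorted(negative)), tuple(sorted(positive))),
        scores=pd.Series(scores, index=cols, name="p_positive"),
    )


@dataclass
class HeatmapOrder:
    sample_order: list
    probe_order: list
    sample_linkage: np.ndarray
    probe_linkage: np.ndarray


def cross_tissue_heatmap_order(betas: pd.DataFrame, sheet: pd.DataFrame) -> HeatmapOrder:
    """Deterministic two-way Ward clustering for heatmap rendering.

    Inputs are canonicalised by sorting sample and probe IDs before linkage,
    so the leaf orders are invariant to the order in which samples arrive.
    """
    if betas.shape[0] == 0:
        raise ValueError("empty probe panel")
    work = betas.sort_index(axis=0).sort_index(axis=1).dropna(axis=0, how="any")
    if work.shape[1] == 1:
        return HeatmapOrder(
            sample_order=list(work.columns),
            probe_order=list(work.index),
            sample_linkage=np.empty((0, 4)),
            probe_linkage=np.empty((0, 4)),
        )
    x = work.to_numpy(dtype=float)
    probe_z = linkage(x, method="ward") if x.shape[0] > 1 else np.empty((0, 4))
    sample_z = linkage(x.T, method="ward")
    probe_order = (
        [work.index[i] for i in leaves_list(probe_z)] if len(probe_z) else list(work.index)
    )
    sample_order = [work.columns[i] for i in leaves_list(sample_z)]
    return HeatmapOrder(
        sample_order=sample_order,
        probe_order=probe_order,
        sample_linkage=sample_z,
        probe_linkage=probe_z,
    )
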