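"""Aggregate Local Outlier Factor scoring and k-NN classification.

The LOF of a point is the ratio of the average local reachability density
of its neighbors to its own: approximately 1 inside homogeneous regions,
and above 1 for points whose neighborhood is locally sparser than that of
their neighbors — the signature of an anomalous patient. Definitions
follow Breunig et al.: with Euclidean distances,

    k-distance(p)      = distance to the k-th nearest neighbor
                         (the neighborhood includes every point at that
                         distance, so ties can enlarge it),
    reach-dist_k(p, o) = max(k-distance(o), d(p, o)),
    lrd_k(p)           = 1 / mean_{o in N_k(p)} reach-dist_k(p, o),
    LOF_k(p)           = mean_{o in N_k(p)} lrd_k(o) / lrd_k(p).

Duplicated points get infinite lrd; a point whose whole neighborhood is
duplicates has LOF 1 (it is indistinguishable from its neighbors).

The per-patient aggregate LOF — computed in the joint z-scored space of
the flagged anomaly parameters — is then the single feature of a k-NN
classifier separating EOP (positive class) from LOP, evaluated both
apparently and by seeded stratified cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortTable
from .pca import standardize

_LRD_CAP = 1e10  # lrd of a point whose whole neighborhood is duplicates


@dataclass(frozen=True)
class LOFScores:
    scores: np.ndarray
    k_lof: int
    feature_parameters: tuple[str, ...]


@dataclass(frozen=True)
class ClassificationReport:
    """EOP/LOP confusion summary; EOP is the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    cv_tp: int
    cv_fp: int
    cv_tn: int
    cv_fn: int
    cv_sensitivity: float
    cv_specificity: float
    k_nn: int
    folds: int
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def lof(points: np.ndarray, k_lof: int) -> LOFScores:
    """LOF scores for every row of ``points`` (n x d), Euclidean metric."""
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x.reshape(-1, 1)
    n = x.shape[0]
    if not 1 <= k_lof < n:
        raise ValueError(f"need 1 <= k_lof < n ({k_lof=}, {n=})")
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(dist, np.inf)  # a point is not its own neighbor

    sorted_dist = np.sort(dist, axis=1)
    k_distance = sorted_dist[:, k_lof - 1]
    # neighborhoods, tie-inclusive
    neighbors = [np.flatnonzero(dist[i] <= k_distance[i]) for i in range(n)]

    # a zero mean reachability (point duplicated >= k_lof times) gets a
    # large capped lrd; duplicates then score exactly 1 against each other
    lrd = np.empty(n)
    for i in range(n):
        nb = neighbors[i]
        reach = np.maximum(k_distance[nb], dist[i, nb])
        mean_reach = reach.mean()
        lrd[i] = _LRD_CAP if mean_reach == 0 else 1.0 / mean_reach

    scores = np.empty(n)
    for i in range(n):
        nb = neighbors[i]
        scores[i] = (lrd[nb] / lrd[i]).mean()
    return LOFScores(scores=scores, k_lof=k_lof, feature_parameters=())


def aggregate_lof(cohort: CohortTable, parameters, k_lof: int = 10) -> LOFScores:
    """Per-patient LOF in the joint z-scored space of selected parameters."""
    parameters = list(parameters)
    if not parameters:
        raise ValueError("parameter set must be non-empty")
    z = standardize(cohort.matrix(parameters), parameters)
    res = lof(z, k_lof)
    return LOFScores(scores=res.scores, k_lof=k_lof,
                     feature_parameters=tuple(parameters))


def _knn_predict(train_scores: np.ndarray, train_labels: np.ndarray,
                 test_scores: np.ndarray, k_nn: int) -> np.ndarray:
    """1-D k-NN majority vote; vote ties go to the single nearest neighbor."""
    preds = np.empty(test_scores.size, dtype=train_labels.dtype)
    for i, s in enumerate(test_scores):
        d = np.abs(train_scores - s)
        order = np.argsort(d, kind="stable")
        nb = order[:min(k_nn, train_scores.size)]
        votes = train_labels[nb]
        pos = int((votes == "EOP").sum())
        neg = votes.size - pos
        if pos > neg:
            preds[i] = "EOP"
        elif neg > pos:
            preds[i] = "LOP"
        else:
            preds[i] = train_labels[order[0]]
    return preds


def _confusion(labels: np.ndarray, preds: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(((labels == "EOP") & (preds == "EOP")).sum())
    fn = int(((labels == "EOP") & (preds == "LOP")).sum())
    tn = int(((labels == "LOP") & (preds == "LOP")).sum())
    fp = int(((labels == "LOP") & (preds == "EOP")).sum())
    return tp, fp, tn, fn


def knn_classify_cv(
    scores: np.ndarray,
    labels,
    k_nn: int = 5,
    folds: int = 10,
    seed: int = 0,
) -> ClassificationReport:
    """k-NN on the scalar LOF score, apparent and stratified-CV metrics.

    Apparent metrics come from fitting and predicting on all patients
    (each patient then contributes itself as a neighbor). CV metrics use
    seeded stratified folds; within each fold, neighbors come only from
    the training part.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray([str(g) for g in labels])
    classes = set(labels)
    if classes != {"EOP", "LOP"}:
        raise ValueError(f"need both EOP and LOP labels, got {sorted(classes)}")
    if k_nn % 2 == 0:
        raise ValueError("k_nn must be odd")
    counts = {c: int((labels == c).sum()) for c in classes}
    if folds > min(counts.values()):
        raise ValueError(
            f"folds={folds} exceeds the smallest class size "
            f"{min(counts.values())}; use fewer folds")

    apparent = _knn_predict(scores, labels, scores, k_nn)
    tp, fp, tn, fn = _confusion(labels, apparent)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_preds = np.empty_like(labels)
    for train, test in skf.split(scores.reshape(-1, 1), labels):
        if len(set(labels[train])) < 2:
            raise ValueError("a training fold has one class; use fewer folds")
        cv_preds[test] = _knn_predict(
            scores[train], labels[train], scores[test], k_nn)
    ctp, cfp, ctn, cfn = _confusion(labels, cv_preds)

    return ClassificationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        cv_tp=ctp, cv_fp=cfp, cv_tn=ctn, cv_fn=cfn,
        cv_sensitivity=ctp / (ctp + cfn),
        cv_specificity=ctn / (ctn + cfp),
        k_nn=k_nn, folds=folds, seed=seed)


def select_k(
    scores: np.ndarray,
    labels,
    candidate_ks=(1, 3, 5, 7, 9, 11, 13, 15),
    folds: int = 10,
    seed: int = 0,
) -> int:
    """Choose k_nn maximizing CV balanced accuracy; ties take the smallest k."""
    best_k, best_acc = None, -1.0
    for k in sorted(candidate_ks):
        rep = knn_classify_cv(scores, labels, k_nn=k, folds=folds, seed=seed)
        bal = (rep.cv_sensitivity + rep.cv_specificity) / 2.0
        if bal > best_acc + 1e-12:
            best_k, best_acc = k, bal
    return best_k


def scores_frame(cohort: CohortTable, lof_scores: LOFScores) -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": cohort.patient_ids,
        "group": cohort.group_labels,
        "LOF": lof_scores.scores,
    })


def boxplot_frame(cohort: CohortTable, lof_scores: LOFScores) -> pd.DataFrame:
    """Five-number summary of LOF scores per group (box-plot export)."""
    df = scores_frame(cohort, lof_scores)
    rows = []
    for g, sub in df.groupby("group", sort=True):
        q1, med, q3 = np.percentile(sub["LOF"], [25, 50, 75])
        rows.append({"group": g, "min": sub["LOF"].min(), "q1": q1,
                     "median": med, "q3": q3, "max": sub["LOF"].max()})
    return pd.DataFrame(rows)
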