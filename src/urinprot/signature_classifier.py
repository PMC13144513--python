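"""Staged SVM mutation-status classifier.

Pipeline: per-cohort stratified 70/30 split -> two-stage feature reduction
(intersection of top-ranked features by ANOVA F and by mutual information) ->
absolute-coefficient ranking with a linear-kernel SVM -> incremental feature
addition under repeated stratified cross-validation (5 splits x 3 repeats)
with the feature count chosen where train and validation performance meet ->
per-cohort held-out evaluation (ROC AUC, average precision, confusion matrix).

All data-dependent statistics (standardization moments, filter scores, SVM
coefficients, the chosen k) are learned from training data or training folds
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif, mutual_info_classif
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import ProteinMatrix

__all__ = [
    "SplitPlan",
    "FeatureSelectionTrace",
    "CohortEvaluation",
    "ClassifierReport",
    "split_cohorts",
    "filter_features",
    "rank_by_svm",
    "incremental_cv",
    "choose_k",
    "evaluate",
    "train_classifier",
    "restricted_train",
    "cross_cohort_mode",
]


def _svm() -> Pipeline:
    return Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="linear", C=1.0))]
    )


@dataclass
class SplitPlan:
    train_ids: dict[str, list[str]]  # cohort -> sample ids (70%)
    test_ids: dict[str, list[str]]  # cohort -> sample ids (30%)
    seed: int

    @property
    def combined_train(self) -> list[str]:
        return [sid for ids in self.train_ids.values() for sid in ids]


@dataclass
class FeatureSelectionTrace:
    candidates: list[str]
    ranked: list[str]
    coefficients: pd.Series  # feature -> |SVM coefficient|
    curve: pd.DataFrame  # per k: mean/sd of train & validation AUC/acc/AP
    chosen_k: int | None = None
    log: list[str] = field(default_factory=list)


@dataclass
class CohortEvaluation:
    cohort: str
    roc_points: pd.DataFrame | None
    auc: float
    pr_points: pd.DataFrame | None
    average_precision: float
    tp: int
    fp: int
    tn: int
    fn: int
    decision_values: pd.Series | None = None

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


@dataclass
class ClassifierReport:
    trace: FeatureSelectionTrace | None
    features: list[str]
    per_cohort: dict[str, CohortEvaluation]
    pooled: CohortEvaluation | None


def split_cohorts(
    meta: pd.DataFrame,
    labels: pd.Series,
    fraction: float = 0.7,
    seed: int = 0,
    stratify_extra: pd.Series | None = None,
) -> SplitPlan:
    """Stratified per-cohort train/test split.

    Stratifies by the binary label (optionally jointly with an extra column,
    e.g. diagnosis) within each cohort; the training fraction defaults to 70%.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    strat = labels.astype(str)
    if stratify_extra is not None:
        strat = strat + "|" + stratify_extra.loc[labels.index].astype(str)
    train: dict[str, list[str]] = {}
    test: dict[str, list[str]] = {}
    for cohort, ids in meta.loc[labels.index].groupby("cohort").groups.items():
        if labels.loc[ids].nunique() < 2:
            raise ValueError(f"cohort {cohort!r} lacks both classes")
        tr: list[str] = []
        te: list[str] = []
        for _, grp in pd.Index(ids).to_series().groupby(strat.loc[ids]):
            members = grp.index.to_numpy()
            rng.shuffle(members)
            n_train = int(round(fraction * len(members)))
            tr.extend(members[:n_train])
            te.extend(members[n_train:])
        if not te or not tr:
            raise ValueError(f"cohort {cohort!r}: empty train or test split")
        train[str(cohort)], test[str(cohort)] = sorted(tr), sorted(te)
    return SplitPlan(train, test, seed)


def filter_features(
    train: pd.DataFrame,
    labels: pd.Series,
    k_each: int = 256,
    min_intersection: int = 30,
    seed: int = 0,
    log: list[str] | None = None,
) -> list[str]:
    """First-stage reduction: intersect top-k features by F-test and by MI.

    Features are ranked by the ANOVA F statistic and, separately, by
    nearest-neighbour mutual information with the label; the candidate set is
    the intersection of the two top-``k_each`` lists, falling back to their
    union when the intersection is smaller than ``min_intersection``.
    Constant features rank last.
    """
    y = labels.loc[train.index].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes for feature filtering")
    X = train.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, _ = f_classif(X, y)
    f_stat = np.nan_to_num(f_stat, nan=-np.inf)  # constant features last
    mi = mutual_info_classif(X, y, n_neighbors=3, random_state=seed)
    cols = np.asarray(train.columns)
    top_f = set(cols[np.argsort(-f_stat, kind="stable")[:k_each]])
    top_mi = set(cols[np.argsort(-mi, kind="stable")[:k_each]])
    candidates = top_f & top_mi
    if len(candidates) < min_intersection:
        candidates = top_f | top_mi
        if log is not None:
            log.append(
                f"filter intersection {len(top_f & top_mi)} < {min_intersection}; "
                "fell back to union"
            )
    return sorted(candidates)


def rank_by_svm(
    train: pd.DataFrame, labels: pd.Series, candidates: list[str]
) -> tuple[list[str], pd.Series]:
    """Rank candidates by |coefficient| of one linear SVM fit on all of them."""
    if not candidates:
        raise ValueError("empty candidate set")
    y = labels.loc[train.index].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training data")
    model = _svm().fit(train[candidates].to_numpy(dtype=float), y)
    coefs = pd.Series(
        np.abs(model.named_steps["svm"].coef_[0]), index=candidates, name="abs_coef"
    )
    ranked = sorted(candidates, key=lambda f: (-coefs[f], f))
    return ranked, coefs


_METRICS = ("auc", "accuracy", "ap")


def _fold_metrics(model: Pipeline, X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    scores = model.decision_function(X)
    return (
        roc_auc_score(y, scores),
        float(np.mean((scores > 0) == (y == 1))),
        average_precision_score(y, scores),
    )


def incremental_cv(
    train: pd.DataFrame,
    labels: pd.Series,
    ranked: list[str],
    folds: int = 5,
    repeats: int = 3,
    seed: int = 0,
    max_k: int | None = None,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Repeated stratified CV performance as features are added in rank order.

    For each k, the linear SVM is refit on the top-k features inside each of
    the ``folds * repeats`` fold-fits; standardization is learned per training
    fold.  Returns a per-k frame of train/validation metric means and sds.
    Fold draws with a single-class fold are redrawn with a new seed (at most
    five attempts).
    """
    if not ranked:
        raise ValueError("empty ranked list")
    y = labels.loc[train.index].to_numpy()
    y_bin = (y == np.max(y)).astype(int) if y.dtype != object else (y == sorted(set(y))[-1]).astype(int)
    K = len(ranked) if max_k is None else min(max_k, len(ranked))

    splits = None
    for attempt in range(5):
        cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed + attempt)
        candidate = list(cv.split(np.zeros(len(y_bin)), y_bin))
        if all(len(np.unique(y_bin[tr])) == 2 and len(np.unique(y_bin[va])) == 2 for tr, va in candidate):
            splits = candidate
            if attempt and log is not None:
                log.append(f"fold redraw needed ({attempt} extra attempts)")
            break
    if splits is None:
        raise ValueError("could not draw folds containing both classes")

    X_all = train[ranked].to_numpy(dtype=float)
    rows = []
    for k in range(1, K + 1):
        Xk = X_all[:, :k]
        per_fold = {("train", m): [] for m in _METRICS} | {("val", m): [] for m in _METRICS}
        for tr_idx, va_idx in splits:
            model = _svm().fit(Xk[tr_idx], y_bin[tr_idx])
            for split_name, idx in (("train", tr_idx), ("val", va_idx)):
                for m, v in zip(_METRICS, _fold_metrics(model, Xk[idx], y_bin[idx])):
                    per_fold[(split_name, m)].append(v)
        row: dict[str, float] = {"k": k}
        for (split_name, m), vals in per_fold.items():
            row[f"{split_name}_{m}_mean"] = float(np.mean(vals))
            row[f"{split_name}_{m}_sd"] = float(np.std(vals, ddof=1))
        rows.append(row)
    return pd.DataFrame(rows).set_index("k")


def choose_k(curve: pd.DataFrame, delta: float = 0.05, epsilon: float = 0.01,
             log: list[str] | None = None) -> int:
    """Feature count where train and validation AUC curves meet.

    The smallest k with train-validation AUC gap <= ``delta`` and validation
    AUC within ``epsilon`` of its maximum; if no k qualifies, the argmax of
    validation AUC (logged).
    """
    gap = curve["train_auc_mean"] - curve["val_auc_mean"]
    val = curve["val_auc_mean"]
    ok = (gap <= delta) & (val >= val.max() - epsilon)
    if ok.any():
        return int(curve.index[ok][0])
    if log is not None:
        log.append("no k met the gap/slack rule; using argmax validation AUC")
    return int(val.idxmax())


def _evaluate_one(
    name: str, scores: np.ndarray, y: np.ndarray, index: pd.Index
) -> CohortEvaluation:
    pred = scores > 0
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    if len(np.unique(y)) < 2:
        auc, ap = float("nan"), float("nan")
        roc_pts = pr_pts = None
    else:
        auc = float(roc_auc_score(y, scores))
        ap = float(average_precision_score(y, scores))
        fpr, tpr, _ = roc_curve(y, scores)
        roc_pts = pd.DataFrame({"fpr": fpr, "tpr": tpr})
        prec, rec, _ = precision_recall_curve(y, scores)
        pr_pts = pd.DataFrame({"precision": prec, "recall": rec})
    return CohortEvaluation(
        name, roc_pts, auc, pr_pts, ap, tp, fp, tn, fn,
        decision_values=pd.Series(scores, index=index),
    )


def evaluate(
    model: Pipeline,
    features: list[str],
    matrix: ProteinMatrix,
    labels: pd.Series,
    test_ids: dict[str, list[str]],
) -> tuple[dict[str, CohortEvaluation], CohortEvaluation]:
    """Per-cohort and pooled held-out metrics at decision threshold 0."""
    missing = [f for f in features if f not in matrix.protein_ids]
    if missing:
        raise ValueError(f"panel features absent from the matrix: {missing}")
    per_cohort: dict[str, CohortEvaluation] = {}
    all_scores, all_y, all_idx = [], [], []
    for cohort, ids in test_ids.items():
        X = matrix.data.loc[ids, features].to_numpy(dtype=float)
        y = labels.loc[ids].to_numpy().astype(int)
        scores = model.decision_function(X)
        per_cohort[cohort] = _evaluate_one(cohort, scores, y, pd.Index(ids))
        all_scores.append(scores)
        all_y.append(y)
        all_idx.extend(ids)
    pooled = _evaluate_one(
        "pooled", np.concatenate(all_scores), np.concatenate(all_y), pd.Index(all_idx)
    )
    return per_cohort, pooled


def train_classifier(
    matrix: ProteinMatrix,
    meta: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    k_each: int = 256,
    folds: int = 5,
    repeats: int = 3,
    delta: float = 0.05,
    epsilon: float = 0.01,
    max_k: int | None = None,
    plan: SplitPlan | None = None,
) -> ClassifierReport:
    """Full staged pipeline on one matrix: split, filter, rank, choose k, test."""
    labels = labels.astype(int)
    if plan is None:
        plan = split_cohorts(meta, labels, seed=seed)
    log: list[str] = []
    train_df = matrix.data.loc[plan.combined_train]
    candidates = filter_features(train_df, labels, k_each=k_each, seed=seed, log=log)
    ranked, coefs = rank_by_svm(train_df, labels, candidates)
    curve = incremental_cv(
        train_df, labels, ranked, folds=folds, repeats=repeats, seed=seed,
        max_k=max_k, log=log,
    )
    k = choose_k(curve, delta=delta, epsilon=epsilon, log=log)
    features = ranked[:k]
    model = _svm().fit(
        train_df[features].to_numpy(dtype=float),
        labels.loc[train_df.index].to_numpy(),
    )
    per_cohort, pooled = evaluate(model, features, matrix, labels, plan.test_ids)
    trace = FeatureSelectionTrace(candidates, ranked, coefs, curve, k, log)
    return ClassifierReport(trace, features, per_cohort, pooled)


def restricted_train(
    matrix: ProteinMatrix,
    meta: pd.DataFrame,
    labels: pd.Series,
    features: list[str],
    seed: int = 0,
    plan: SplitPlan | None = None,
) -> ClassifierReport:
    """Train on a fixed externally supplied panel, skipping all selection."""
    labels = labels.astype(int)
    missing = [f for f in features if f not in matrix.protein_ids]
    if missing:
        raise ValueError(f"fixed features absent from the matrix: {missing}")
    if plan is None:
        plan = split_cohorts(meta, labels, seed=seed)
    train_df = matrix.data.loc[plan.combined_train]
    model = _svm().fit(
        train_df[features].to_numpy(dtype=float),
        labels.loc[train_df.index].to_numpy(),
    )
    per_cohort, pooled = evaluate(model, features, matrix, labels, plan.test_ids)
    return ClassifierReport(None, list(features), per_cohort, pooled)


def cross_cohort_mode(
    matrix: ProteinMatrix,
    meta: pd.DataFrame,
    labels: pd.Series,
    selection_cohort: str,
    feature_universes: dict[str, set] | None = None,
    seed: int = 0,
    **kwargs,
) -> ClassifierReport:
    """Select features on one cohort's training split only.

    Candidate features not quantified in every designated test cohort's
    feature universe are dropped before ranking (leakage guard for features
    that would be unavailable at test time); training and evaluation then
    proceed as in the standard pipeline.
    """
    labels = labels.astype(int)
    plan = split_cohorts(meta, labels, seed=seed)
    if selection_cohort not in plan.train_ids:
        raise ValueError(f"unknown selection cohort {selection_cohort!r}")
    log: list[str] = []
    sel_df = matrix.data.loc[plan.train_ids[selection_cohort]]
    candidates = filter_features(
        sel_df, labels, k_each=kwargs.get("k_each", 256), seed=seed, log=log
    )
    if feature_universes:
        shared = set.intersection(*(set(u) for u in feature_universes.values()))
        dropped = [c for c in candidates if c not in shared]
        candidates = [c for c in candidates if c in shared]
        if dropped:
            log.append(f"dropped {len(dropped)} candidates absent from a test cohort")
    if not candidates:
        raise ValueError("no candidate features shared across all test cohorts")
    train_df = matrix.data.loc[plan.combined_train]
    ranked, coefs = rank_by_svm(train_df, labels, candidates)
    curve = incremental_cv(
        train_df, labels, ranked, seed=seed, max_k=kwargs.get("max_k"), log=log
    )
    k = choose_k(curve, delta=kwargs.get("delta", 0.05), epsilon=kwargs.get("epsilon", 0.01), log=log)
    features = ranked[:k]
    model = _svm().fit(
        train_df[features].to_numpy(dtype=float),
        labels.loc[train_df.index].to_numpy(),
    )
    per_cohort, pooled = evaluate(model, features, matrix, labels, plan.test_ids)
    trace = FeatureSelectionTrace(candidates, ranked, coefs, curve, k, log)
    return ClassifierReport(trace, features, per_cohort, pooled)
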