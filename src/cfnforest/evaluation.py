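"""Stratified cross-validation and macro classification metrics."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .cascade import CascadeConfig, fit_cascade
from .expression import (
    ExpressionMatrix,
    LabelSet,
    apply_normalization,
    knn_impute,
    zscore_normalize,
)

__all__ = ["FoldPlan", "MetricsReport", "stratified_kfold", "evaluate", "run_cv",
           "CVReport"]

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """A disjoint, exhaustive split of sample indices into k folds with
    per-class counts differing by at most one across folds."""

    k: int
    folds: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.k != len(self.folds):
            raise ValueError("k differs from the number of folds")
        all_idx = np.concatenate(self.folds) if self.folds else np.array([], dtype=int)
        if len(np.unique(all_idx)) != all_idx.size:
            raise ValueError("folds overlap")


@dataclass
class MetricsReport:
    class_list: list[str]
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def to_dict(self) -> dict:
        return {
            "class_list": self.class_list,
            "confusion": self.confusion.tolist(),
            "per_class": {
                c: {"precision": float(p), "recall": float(r), "f1": float(f)}
                for c, p, r, f in zip(self.class_list, self.precision,
                                      self.recall, self.f1)
            },
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
        }


def stratified_kfold(y: LabelSet, k: int, seed: int = 0) -> FoldPlan:
    """Deterministic stratified fold assignment (shuffled within classes)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = Counter(y.labels)
    for cls in y.class_list:
        if counts[cls] < k:
            raise ValueError(
                f"class {cls!r} has only {counts[cls]} samples, fewer than k={k}"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    idx = np.arange(len(y.sample_ids))
    folds = [test for _, test in skf.split(idx, y.class_indices())]
    return FoldPlan(k, [np.asarray(f, dtype=int) for f in folds])


def evaluate(
    y_true: list[str], y_pred: list[str], class_list: list[str] | None = None
) -> MetricsReport:
    """Per-class one-vs-rest precision/recall/F1 and their macro averages."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if class_list is None:
        seen: dict[str, None] = {}
        for lab in y_true:
            seen.setdefault(lab, None)
        class_list = list(seen)
    unknown = (set(y_true) | set(y_pred)) - set(class_list)
    if unknown:
        raise ValueError(f"labels outside the class list: {sorted(unknown)}")
    cm = confusion_matrix(y_true, y_pred, labels=class_list)
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=class_list, zero_division=0
    )
    acc = float(np.mean([t == q for t, q in zip(y_true, y_pred)]))
    return MetricsReport(list(class_list), cm, p, r, f1, acc)


@dataclass
class CVReport:
    fold_reports: list[MetricsReport]
    class_list: list[str]

    @property
    def macro_f1_mean(self) -> float:
        return float(np.mean([r.macro_f1 for r in self.fold_reports]))

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean([r.accuracy for r in self.fold_reports]))

    @property
    def accuracy_sd(self) -> float:
        accs = [r.accuracy for r in self.fold_reports]
        return float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "folds": [r.to_dict() for r in self.fold_reports],
            "aggregate": {
                "macro_precision_mean": float(
                    np.mean([r.macro_precision for r in self.fold_reports])
                ),
                "macro_recall_mean": float(
                    np.mean([r.macro_recall for r in self.fold_reports])
                ),
                "macro_f1_mean": self.macro_f1_mean,
                "macro_f1_sd": float(
                    np.std([r.macro_f1 for r in self.fold_reports], ddof=1)
                ) if len(self.fold_reports) > 1 else 0.0,
                "accuracy_mean": self.accuracy_mean,
                "accuracy_sd": self.accuracy_sd,
            },
        }


def run_cv(
    X: ExpressionMatrix,
    y: LabelSet,
    cfg: CascadeConfig | None = None,
    k: int = 5,
    seed: int = 0,
    impute_k: int = 5,
) -> CVReport:
    """k-fold cross-validation of the full pipeline without leakage.

    Per fold: the training part is imputed and z-scored on its own; the test
    part is imputed against the training samples and transformed with the
    training fold's normalization statistics; one cascade is fitted per fold.
    """
    cfg = cfg or CascadeConfig()
    plan = stratified_kfold(y, k, seed)
    reports: list[MetricsReport] = []
    for fold_no, test_idx in enumerate(plan.folds):
        train_idx = np.setdiff1d(np.arange(X.n_samples), test_idx)
        X_tr = ExpressionMatrix(
            [X.sample_ids[i] for i in train_idx], list(X.gene_ids),
            X.values[train_idx], X.missing_mask[train_idx],
        )
        X_te = ExpressionMatrix(
            [X.sample_ids[i] for i in test_idx], list(X.gene_ids),
            X.values[test_idx], X.missing_mask[test_idx],
        )
        if X_tr.missing_mask.any():
            X_tr_imp = knn_impute(X_tr, k=min(impute_k, X_tr.n_samples - 1))
        else:
            X_tr_imp = X_tr
        if X_te.missing_mask.any():
            X_te_imp = knn_impute(X_te, k=min(impute_k, X_tr.n_samples),
                                  reference=X_tr)
        else:
            X_te_imp = X_te
        X_tr_n, stats = zscore_normalize(X_tr_imp)
        X_te_n = apply_normalization(X_te_imp, stats)
        y_tr = y.subset(train_idx)
        model, _ = fit_cascade(X_tr_n.values, y_tr, cfg, seed=seed + fold_no)
        pred, _ = model.predict(X_te_n.values)
        rep = evaluate([y.labels[i] for i in test_idx], pred, list(y.class_list))
        reports.append(rep)
        logger.info("fold %d: accuracy %.4f macro-F1 %.4f",
                    fold_no + 1, rep.accuracy, rep.macro_f1)
    return CVReport(reports, list(y.class_list))
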