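"""Cross-validated classification of connectome edge features.

The protocol: vectorize each subject's connectome into its upper-triangle
edge features, split subjects with stratified k-fold cross-validation, and in
every fold (a) keep only edges whose two-sample t-test on the TRAINING
subjects has raw p < alpha, (b) fit a linear soft-margin SVM (C = 1) on those
edges, (c) score the held-out fold.  Performance is the arithmetic mean of
per-fold accuracy, precision and F1.  Connections selected in every fold form
the consensus set, ranked by mean |t| across folds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from fmsc.core import FmscError, flat_index_to_pair
from fmsc.stats import feature_t_scores

logger = logging.getLogger(__name__)


def stratified_kfold(
    labels: Sequence[int], k: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified k-fold partition of subject indices.

    Folds partition the index set; per-fold class counts differ by at most
    one from proportional allocation.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if k == n:
        # leave-one-out: singleton test folds, trivially stratified
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise FmscError(
            f"class {classes[np.argmin(counts)]} has {counts.min()} members, "
            f"fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(len(labels)), labels)]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary-classification confusion counts for one test fold."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise FmscError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray, positive: int = 1
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            TP=int(np.sum(pos_t & pos_p)),
            FP=int(np.sum(~pos_t & pos_p)),
            TN=int(np.sum(~pos_t & ~pos_p)),
            FN=int(np.sum(pos_t & ~pos_p)),
        )


def metrics_from_confusion(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, precision, F1) on [0, 1] from confusion counts.

    Accuracy = (TP+TN)/total; precision = TP/(TP+FP); F1 is the harmonic mean
    of precision and recall.  With no positive predictions precision is
    undefined and scored 0 (logged), keeping fold averages total.
    """
    if c.total == 0:
        raise FmscError("empty test fold")
    accuracy = (c.TP + c.TN) / c.total
    if c.TP + c.FP == 0:
        logger.warning("no positive predictions in fold: precision scored 0")
        precision = 0.0
    else:
        precision = c.TP / (c.TP + c.FP)
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return accuracy, precision, f1


@dataclass
class FoldResult:
    fold: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    selected_features: np.ndarray
    train_t: np.ndarray  # t statistic per selected feature, train fold only
    confusion: ConfusionCounts
    accuracy: float
    precision: float
    f1: float
    predictions: np.ndarray
    margins: np.ndarray  # signed decision-function values, test fold
    fallback_all_features: bool = False


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validated classification results."""

    model_name: str
    k: int
    seed: int
    alpha: float
    C: float
    n_features: int
    per_fold: list[FoldResult]
    accuracy_pct: float
    precision_pct: float
    f1_pct: float

    def subject_predictions(self, n_subjects: int) -> tuple[np.ndarray, np.ndarray]:
        """(predictions, margins) aligned on subject index; each subject is
        in exactly one test fold."""
        pred = np.full(n_subjects, -1, dtype=int)
        marg = np.zeros(n_subjects)
        for fr in self.per_fold:
            pred[fr.test_indices] = fr.predictions
            marg[fr.test_indices] = fr.margins
        if np.any(pred < 0):
            raise FmscError("test folds do not cover every subject")
        return pred, marg

    def fold_structure(self) -> tuple[tuple[int, ...], ...]:
        return tuple(tuple(int(i) for i in fr.test_indices) for fr in self.per_fold)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "k": self.k,
            "seed": self.seed,
            "alpha": self.alpha,
            "C": self.C,
            "n_features": self.n_features,
            "aggregate": {
                "accuracy_pct": self.accuracy_pct,
                "precision_pct": self.precision_pct,
                "f1_pct": self.f1_pct,
            },
            "per_fold": [
                {
                    "fold": fr.fold,
                    "test_indices": [int(i) for i in fr.test_indices],
                    "n_selected": int(fr.selected_features.size),
                    "selected_features": [int(i) for i in fr.selected_features],
                    "accuracy": fr.accuracy,
                    "precision": fr.precision,
                    "f1": fr.f1,
                    "predictions": [int(p) for p in fr.predictions],
                    "margins": [float(g) for g in fr.margins],
                    "fallback_all_features": fr.fallback_all_features,
                }
                for fr in self.per_fold
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def cross_validate(
    features: np.ndarray,
    labels: Sequence[int],
    k: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    C: float = 1.0,
    positive: int = 1,
    model_name: str = "model",
    empty_selection: str = "all",
) -> CVReport:
    """Stratified k-fold CV with fold-internal t-test feature selection.

    In each fold the t-test and the SVM see training subjects only; the test
    fold is touched once, for prediction.  A fold whose selection is empty
    falls back to all features by default (``empty_selection='all'``); with
    ``'skip'`` such folds contribute no metrics.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise FmscError("features must be subjects x p with one label per subject")
    if not np.all(np.isfinite(X)):
        raise FmscError("features must be finite")
    if empty_selection not in ("all", "skip"):
        raise FmscError("empty_selection must be 'all' or 'skip'")
    folds = stratified_kfold(y, k, seed)
    per_fold: list[FoldResult] = []
    for f, (train, test) in enumerate(folds):
        t_stat, p_val = feature_t_scores(X[train], y[train])
        selected = np.flatnonzero(p_val < alpha)
        fallback = False
        if selected.size == 0:
            if empty_selection == "skip":
                logger.warning("fold %d: empty selection, skipped", f)
                continue
            logger.warning("fold %d: empty selection, falling back to all features", f)
            selected = np.arange(X.shape[1])
            fallback = True
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[np.ix_(train, selected)], y[train])
        pred = clf.predict(X[np.ix_(test, selected)])
        margins = clf.decision_function(X[np.ix_(test, selected)])
        # sklearn's decision function is signed toward the larger class label;
        # re-sign toward the declared positive class
        if clf.classes_[1] != positive:
            margins = -margins
        conf = ConfusionCounts.from_predictions(y[test], pred, positive=positive)
        acc, prec, f1 = metrics_from_confusion(conf)
        per_fold.append(
            FoldResult(
                fold=f,
                train_indices=train,
                test_indices=test,
                selected_features=selected,
                train_t=t_stat[selected],
                confusion=conf,
                accuracy=acc,
                precision=prec,
                f1=f1,
                predictions=pred,
                margins=np.asarray(margins, dtype=float),
                fallback_all_features=fallback,
            )
        )
    if not per_fold:
        raise FmscError("every fold was skipped: no results")
    return CVReport(
        model_name=model_name,
        k=k,
        seed=seed,
        alpha=alpha,
        C=C,
        n_features=X.shape[1],
        per_fold=per_fold,
        accuracy_pct=100.0 * float(np.mean([fr.accuracy for fr in per_fold])),
        precision_pct=100.0 * float(np.mean([fr.precision for fr in per_fold])),
        f1_pct=100.0 * float(np.mean([fr.f1 for fr in per_fold])),
    )


def consensus_connections(
    r: CVReport,
    m: int,
    region_ids: Sequence[str] | None = None,
    top_n: int = 10,
) -> list[dict]:
    """Connections selected in ALL folds, ranked by mean |t| across folds.

    Each entry maps the flat edge index back to its region pair.  Ties in
    mean |t| break toward the smaller flat index.  Returns an empty list
    (with a warning) when no connection is common to every fold.
    """
    k = len(r.per_fold)
    common: set[int] | None = None
    t_by_feature: dict[int, list[float]] = {}
    for fr in r.per_fold:
        sel = set(int(i) for i in fr.selected_features)
        common = sel if common is None else (common & sel)
        for idx, t in zip(fr.selected_features, fr.train_t):
            t_by_feature.setdefault(int(idx), []).append(abs(float(t)))
    if not common:
        logger.warning("no connection selected in all %d folds", k)
        return []
    ranked = sorted(common, key=lambda idx: (-float(np.mean(t_by_feature[idx])), idx))
    out = []
    for idx in ranked[:top_n]:
        i, j = flat_index_to_pair(idx, m)
        entry = {
            "flat_index": idx,
            "region_pair": (i, j),
            "selection_frequency": 1.0,
            "mean_abs_t": float(np.mean(t_by_feature[idx])),
        }
        if region_ids is not None:
            entry["region_names"] = (region_ids[i], region_ids[j])
        out.append(entry)
    return out
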