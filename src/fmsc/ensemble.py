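"""Majority-vote combination of separately trained connectome classifiers.

Models trained on different networks (e.g. the best anatomical-similarity
model and the functional-connectivity model) can carry complementary signal;
a per-subject majority vote over their cross-validated predictions tests
this.  All voters must share the same fold structure so that every model's
prediction for a subject is an honest out-of-fold prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from fmsc.classify import ConfusionCounts, CVReport, FmscError, metrics_from_confusion


@dataclass
class VoteBundle:
    """Aligned out-of-fold predictions and decision margins from >= 2 models."""

    predictions: np.ndarray  # models x subjects
    margins: np.ndarray  # models x subjects, signed toward the positive class
    fold_structure: tuple[tuple[int, ...], ...]
    positive: int = 1
    negative: int = 0

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions, dtype=int)
        self.margins = np.asarray(self.margins, dtype=float)
        if self.predictions.ndim != 2 or self.predictions.shape[0] < 2:
            raise FmscError("vote bundle needs >= 2 models over aligned subjects")
        if self.margins.shape != self.predictions.shape:
            raise FmscError("margins shape must match predictions")

    @classmethod
    def from_reports(cls, reports: Sequence[CVReport], n_subjects: int) -> "VoteBundle":
        if len(reports) < 2:
            raise FmscError("need at least 2 models to vote")
        structure = reports[0].fold_structure()
        for r in reports[1:]:
            if r.fold_structure() != structure:
                raise FmscError(
                    "models have different fold structures (k/seed mismatch): "
                    "out-of-fold votes would not be aligned"
                )
        preds, margs = [], []
        for r in reports:
            p, g = r.subject_predictions(n_subjects)
            preds.append(p)
            margs.append(g)
        return cls(np.stack(preds), np.stack(margs), structure)


def vote_bundle_from_dicts(report_dicts: Sequence[dict]) -> VoteBundle:
    """Build a :class:`VoteBundle` from saved cross-validation report dicts."""
    if len(report_dicts) < 2:
        raise FmscError("need at least 2 saved reports to vote")
    structures = []
    preds, margs = [], []
    for d in report_dicts:
        folds = d["per_fold"]
        structure = tuple(tuple(int(i) for i in fr["test_indices"]) for fr in folds)
        structures.append(structure)
        n = max(i for fold in structure for i in fold) + 1
        p = np.full(n, -1, dtype=int)
        g = np.zeros(n)
        for fr in folds:
            p[fr["test_indices"]] = fr["predictions"]
            g[fr["test_indices"]] = fr["margins"]
        preds.append(p)
        margs.append(g)
    if any(s != structures[0] for s in structures[1:]):
        raise FmscError("saved reports have different fold structures")
    return VoteBundle(np.stack(preds), np.stack(margs), structures[0])


def majority_vote(b: VoteBundle, tie_break: str = "margin") -> np.ndarray:
    """Per-subject majority label over the bundled models.

    With an odd model count the majority is decisive and margins are ignored.
    Ties (even counts) resolve by ``tie_break``: ``'margin'`` takes the side
    with the larger summed |decision margin| (confidence), ``'positive'``
    takes the positive class, ``'abstain'`` predicts the negative class and
    flags nothing — an abstained tie simply scores as a miss when the subject
    is positive.

    Raw SVM decision values live on model-specific scales, so before the
    confidence comparison each model's margins are standardized by that
    model's median absolute margin.
    """
    if tie_break not in ("margin", "positive", "abstain"):
        raise FmscError(f"unknown tie_break {tie_break!r}")
    pos = b.predictions == b.positive
    n_pos = pos.sum(axis=0)
    n_neg = b.predictions.shape[0] - n_pos
    out = np.where(n_pos > n_neg, b.positive, b.negative)
    tied = n_pos == n_neg
    if np.any(tied):
        if tie_break == "positive":
            out[tied] = b.positive
        elif tie_break == "abstain":
            out[tied] = b.negative
        else:
            scale = np.median(np.abs(b.margins), axis=1, keepdims=True)
            scale[scale == 0] = 1.0
            conf = np.abs(b.margins) / scale
            pos_conf = np.where(pos, conf, 0.0).sum(axis=0)
            neg_conf = np.where(~pos, conf, 0.0).sum(axis=0)
            # equal calibrated confidence (e.g. single-subject bundles where
            # every margin normalizes to 1): fall back to raw margins
            pos_raw = np.where(pos, np.abs(b.margins), 0.0).sum(axis=0)
            neg_raw = np.where(~pos, np.abs(b.margins), 0.0).sum(axis=0)
            decided = np.where(pos_conf >= neg_conf, b.positive, b.negative)
            raw_decided = np.where(pos_raw >= neg_raw, b.positive, b.negative)
            decided = np.where(pos_conf == neg_conf, raw_decided, decided)
            out[tied] = decided[tied]
    return out


def evaluate_ensemble(
    b: VoteBundle, labels: Sequence[int], tie_break: str = "margin"
) -> dict:
    """Fold-wise metrics of the majority-vote predictions.

    The voted per-subject predictions are scored within each fold of the
    shared fold structure and averaged, mirroring single-model evaluation.
    """
    y = np.asarray(labels, dtype=int)
    voted = majority_vote(b, tie_break=tie_break)
    if voted.size != y.size:
        raise FmscError("labels length does not match bundled subjects")
    per_fold = []
    for f, test in enumerate(b.fold_structure):
        idx = np.asarray(test, dtype=int)
        conf = ConfusionCounts.from_predictions(y[idx], voted[idx], positive=b.positive)
        acc, prec, f1 = metrics_from_confusion(conf)
        per_fold.append({"fold": f, "accuracy": acc, "precision": prec, "f1": f1})
    return {
        "tie_break": tie_break,
        "per_fold": per_fold,
        "accuracy_pct": 100.0 * float(np.mean([d["accuracy"] for d in per_fold])),
        "precision_pct": 100.0 * float(np.mean([d["precision"] for d in per_fold])),
        "f1_pct": 100.0 * float(np.mean([d["f1"] for d in per_fold])),
        "predictions": [int(v) for v in voted],
    }
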