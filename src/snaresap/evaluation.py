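"""Confusion-matrix metrics, ROC/AUC and stratified cross-validation.

Metrics for the imbalanced SNARE / non-SNARE problem, with +1 the
positive (SNARE) class:

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    Acc = (TP + TN) / total
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FN)(TP+FP)(TN+FP))
    F   = 2*TP / (2*TP + FN + FP)

Any 0/0 denominator defines the metric as 0. MCC ranges over [-1, 1]
(its full mathematical range). AUC is the area under the ROC curve by
the trapezoidal rule, equal to the Mann-Whitney probability of correct
pair ranking with ties counted one half; it is computed on decision
scores, not probabilities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}

    @classmethod
    def from_dict(cls, d: dict) -> "ConfusionCounts":
        return cls(**d)


@dataclass
class EvaluationReport:
    """Metric bundle, optionally with per-fold detail and an ROC polyline."""

    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    f_score: float
    auc: float | None = None
    roc: np.ndarray | None = None  # (m, 2) array of (FPR, TPR) points
    per_fold: list["EvaluationReport"] | None = None
    pooled: "EvaluationReport | None" = None

    def to_dict(self) -> dict:
        d = {
            "counts": self.counts.to_dict(),
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "mcc": self.mcc,
            "f_score": self.f_score,
            "auc": self.auc,
        }
        if self.roc is not None:
            d["roc"] = np.asarray(self.roc).tolist()
        if self.per_fold is not None:
            d["per_fold"] = [f.to_dict() for f in self.per_fold]
        if self.pooled is not None:
            d["pooled"] = self.pooled.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            counts=ConfusionCounts.from_dict(d["counts"]),
            sn=d["sn"],
            sp=d["sp"],
            acc=d["acc"],
            mcc=d["mcc"],
            f_score=d["f_score"],
            auc=d.get("auc"),
            roc=None if d.get("roc") is None else np.array(d["roc"], dtype=float),
            per_fold=(
                None
                if d.get("per_fold") is None
                else [cls.from_dict(f) for f in d["per_fold"]]
            ),
            pooled=None if d.get("pooled") is None else cls.from_dict(d["pooled"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_pm1(a: np.ndarray, what: str) -> None:
    if not np.all(np.isin(a, (-1, 1))):
        raise ValueError(f"{what} must be +1/-1")


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Standard 2x2 table with +1 the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    if y_true.size:
        _check_pm1(y_true, "labels")
        _check_pm1(y_pred, "predictions")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def metrics(counts: ConfusionCounts) -> EvaluationReport:
    """Compute Sn/Sp/Acc/MCC/F from counts (AUC left unset).

    All intermediate products are exact Python integers; each metric is a
    single correctly-rounded float division (MCC: one sqrt, one division).
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn

    def ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    mcc_den = (tp + fn) * (tn + fn) * (tp + fp) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den) if mcc_den else 0.0
    return EvaluationReport(
        counts=counts,
        sn=ratio(tp, tp + fn),
        sp=ratio(tn, tn + fp),
        acc=ratio(tp + tn, counts.total),
        mcc=mcc,
        f_score=ratio(2 * tp, 2 * tp + fn + fp),
    )


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC polyline and trapezoidal AUC from decision scores.

    Equivalent to the Mann-Whitney probability that a random positive
    outranks a random negative, ties counted one half. Requires both
    classes.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("labels and scores must align")
    _check_pm1(y_true, "labels")
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _roc_curve(y_true, scores, pos_label=1, drop_intermediate=False)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


def evaluate(y_true, y_pred, scores=None) -> EvaluationReport:
    """Full report for one prediction set; adds ROC/AUC when scores given."""
    report = metrics(confusion(y_true, y_pred))
    if scores is not None:
        report.roc, report.auc = roc_auc(y_true, scores)
    return report


def cross_validate(M, cfg=None, folds: int = 10, seed: int = 0) -> EvaluationReport:
    """Stratified k-fold cross-validation of the kernel SVM.

    Folds come from a seeded stratified shuffle. The top-level report is
    the unweighted mean of per-fold metrics (the averaging convention for
    cross-validated results), with pooled confusion counts; a report
    computed from the pooled counts and all held-out scores is attached
    as ``pooled``, and per-fold reports are retained.
    """
    from .classifier import SVMConfig, predict, train

    cfg = cfg or SVMConfig()
    if M.y is None:
        raise ValueError("cross-validation requires labels")
    for cls_label in (-1, 1):
        n_cls = int(np.sum(M.y == cls_label))
        if n_cls < folds:
            raise ValueError(
                f"class {cls_label:+d} has {n_cls} samples, fewer than "
                f"{folds} folds; reduce the number of folds"
            )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_reports: list[EvaluationReport] = []
    pooled_counts = ConfusionCounts()
    all_true: list[np.ndarray] = []
    all_scores: list[np.ndarray] = []
    from .encoding import FeatureMatrix

    for train_idx, test_idx in skf.split(M.X, M.y):
        fold_train = FeatureMatrix(
            X=M.X[train_idx], y=M.y[train_idx], feature_ids=M.feature_ids
        )
        model = train(fold_train, cfg)
        labels, scores = predict(model, M.X[test_idx])
        rep = evaluate(M.y[test_idx], labels, scores)
        fold_reports.append(rep)
        pooled_counts = pooled_counts + rep.counts
        all_true.append(M.y[test_idx])
        all_scores.append(scores)

    pooled = metrics(pooled_counts)
    pooled.roc, pooled.auc = roc_auc(np.concatenate(all_true), np.concatenate(all_scores))

    def mean(attr: str) -> float:
        return float(np.mean([getattr(f, attr) for f in fold_reports]))

    return EvaluationReport(
        counts=pooled_counts,
        sn=mean("sn"),
        sp=mean("sp"),
        acc=mean("acc"),
        mcc=mean("mcc"),
        f_score=mean("f_score"),
        auc=mean("auc"),
        per_fold=fold_reports,
        pooled=pooled,
    )
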