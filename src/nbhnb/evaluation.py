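"""Data-splitting protocols and performance metrics.

The evaluation protocol mirrors common biomarker-study practice: 10% of the
samples are reserved as a blind holdout before any selection and scored
exactly once with the final model; all model comparison during selection
uses stratified 10-fold cross-validation on the remaining training split.

Binary reports carry accuracy, sensitivity, specificity and Mann-Whitney
AUC (ties counted 1/2); multi-class reports carry accuracy only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = ["EvaluationReport", "holdout_split", "stratified_kfold",
           "compute_metrics"]


@dataclass
class EvaluationReport:
    """Confusion-derived metrics for one evaluation pass."""

    accuracy: float
    n: int
    sensitivity: float = None
    specificity: float = None
    auc: float = None
    tp: int = None
    fp: int = None
    tn: int = None
    fn: int = None
    positive_class: object = None
    panel_size: int = None
    protocol: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        return json.dumps(d, sort_keys=True, default=str)

    def to_text(self) -> str:
        lines = [f"samples evaluated : {self.n}",
                 f"accuracy          : {self.accuracy:.4f}"]
        if self.sensitivity is not None:
            lines += [
                f"sensitivity       : {self.sensitivity:.4f}",
                f"specificity       : {self.specificity:.4f}",
                f"AUC               : "
                + ("n/a" if self.auc is None else f"{self.auc:.4f}"),
                f"positive class    : {self.positive_class}",
                f"confusion         : TP={self.tp} FP={self.fp} "
                f"TN={self.tn} FN={self.fn}",
            ]
        if self.panel_size is not None:
            lines.append(f"panel size        : {self.panel_size}")
        return "\n".join(lines) + "\n"


def holdout_split(y, fraction: float = 0.10, seed: int = 0,
                  stratified: bool = True):
    """Reserve a blind holdout of ``round(fraction * N)`` samples.

    Returns ``(train_idx, blind_idx)`` index arrays.  The blind set is
    class-stratified by default and must be evaluated exactly once, after
    panel selection.
    """
    y = np.asarray(y)
    n = y.shape[0]
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    _, counts = np.unique(y, return_counts=True)
    if stratified and counts.min() < 2:
        raise ValueError("stratified holdout needs >= 2 samples per class")
    n_blind = int(round(fraction * n))
    n_blind = max(n_blind, len(counts)) if stratified else max(n_blind, 1)
    train_idx, blind_idx = train_test_split(
        np.arange(n), test_size=n_blind, random_state=seed,
        stratify=y if stratified else None, shuffle=True)
    return np.sort(train_idx), np.sort(blind_idx)


def stratified_kfold(y, k: int = 10, seed: int = 0):
    """Stratified k-fold partition as a list of ``(train_idx, test_idx)``."""
    y = np.asarray(y)
    minority = np.bincount(y).min() if np.issubdtype(y.dtype, np.integer) \
        else np.unique(y, return_counts=True)[1].min()
    if k > minority:
        raise ValueError(f"k={k} exceeds minority class count {minority}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def compute_metrics(truth, predicted, positive_scores=None,
                    positive_class=None, panel_size=None,
                    protocol=None) -> EvaluationReport:
    """Confusion-derived metrics; AUC from positive-class posteriors.

    For binary labels, ``positive_class`` defaults to the lexically
    greater label (the "case" convention) and is echoed in the report.
    AUC is the probability a random positive outranks a random negative,
    ties counted 1/2 — requires ``positive_scores``.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    n = truth.shape[0]
    accuracy = float(np.mean(truth == predicted)) if n else float("nan")
    classes = np.unique(truth)
    rep = EvaluationReport(accuracy=accuracy, n=n, panel_size=panel_size,
                           protocol=protocol or {})
    if classes.size != 2:
        if positive_scores is not None and classes.size > 2:
            raise ValueError("AUC is defined for binary tasks only")
        return rep
    if positive_class is None:
        positive_class = max(classes)
    pos = truth == positive_class
    pred_pos = predicted == positive_class
    rep.tp = int(np.sum(pos & pred_pos))
    rep.fn = int(np.sum(pos & ~pred_pos))
    rep.fp = int(np.sum(~pos & pred_pos))
    rep.tn = int(np.sum(~pos & ~pred_pos))
    rep.sensitivity = rep.tp / (rep.tp + rep.fn) if (rep.tp + rep.fn) else float("nan")
    rep.specificity = rep.tn / (rep.tn + rep.fp) if (rep.tn + rep.fp) else float("nan")
    rep.positive_class = positive_class.item() if hasattr(positive_class, "item") \
        else positive_class
    if positive_scores is not None:
        scores = np.asarray(positive_scores, dtype=float)
        if scores.shape != truth.shape:
            raise ValueError("positive_scores must align with truth")
        rep.auc = float(roc_auc_score(pos.astype(int), scores))
    return rep
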