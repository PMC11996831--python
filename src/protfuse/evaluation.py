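"""Binary-classification metrics and the five-fold cross-validation protocol.

Confusion-matrix metrics (accuracy, precision, recall/TPR, F1, MCC, FPR)
are computed directly from the count definitions. ROC and PR curves, AUC
(trapezoidal) and AUPR (step-interpolated average precision) are computed
with scikit-learn. Cross-validation is stratified: the corpus is balanced
by construction, and stratification keeps every fold's class balance
deterministic.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import model as model_mod
from .embedding import EmbeddingSet, Standardizer
from .errors import ParameterError
from .model import ModelConfig

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "mcc", "fpr", "auc", "aupr")


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN tallies."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    fpr: float
    zero_denominators: tuple[str, ...] = ()


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Exact confusion tallies for binary labels/predictions (1 = positive)."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ParameterError(
            f"labels ({labels.shape}) and predictions ({predictions.shape}) differ in length"
        )
    if labels.size < 1:
        raise ParameterError("empty label vector")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
    )


def metrics_from_confusion(c: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall, F1, MCC and FPR from confusion counts.

    A metric whose denominator is zero is reported as 0 and flagged in
    ``zero_denominators`` (degenerate folds occur in ablation runs).
    """
    if c.total == 0:
        raise ParameterError("all confusion counts are zero")
    flags: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    accuracy = (tp + tn) / c.total
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ratio(tp * tn - fp * fn, mcc_den, "mcc")
    fpr = ratio(fp, fp + tn, "fpr")
    if flags:
        warnings.warn(f"zero denominator for: {', '.join(flags)}", stacklevel=2)
    return Metrics(accuracy, precision, recall, f1, mcc, fpr, tuple(flags))


@dataclass
class CurveReport:
    """ROC/PR curve points plus the areas under them."""

    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    pr_recall: np.ndarray
    pr_precision: np.ndarray
    auc: float
    aupr: float


def roc_pr_curves(labels: Sequence[int], scores: Sequence[float]) -> CurveReport:
    """ROC and PR curves from a descending threshold sweep over the scores.

    AUC is the trapezoidal area over (FPR, TPR); AUPR is step-interpolated
    average precision. Tied scores are grouped at one threshold.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ParameterError("labels and scores differ in length")
    if len(np.unique(labels)) < 2:
        raise ParameterError("ROC/PR curves require both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    prec, rec, _ = precision_recall_curve(labels, scores)
    aupr = float(average_precision_score(labels, scores))
    return CurveReport(fpr, tpr, thr, rec, prec, auc, aupr)


def kfold_split(
    n: int, k: int, labels: Sequence[int], seed: int
) -> list[np.ndarray]:
    """Stratified partition of ``range(n)`` into ``k`` disjoint folds."""
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    if n < k:
        raise ParameterError(f"cannot split {n} samples into {k} folds")
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != n:
        raise ParameterError("label vector length != n")
    counts = np.bincount(labels)
    if counts[counts > 0].min() < k:
        raise ParameterError(f"every class needs >= {k} members for {k}-fold stratification")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(n), labels)]


@dataclass
class FoldReport:
    """Per-fold metrics and curves, plus their across-fold means."""

    folds: list[dict] = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return json.dumps({"folds": clean(self.folds), "aggregate": clean(self.aggregate)},
                          indent=2)


def evaluate_fold(
    config: ModelConfig,
    params: dict,
    X_test: np.ndarray,
    y_test: np.ndarray,
) -> dict:
    """Metrics + curves for one held-out fold, evaluated as a single batch."""
    scores = model_mod.forward(X_test, config, params)
    preds = (scores >= 0.5).astype(int)
    m = metrics_from_confusion(confusion(y_test, preds))
    curves = roc_pr_curves(y_test, scores)
    entry = {name: getattr(m, name) for name in METRIC_NAMES[:6]}
    entry["auc"] = curves.auc
    entry["aupr"] = curves.aupr
    entry["roc"] = {"fpr": curves.fpr, "tpr": curves.tpr}
    entry["pr"] = {"recall": curves.pr_recall, "precision": curves.pr_precision}
    return entry


def cross_validate(
    embeddings: EmbeddingSet | np.ndarray,
    labels: Sequence[int],
    config: ModelConfig,
    k: int = 5,
    seed: int = 0,
    folds: list[np.ndarray] | None = None,
) -> FoldReport:
    """Stratified k-fold cross-validation of the hybrid classifier.

    Per fold: standardize on the training split only, train a fresh model
    (seed offset by the fold index), and evaluate the held-out split as
    one fixed batch. The aggregate is the arithmetic mean of the per-fold
    metrics. Pass ``folds`` to reuse a split across paired experiments.
    """
    X = embeddings.matrix if isinstance(embeddings, EmbeddingSet) else np.asarray(embeddings)
    y = np.asarray(labels, dtype=int)
    if folds is None:
        folds = kfold_split(X.shape[0], k, y, seed)
    report = FoldReport()
    for fold_idx, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(X.shape[0]), test_idx)
        scaler = Standardizer().fit(X[train_idx])
        X_tr, X_te = scaler.transform(X[train_idx]), scaler.transform(X[test_idx])
        fold_config = _with_seed(config, config.seed + 1000 * (fold_idx + 1))
        params, trace = model_mod.train(
            X_tr, y[train_idx], fold_config, validation=(X_te, y[test_idx])
        )
        entry = evaluate_fold(fold_config, params, X_te, y[test_idx])
        entry["fold"] = fold_idx
        entry["n_train"] = int(len(train_idx))
        entry["n_test"] = int(len(test_idx))
        entry["final_train_loss"] = trace[-1]
        report.folds.append(entry)
    report.aggregate = {
        name: float(np.mean([f[name] for f in report.folds])) for name in METRIC_NAMES
    }
    return report


def _with_seed(config: ModelConfig, seed: int) -> ModelConfig:
    cfg = asdict(config)
    cfg["seed"] = seed
    return ModelConfig(**cfg)
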