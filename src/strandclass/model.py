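"""Gradient-tree-boosting classification and cross-validated evaluation.

The classifier is sklearn's ``GradientBoostingClassifier`` — an additive
ensemble of depth-limited regression trees fitted to gradient residuals.
Evaluation follows the conventions of binary protein-class benchmarks:
single-stranded binders (SSB) are the positive class and the report carries
the raw confusion counts plus six metrics:

    SN  = TP / (TP + FN)                      (sensitivity / recall)
    SP  = TN / (TN + FP)                      (specificity)
    F1  = 2 * Recall * Precision / (Recall + Precision)
    Acc = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    AUC = P(score_pos > score_neg), ties counted 1/2 (rank statistic)

Degenerate denominators yield NaN, never a silent 0.  Headline metrics come
from predictions pooled across the held-out folds of a stratified k-fold
split, so the confusion counts cover every sample exactly once; per-fold
reports are retained alongside.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .types import FeatureMatrix, POSITIVE_LABEL, NEGATIVE_LABEL, StrandclassError


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the boosted ensemble plus the search grid.

    ``max_leaf_nodes`` bounds the number of leaves per tree (when set it takes
    precedence over ``max_depth`` in sklearn's implementation).  All
    randomness — fold shuffling and per-fit subsampling — derives from
    ``seed``.
    """

    n_trees: int = 200
    learning_rate: float = 0.1
    max_depth: int = 3
    max_leaf_nodes: Optional[int] = None
    subsample: float = 1.0
    seed: int = 0
    grid: Optional[Dict[str, List]] = None

    def estimator(self) -> GradientBoostingClassifier:
        return GradientBoostingClassifier(
            n_estimators=self.n_trees,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            max_leaf_nodes=self.max_leaf_nodes,
            subsample=self.subsample,
            random_state=self.seed,
        )


#: Grid searched by default when a config carries no explicit grid.
DEFAULT_GRID: Dict[str, List] = {
    "n_trees": [100, 200, 500],
    "learning_rate": [0.05, 0.1],
    "max_depth": [3, 5],
}


@dataclass
class EvalReport:
    """Confusion counts and the six headline metrics; NaN marks a metric whose
    denominator vanished."""

    tp: int
    tn: int
    fp: int
    fn: int
    sn: float
    sp: float
    f1: float
    accuracy: float
    mcc: float
    auc: float
    per_fold: List["EvalReport"] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in ("tp", "tn", "fp", "fn", "sn", "sp", "f1", "accuracy", "mcc", "auc")
        }
        if self.per_fold:
            d["per_fold"] = [f.to_dict() for f in self.per_fold]
        return d


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def auc_score(truth: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC: probability a random positive outscores a random
    negative, ties counted one half.  Invariant to strictly monotone
    transforms of the scores."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    r_pos = ranks[truth == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    truth: Sequence[int], predicted: Sequence[int], scores: Sequence[float]
) -> EvalReport:
    """Evaluate binary predictions against truth (1 = SSB positive).

    ``scores`` are positive-class probabilities aligned with ``truth`` and are
    used only for AUC; label metrics use ``predicted``.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    scores = np.asarray(scores, dtype=float)
    if not (truth.shape == predicted.shape == scores.shape):
        raise StrandclassError("truth, predicted and scores must align")
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise StrandclassError("scores must be probabilities in [0, 1]")
    tp = int(np.sum((truth == 1) & (predicted == 1)))
    tn = int(np.sum((truth == 0) & (predicted == 0)))
    fp = int(np.sum((truth == 0) & (predicted == 1)))
    fn = int(np.sum((truth == 1) & (predicted == 0)))
    sn = _safe_div(tp, tp + fn)
    sp = _safe_div(tn, tn + fp)
    precision = _safe_div(tp, tp + fp)
    recall = sn
    f1 = (
        _safe_div(2 * recall * precision, recall + precision)
        if not (math.isnan(precision) or math.isnan(recall))
        else float("nan")
    )
    accuracy = _safe_div(tp + tn, tp + tn + fp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom != 0 else float("nan")
    return EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sn=sn, sp=sp, f1=f1, accuracy=accuracy, mcc=mcc,
        auc=auc_score(truth, scores),
    )


def cross_validate(
    matrix: FeatureMatrix, config: ModelConfig, folds: int = 10
) -> EvalReport:
    """Stratified k-fold cross-validation with pooled out-of-fold predictions.

    Fold assignment is shuffled deterministically from ``config.seed``; the
    headline report pools the held-out predictions of all folds (so the
    confusion counts sum to the sample count) and per-fold reports are kept in
    ``per_fold``.
    """
    if folds < 2:
        raise StrandclassError(f"need at least 2 folds, got {folds}")
    y = matrix.y()
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < folds:
        raise StrandclassError(
            f"smallest class has {class_counts.min()} samples; cannot stratify "
            f"into {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    x = matrix.values
    oof_pred = np.empty(len(y), dtype=int)
    oof_score = np.empty(len(y), dtype=float)
    per_fold: List[EvalReport] = []
    for train_idx, test_idx in skf.split(x, y):
        est = config.estimator()
        est.fit(x[train_idx], y[train_idx])
        prob = est.predict_proba(x[test_idx])[:, list(est.classes_).index(1)]
        pred = (prob >= 0.5).astype(int)
        oof_pred[test_idx] = pred
        oof_score[test_idx] = prob
        per_fold.append(compute_metrics(y[test_idx], pred, prob))
    report = compute_metrics(y, oof_pred, oof_score)
    report.per_fold = per_fold
    return report


def grid_search(
    matrix: FeatureMatrix, config: ModelConfig, folds: int = 10
) -> Tuple[ModelConfig, List[Tuple[ModelConfig, EvalReport]]]:
    """Exhaustive grid search scored by cross-validated AUC.

    Candidates are evaluated in grid order; the winner maximises AUC with
    ties broken by accuracy and then by grid order.  Returns the winning
    config (grid cleared) and the full (config, report) trace.
    """
    grid = config.grid if config.grid else DEFAULT_GRID
    names = list(grid)
    trace: List[Tuple[ModelConfig, EvalReport]] = []
    best: Optional[Tuple[float, float, int]] = None
    best_cfg: Optional[ModelConfig] = None
    for order, combo in enumerate(itertools.product(*(grid[n] for n in names))):
        cand = replace(config, grid=None, **dict(zip(names, combo)))
        report = cross_validate(matrix, cand, folds=folds)
        trace.append((cand, report))
        key = (report.auc, report.accuracy, -order)
        if best is None or key > best:
            best, best_cfg = key, cand
    assert best_cfg is not None
    return best_cfg, trace


@dataclass
class TrainedModel:
    """A fitted ensemble frozen together with its training column list and
    configuration, so predictions on new data can enforce column identity."""

    estimator: GradientBoostingClassifier
    columns: List[str]
    config: ModelConfig

    def save(self, path) -> None:
        joblib.dump(
            {"estimator": self.estimator, "columns": self.columns,
             "config": asdict(self.config)},
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        payload = joblib.load(path)
        return cls(
            estimator=payload["estimator"],
            columns=list(payload["columns"]),
            config=ModelConfig(**payload["config"]),
        )


def train_final(matrix: FeatureMatrix, config: ModelConfig) -> TrainedModel:
    """Fit the ensemble on the full matrix and freeze it with its columns."""
    est = config.estimator()
    est.fit(matrix.values, matrix.y())
    return TrainedModel(estimator=est, columns=list(matrix.columns), config=config)


def predict(model: TrainedModel, matrix: FeatureMatrix) -> Tuple[np.ndarray, List[str]]:
    """Score new samples with a trained model.

    The matrix columns must match the training columns exactly, in order —
    silently reordered or missing columns are refused with an error naming
    the offenders.  Returns (positive-class scores, predicted labels).
    """
    if list(matrix.columns) != model.columns:
        missing = [c for c in model.columns if c not in set(matrix.columns)]
        extra = [c for c in matrix.columns if c not in set(model.columns)]
        detail = []
        if missing:
            detail.append(f"missing: {missing[:5]}")
        if extra:
            detail.append(f"unexpected: {extra[:5]}")
        if not detail:
            detail.append("columns present but reordered")
        raise StrandclassError(
            "prediction matrix columns do not match the training columns ("
            + "; ".join(detail) + ")"
        )
    prob = model.estimator.predict_proba(matrix.values)
    pos_idx = list(model.estimator.classes_).index(1)
    scores = prob[:, pos_idx]
    labels = [POSITIVE_LABEL if s >= 0.5 else NEGATIVE_LABEL for s in scores]
    return scores, labels
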