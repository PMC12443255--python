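"""Binary-classification evaluation: six metrics, ROC/AUC, stratified CV.

Metrics follow the standard confusion-count closed forms

    ACC = (TP+TN) / (TP+FP+TN+FN)
    SN  = TP / (TP+FN)                      (sensitivity / recall)
    SP  = TN / (TN+FP)                      (specificity)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    Precision = TP / (TP+FP)
    F1  = 2 * Precision * SN / (Precision + SN)

with the convention that any zero denominator yields a metric value of 0,
which keeps MCC and friends defined for degenerate predictors. AUC is the
trapezoidal area under the ROC curve built over descending score
thresholds (tied scores grouped), equal to the Mann-Whitney pairwise
statistic with ties counted one half.

Cross-validation is stratified and seeded. ``resample_mode="safe"``
applies ANBS inside each training fold only (no synthetic leakage into
test folds); ``"paper"`` balances the full set once before folding, the
protocol used when every model is evaluated on one pre-balanced dataset;
``"none"`` disables resampling for matched baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Literal, Optional

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .ensemble_model import EnsembleConfig, predict, train_ensemble
from .sampling import AnbsConfig, LabeledMatrix, anbs

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "CvResult",
    "confusion",
    "metric_suite",
    "roc_auc",
    "cross_validate",
    "METRIC_NAMES",
]

METRIC_NAMES = ("acc", "sn", "sp", "mcc", "f1", "precision")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies for one binary evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class RocCurve:
    """Ordered ROC points from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def confusion(y_true, y_pred, positive=1) -> ConfusionCounts:
    """Exact confusion tallies for binary labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
        fn=int((t & ~p).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def metric_suite(counts: ConfusionCounts) -> dict[str, float]:
    """ACC, SN, SP, MCC, F1 and Precision from confusion counts."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    acc = _safe_div(tp + tn, counts.total)
    sn = _safe_div(tp, tp + fn)
    sp = _safe_div(tn, tn + fp)
    precision = _safe_div(tp, tp + fp)
    mcc_den = sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    f1 = _safe_div(2 * precision * sn, precision + sn)
    return {"acc": acc, "sn": sn, "sp": sp, "mcc": mcc, "f1": f1, "precision": precision}


def roc_auc(scores, y_true, positive=1) -> tuple[RocCurve, float]:
    """ROC curve over descending unique thresholds and its trapezoidal area."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    pos = y_true == positive
    if pos.all() or (~pos).all():
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, thr = _sk_roc_curve(pos.astype(int), scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr), auc


@dataclass
class CvResult:
    """Per-fold metric table plus means; ``fold_assignment`` maps each row
    of the evaluated data to its test fold."""

    per_fold: pd.DataFrame
    mean: pd.Series
    fold_assignment: np.ndarray
    mode: str

    def write_csv(self, path) -> None:
        df = self.per_fold.copy()
        df.loc["mean"] = self.mean
        df.to_csv(path, index_label="fold")


def cross_validate(
    data: LabeledMatrix,
    config: Optional[EnsembleConfig] = None,
    folds: int = 10,
    resample_mode: Literal["paper", "safe", "none"] = "safe",
    anbs_config: Optional[AnbsConfig] = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> CvResult:
    """Stratified k-fold cross-validation of the soft-voting ensemble.

    Per-fold seeds derive deterministically from the master seed. In
    "safe" mode ANBS runs inside each training fold; in "paper" mode the
    full set is balanced once and folds are drawn from the balanced data;
    "none" trains on the raw folds.
    """
    if resample_mode not in {"paper", "safe", "none"}:
        raise ValueError(f"unknown resample_mode {resample_mode!r}")
    config = config or EnsembleConfig()
    positive = None  # inferred below as the larger class label

    work = data
    if resample_mode == "paper":
        cfg = anbs_config or AnbsConfig(seed=seed)
        work = anbs(data, cfg).data

    labels, counts = np.unique(work.y, return_counts=True)
    if len(labels) != 2:
        raise ValueError("cross_validate requires exactly two classes")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} rows < {folds} folds"
        )
    positive = labels[-1]

    fold_seeds = np.random.SeedSequence(seed).generate_state(folds + 1)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(fold_seeds[0] % (2**31)))
    rows = []
    assignment = np.full(work.y.shape[0], -1, dtype=int)
    for fold_no, (train_idx, test_idx) in enumerate(skf.split(work.X, work.y)):
        assignment[test_idx] = fold_no
        fold_seed = int(fold_seeds[fold_no + 1] % (2**31))
        train = LabeledMatrix(work.X[train_idx], work.y[train_idx])
        if resample_mode == "safe":
            cfg = anbs_config or AnbsConfig(seed=fold_seed)
            train = anbs(train, cfg).data
        fold_config = EnsembleConfig(
            members=config.members,
            weights=config.weights,
            seed=fold_seed,
            member_params=config.member_params,
        )
        model = train_ensemble(train, fold_config)
        y_pred, prob = predict(model, work.X[test_idx], threshold=threshold)
        metrics = metric_suite(confusion(work.y[test_idx], y_pred, positive=positive))
        try:
            _, auc = roc_auc(prob, work.y[test_idx], positive=positive)
        except ValueError:
            auc = float("nan")
        metrics["auc"] = auc
        rows.append(metrics)

    per_fold = pd.DataFrame(rows)
    return CvResult(
        per_fold=per_fold,
        mean=per_fold.mean(),
        fold_assignment=assignment,
        mode=resample_mode,
    )
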