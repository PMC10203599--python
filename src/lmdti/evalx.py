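"""Evaluation metrics and the holdout-plus-10-fold cross-validation protocol.

AUC is the area under the ROC curve; AUPR is step-interpolated average
precision.  Because drug-target data are heavily imbalanced, AUPR is the
headline metric; the derived error rate ER = 1 - AUPR and the relative
error-rate reduction dER = (ER2 - ER1) / ER2 compare two models.

The protocol splits the labelled pairs (stratified by label) into 11 equal
parts: part 11 is an independent holdout, and the remaining 10 parts are
the folds of a 10-fold cross-validation (each fold trains on 9 parts and
tests on 1).  The final model is refit on parts 1-10 and scored on the
holdout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass
class MetricReport:
    auc: float
    aupr: float
    er: float = field(init=False)

    def __post_init__(self) -> None:
        self.er = 1.0 - self.aupr

    def as_dict(self) -> dict[str, float]:
        return {"auc": self.auc, "aupr": self.aupr, "er": self.er}


@dataclass
class CVResult:
    fold_reports: list[MetricReport]
    holdout_report: MetricReport
    mean_auc: float = field(init=False)
    mean_aupr: float = field(init=False)
    sd_aupr: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_auc = float(np.mean([r.auc for r in self.fold_reports]))
        self.mean_aupr = float(np.mean([r.aupr for r in self.fold_reports]))
        self.sd_aupr = float(np.std([r.aupr for r in self.fold_reports], ddof=1))

    def as_dict(self) -> dict:
        return {
            "auc": self.mean_auc,
            "aupr": self.mean_aupr,
            "er": 1.0 - self.mean_aupr,
            "sd_aupr": self.sd_aupr,
            "per_fold": [r.as_dict() for r in self.fold_reports],
            "holdout": self.holdout_report.as_dict(),
        }


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be in {0, 1}")
    return labels


def compute_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based ROC AUC (midrank tie handling)."""
    labels = _check_binary(labels)
    if labels.min() == labels.max():
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def compute_aupr(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Average precision: step-interpolated area under the PR curve."""
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise ValueError("AUPR needs at least one positive")
    return float(average_precision_score(labels, scores))


def error_rate(aupr: float) -> float:
    """ER = 1 - AUPR."""
    if not 0.0 <= aupr <= 1.0:
        raise ValueError(f"AUPR {aupr} outside [0, 1]")
    return 1.0 - aupr


def relative_error_reduction(er1: float, er2: float) -> float:
    """dER = (ER2 - ER1) / ER2: the fraction of model 2's error removed by model 1."""
    if er2 <= 0:
        raise ValueError("reference error rate must be positive")
    return (er2 - er1) / er2


def metric_report(labels: Sequence[int], scores: Sequence[float]) -> MetricReport:
    return MetricReport(auc=compute_auc(labels, scores), aupr=compute_aupr(labels, scores))


def partition_eleven(labels: Sequence[int], seed: int) -> list[np.ndarray]:
    """Stratified split of sample indices into 11 near-equal parts."""
    labels = _check_binary(labels)
    skf = StratifiedKFold(n_splits=11, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def cross_validate(
    labels: Sequence[int],
    scorer: Callable[[np.ndarray, np.ndarray], np.ndarray],
    seed: int = 0,
) -> CVResult:
    """Run the 11-part protocol.

    ``scorer(train_idx, test_idx)`` must return prediction scores for the
    test indices after fitting on the train indices only; it is the hook
    through which the pipeline decides whether embeddings and path scores
    are recomputed per fold (leak-free) or computed once on the full graph.
    """
    labels = _check_binary(labels)
    parts = partition_eleven(labels, seed)
    holdout = parts[-1]
    cv_parts = parts[:-1]
    for k, part in enumerate(parts):
        if len(np.unique(labels[part])) < 2:
            raise ValueError(
                f"part {k + 1} contains a single class; stratification failed or too few samples"
            )
    fold_reports = []
    for k in range(10):
        test_idx = cv_parts[k]
        train_idx = np.concatenate([cv_parts[u] for u in range(10) if u != k])
        scores = np.asarray(scorer(np.sort(train_idx), np.sort(test_idx)))
        fold_reports.append(metric_report(labels[np.sort(test_idx)], scores))
    train_idx = np.sort(np.concatenate(cv_parts))
    holdout_scores = np.asarray(scorer(train_idx, np.sort(holdout)))
    holdout_report = metric_report(labels[np.sort(holdout)], holdout_scores)
    return CVResult(fold_reports=fold_reports, holdout_report=holdout_report)
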