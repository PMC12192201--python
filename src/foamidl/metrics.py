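"""Confusion-matrix metrics, ROC/AUC and stratified data splits.

ACC = (TP+TN)/(TP+TN+FP+FN), SEN = TP/(TP+FN), SPE = TN/(TN+FP); AUC is the
trapezoidal area under the ROC over all score thresholds, which equals the
Mann-Whitney probability with ties counted 1/2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .volio import ValidationError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "acc_sen_spe",
    "auc",
    "evaluate",
    "split_holdout",
    "kfold",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    acc: float
    sen: float
    spe: float
    auc: float
    counts: ConfusionCounts
    threshold: float = 0.5
    n: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n"] = self.counts.total
        return d

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return Path(path)


def _as_binary(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} must be binary 0/1")
    return arr.astype(int)


def confusion(labels, hard_calls) -> ConfusionCounts:
    """2x2 confusion counts; positive class is 1."""
    y = _as_binary(labels, "labels")
    c = _as_binary(hard_calls, "hard_calls")
    if y.shape != c.shape:
        raise ValidationError("labels and calls differ in length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (c == 1))),
        tn=int(np.sum((y == 0) & (c == 0))),
        fp=int(np.sum((y == 0) & (c == 1))),
        fn=int(np.sum((y == 1) & (c == 0))),
    )


def acc_sen_spe(c: ConfusionCounts) -> tuple[float, float, float]:
    """Accuracy, sensitivity, specificity; undefined denominators give NaN."""
    acc = (c.tp + c.tn) / c.total if c.total else float("nan")
    if c.tp + c.fn:
        sen = c.tp / (c.tp + c.fn)
    else:
        logger.warning("no positive subjects: sensitivity undefined (NaN)")
        sen = float("nan")
    if c.tn + c.fp:
        spe = c.tn / (c.tn + c.fp)
    else:
        logger.warning("no negative subjects: specificity undefined (NaN)")
        spe = float("nan")
    return acc, sen, spe


def auc(labels, scores) -> float:
    """Area under the ROC curve (ties counted 1/2)."""
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValidationError("AUC needs both classes present")
    return float(roc_auc_score(y, s))


def evaluate(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report: hard calls at ``threshold``, counts, ACC/SEN/SPE/AUC."""
    s = np.asarray(scores, dtype=float)
    calls = (s >= threshold).astype(int)
    counts = confusion(labels, calls)
    acc, sen, spe = acc_sen_spe(counts)
    return MetricsReport(
        acc=acc, sen=sen, spe=spe, auc=auc(labels, s),
        counts=counts, threshold=threshold, n=counts.total,
    )


def _check_class_sizes(labels: np.ndarray, minimum: int) -> None:
    vals, counts = np.unique(labels, return_counts=True)
    if len(vals) < 2 or counts.min() < minimum:
        raise ValidationError(
            f"each class needs >= {minimum} subjects, got {dict(zip(vals.tolist(), counts.tolist()))}"
        )


def split_holdout(
    manifest: pd.DataFrame, fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/hold-out split of a subject manifest by ``label``."""
    labels = _as_binary(manifest["label"].to_numpy(), "label")
    _check_class_sizes(labels, 2)
    idx_train, idx_test = train_test_split(
        np.arange(len(manifest)),
        train_size=fraction,
        stratify=labels,
        random_state=seed,
    )
    idx_train.sort()
    idx_test.sort()
    return manifest.iloc[idx_train].reset_index(drop=True), manifest.iloc[idx_test].reset_index(drop=True)


def kfold(
    manifest: pd.DataFrame, k: int = 5, seed: int = 0
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Stratified k-fold CV pairs; each subject validates exactly once."""
    labels = _as_binary(manifest["label"].to_numpy(), "label")
    _check_class_sizes(labels, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (
            manifest.iloc[np.sort(tr)].reset_index(drop=True),
            manifest.iloc[np.sort(va)].reset_index(drop=True),
        )
        for tr, va in skf.split(np.zeros(len(manifest)), labels)
    ]
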