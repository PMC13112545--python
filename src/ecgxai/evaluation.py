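"""Classification evaluation: splits, cross-validation folds, metrics.

Per-class precision/recall/F1 are computed from the 2x2 confusion matrix
(decision threshold 0.5 on the AFib probability unless predictions are
given); the ROC curve comes from a full threshold sweep with trapezoidal
AUC.  Everything is plain arithmetic on counts so the consistency between
the matrix and the derived rates is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .records import Rhythm

__all__ = ["Metrics", "split_dataset", "kfold_indices", "compute_metrics", "f1_from_pr"]

CLASS_NAMES = ("normal", "afib")


def split_dataset(n: int, train_fraction: float, seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Shuffled disjoint train/test index split.

    The train size is ``n * train_fraction`` rounded half-up, so a 90/10
    split of 5830 records gives exactly 5247 / 583.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(math.floor(n * train_fraction + 0.5))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves one side empty")
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train:]


def kfold_indices(n: int, k: int = 10, seed: int = 0) -> List[np.ndarray]:
    """``k`` disjoint exhaustive test folds with sizes differing by <= 1."""
    if k > n:
        raise ValueError("cannot make more folds than samples")
    if k < 2:
        raise ValueError("need at least 2 folds")
    perm = np.random.default_rng(seed).permutation(n)
    return [fold for fold in np.array_split(perm, k)]


@dataclass(frozen=True)
class Metrics:
    """Per-class rates plus the confusion matrix and ROC they derive from.

    ``confusion[i, j]`` counts records with true class ``i`` predicted as
    ``j`` in the order (normal, afib).
    """

    precision: Dict[str, float]
    recall: Dict[str, float]
    f1: Dict[str, float]
    confusion: np.ndarray
    roc_points: List[Tuple[float, float]]
    auc: float


def _to_indices(labels: Sequence) -> np.ndarray:
    out = []
    for lab in labels:
        r = lab if isinstance(lab, Rhythm) else Rhythm.parse(str(lab))
        out.append(CLASS_NAMES.index(r.value))
    return np.asarray(out, dtype=int)


def _roc(y: np.ndarray, scores: np.ndarray) -> Tuple[List[Tuple[float, float]], float]:
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last point of each tied-score run
    keep = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tps, fps = tps[keep], fps[keep]
    p, n = tps[-1], fps[-1]
    tpr = np.r_[0.0, tps / p]
    fpr = np.r_[0.0, fps / n]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def compute_metrics(
    y_true: Sequence, y_pred: Sequence, scores: Sequence[float]
) -> Metrics:
    """Full evaluation from labels, predictions and AFib probabilities."""
    yt, yp = _to_indices(y_true), _to_indices(y_pred)
    scores = np.asarray(scores, dtype=float)
    if not (len(yt) == len(yp) == len(scores)):
        raise ValueError("y_true, y_pred and scores must have equal lengths")
    if len(np.unique(yt)) < 2:
        raise ValueError("both classes must be present in y_true")

    confusion = np.zeros((2, 2), dtype=int)
    np.add.at(confusion, (yt, yp), 1)
    precision, recall, f1 = {}, {}, {}
    for i, name in enumerate(CLASS_NAMES):
        tp = confusion[i, i]
        predicted = confusion[:, i].sum()
        actual = confusion[i, :].sum()
        p = tp / predicted if predicted else 0.0
        r = tp / actual if actual else 0.0
        precision[name] = float(p)
        recall[name] = float(r)
        f1[name] = f1_from_pr(p, r)
    roc_points, auc = _roc(yt, scores)
    return Metrics(precision, recall, f1, confusion, roc_points, auc)


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
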