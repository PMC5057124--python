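"""Confusion counting, threshold metrics, k-fold CV, jackknife, and the
(w, lambda) parameter sweep.

Metrics follow the usual definitions over pooled confusion counts:

    Sn  = TP / (TP + FN)                       (sensitivity, % of true sites found)
    Sp  = TN / (TN + FP)                       (specificity)
    Acc = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Cross-validation pools confusion counts over the folds before computing
metrics rather than averaging per-fold metrics; this keeps the leave-one-out
(jackknife) case well defined, where each fold holds a single sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .model import train, predict
from .properties import PropertyTable
from .psednc import PseDNCConfig, encode_batch
from .sequence_io import SiteWindow

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.TN + other.TN,
            self.FN + other.FN,
        )

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """Sn/Sp/Acc as percentages (0-100), MCC in [-1, 1]."""

    Sn: float
    Sp: float
    Acc: float
    MCC: float
    counts: ConfusionCounts

    def __str__(self) -> str:
        return (
            f"Sn = {self.Sn:.2f}%  Sp = {self.Sp:.2f}%  "
            f"Acc = {self.Acc:.2f}%  MCC = {self.MCC:.2f}"
        )


def confusion_from_labels(
    true_labels: Sequence[int], predicted: Sequence[int]
) -> ConfusionCounts:
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise EvaluationError("label vectors differ in length")
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        FP=int(np.sum((t == -1) & (p == 1))),
        TN=int(np.sum((t == -1) & (p == -1))),
        FN=int(np.sum((t == 1) & (p == -1))),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Compute Sn, Sp, Acc (percent) and MCC from confusion counts.

    With an empty class the corresponding rate is NaN (warned); MCC is 0 by
    convention when any marginal of the confusion table is zero.
    """
    if counts.total == 0:
        raise EvaluationError("all confusion counts are zero")
    pos = counts.TP + counts.FN
    neg = counts.TN + counts.FP
    if pos == 0:
        logger.warning("no positive samples presented; Sn undefined (NaN)")
        sn = math.nan
    else:
        sn = 100.0 * counts.TP / pos
    if neg == 0:
        logger.warning("no negative samples presented; Sp undefined (NaN)")
        sp = math.nan
    else:
        sp = 100.0 * counts.TN / neg
    acc = 100.0 * (counts.TP + counts.TN) / counts.total
    denom = (
        (counts.TP + counts.FP)
        * (counts.TP + counts.FN)
        * (counts.TN + counts.FP)
        * (counts.TN + counts.FN)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (counts.TP * counts.TN - counts.FP * counts.FN) / math.sqrt(denom)
    return MetricsReport(sn, sp, acc, mcc, counts)


def _fold_indices(
    y: np.ndarray, k: int, seed: int | None
) -> list[np.ndarray]:
    """Held-out index sets for stratified k-fold; leave-one-out when k == n."""
    n = len(y)
    if k < 2:
        raise EvaluationError("k must be >= 2")
    if k > n:
        raise EvaluationError(f"k={k} exceeds sample count n={n}")
    if k == n:
        return [np.array([i]) for i in range(n)]
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if k > min(n_pos, n_neg):
        raise EvaluationError(
            f"k={k} exceeds the smaller class size ({min(n_pos, n_neg)}); "
            "stratified folds would be single-class"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=seed is not None, random_state=seed)
    return [test for _, test in skf.split(np.zeros(n), y)]


def kfold_cv(
    windows: Sequence[SiteWindow | str],
    labels: Sequence[int],
    config: PseDNCConfig,
    table: PropertyTable,
    C: float,
    gamma: float,
    k: int = 5,
    seed: int | None = 0,
) -> MetricsReport:
    """Stratified k-fold cross-validation of the full encode-train-predict
    pipeline; confusion counts pooled over folds. ``k == n`` degenerates to
    the jackknife (leave-one-out) exactly."""
    y = np.asarray(labels, dtype=int)
    if len(windows) != len(y):
        raise EvaluationError("windows and labels differ in length")
    X = encode_batch(list(windows), config, table)
    pooled = ConfusionCounts(0, 0, 0, 0)
    for test_idx in _fold_indices(y, k, seed):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        model = train(
            X[train_mask], y[train_mask], C, gamma, config, table.fingerprint()
        )
        pred = predict(model, X[test_idx])
        pooled = pooled + confusion_from_labels(y[test_idx], pred)
    return metrics(pooled)


def jackknife(
    windows: Sequence[SiteWindow | str],
    labels: Sequence[int],
    config: PseDNCConfig,
    table: PropertyTable,
    C: float,
    gamma: float,
) -> MetricsReport:
    """Leave-one-out test: each sample predicted by a model trained on all
    the others; fully deterministic, no fold randomness."""
    n = len(labels)
    if n < 2:
        raise EvaluationError("jackknife needs at least 2 samples")
    return kfold_cv(windows, labels, config, table, C, gamma, k=n, seed=None)


@dataclass(frozen=True)
class SweepResult:
    """Cross-validated accuracy over a (w, lambda) grid.

    ``accuracy`` is indexed [i_w, i_lam]; the best cell attains the grid
    maximum, ties broken toward smaller lambda then smaller w.
    """

    w_values: tuple[float, ...]
    lam_values: tuple[int, ...]
    accuracy: np.ndarray
    best_w: float
    best_lam: int
    best_acc: float


def parameter_sweep(
    windows: Sequence[SiteWindow | str],
    labels: Sequence[int],
    table: PropertyTable,
    w_values: Sequence[float] = tuple(round(0.1 * i, 1) for i in range(11)),
    lam_values: Sequence[int] = tuple(range(1, 11)),
    C: float = 8.0,
    gamma: float = 8.0,
    k: int = 5,
    seed: int = 0,
    counting_mode: str = "overlapping",
) -> SweepResult:
    """Evaluate k-fold CV accuracy at every (w, lambda) grid point.

    Defaults cover w in [0, 1] step 0.1 and lambda in [1, 10] step 1
    (110 cells).
    """
    if not w_values or not lam_values:
        raise EvaluationError("sweep ranges must be non-empty")
    acc = np.empty((len(w_values), len(lam_values)))
    for j, lam in enumerate(lam_values):
        for i, w in enumerate(w_values):
            config = PseDNCConfig(w=w, lam=int(lam), counting_mode=counting_mode)
            report = kfold_cv(
                windows, labels, config, table, C, gamma, k=k, seed=seed
            )
            acc[i, j] = report.Acc
    # argmax with tie-break: smaller lambda, then smaller w
    best_acc = acc.max()
    best_i, best_j = min(
        (
            (i, j)
            for i in range(len(w_values))
            for j in range(len(lam_values))
            if acc[i, j] == best_acc
        ),
        key=lambda ij: (ij[1], ij[0]),
    )
    return SweepResult(
        tuple(w_values),
        tuple(int(l) for l in lam_values),
        acc,
        float(w_values[best_i]),
        int(lam_values[best_j]),
        float(best_acc),
    )
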