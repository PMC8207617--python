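"""Macro-F1 evaluation and testing-time optimization.

The evaluation metric is the macro-averaged F1: per class,
R = TP/(TP+FN), P = TP/(TP+FP), F1 = 2PR/(P+R), then the unweighted
mean over all classes — rare and common classes count equally, which is
exactly why decision thresholds matter under a long tail.  A model
trained at an implicit 0.5 cutoff scores common classes near 1.0 and
rare ones near 0, so the cutoff is re-fit on validation data: first a
single shared threshold on a coarse grid, then a greedy per-class
refinement that scans one class at a time holding the others fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "F1Report",
    "ThresholdVector",
    "default_grid",
    "confusion_counts",
    "f1_macro",
    "apply_thresholds",
    "search_single_threshold",
    "greedy_multi_threshold",
    "ensemble_average",
]

GRID_LO, GRID_HI, GRID_STEP = 0.1, 0.9, 0.05


def default_grid(lo: float = GRID_LO, hi: float = GRID_HI, step: float = GRID_STEP) -> np.ndarray:
    """Threshold grid from ``lo`` to ``hi`` inclusive by ``step``."""
    n = int(round((hi - lo) / step)) + 1
    if n < 1:
        raise ValueError("empty threshold grid")
    return np.round(lo + step * np.arange(n), 10)


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class true-positive / false-positive / false-negative tallies."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if (arr < 0).any():
                raise ValueError("counts must be non-negative")
            object.__setattr__(self, name, arr)
        if not self.tp.shape == self.fp.shape == self.fn.shape:
            raise ValueError("count vectors must share one shape")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class F1Report:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro: float

    @property
    def n_classes(self) -> int:
        return len(self.f1)


@dataclass(frozen=True)
class ThresholdVector:
    """One decision threshold per class; prediction is prob >= threshold."""

    thresholds: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.ndim != 1 or ((t <= 0) | (t >= 1)).any():
            raise ValueError("thresholds must be a vector with values in (0, 1)")
        object.__setattr__(self, "thresholds", t)


def _check_binary_pair(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 2:
        raise ValueError("y_true and y_pred must be (N, C) matrices of equal shape")
    return y_true.astype(bool), y_pred.astype(bool)


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Column-wise TP/FP/FN of binary (N, C) truth and prediction matrices."""
    y_true, y_pred = _check_binary_pair(y_true, y_pred)
    return ConfusionCounts(
        tp=(y_true & y_pred).sum(axis=0),
        fp=(~y_true & y_pred).sum(axis=0),
        fn=(y_true & ~y_pred).sum(axis=0),
    )


def f1_macro(counts: ConfusionCounts) -> F1Report:
    """Per-class precision/recall/F1 and their macro average.

    Degenerate ratios (0/0) follow the zero convention: a class with no
    predicted and/or no true positives where the numerator vanishes
    scores 0, and such classes still enter the macro mean.
    """
    tp, fp, fn = counts.tp.astype(float), counts.fp.astype(float), counts.fn.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    return F1Report(precision=precision, recall=recall, f1=f1, macro=float(f1.mean()))


def apply_thresholds(probs: np.ndarray, thresholds) -> np.ndarray:
    """Binary predictions: positive iff prob >= threshold (closed bound)."""
    probs = np.asarray(probs, dtype=float)
    t = thresholds.thresholds if isinstance(thresholds, ThresholdVector) else np.asarray(thresholds)
    return probs >= t


def _macro_at(probs: np.ndarray, y_true: np.ndarray, thresholds: np.ndarray) -> float:
    return f1_macro(confusion_counts(y_true, probs >= thresholds)).macro


def search_single_threshold(
    probs: np.ndarray,
    y_true: np.ndarray,
    grid_lo: float = GRID_LO,
    grid_hi: float = GRID_HI,
    grid_step: float = GRID_STEP,
) -> tuple[float, float]:
    """Best single threshold shared by all classes on a coarse grid.

    Evaluates macro-F1 at every grid value (default 0.1 to 0.9 step
    0.05) and returns (threshold, score); ties go to the lower
    threshold, which favors recall on rare classes.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    best_t, best_score = None, -1.0
    for t in default_grid(grid_lo, grid_hi, grid_step):
        score = _macro_at(probs, y_true, np.full(probs.shape[1], t))
        if score > best_score:
            best_t, best_score = float(t), score
    return best_t, best_score


def greedy_multi_threshold(
    probs: np.ndarray,
    y_true: np.ndarray,
    init_threshold: float = 0.3,
    grid_lo: float = GRID_LO,
    grid_hi: float = GRID_HI,
    grid_step: float = GRID_STEP,
    n_passes: int = 1,
) -> tuple[ThresholdVector, np.ndarray]:
    """Greedy per-class threshold refinement of a shared initial value.

    Classes are visited in index order; for each, the grid is scanned
    with all other thresholds held fixed and the value is replaced only
    when it strictly improves validation macro-F1 (lowest improving grid
    value on ties), so the score trace is non-decreasing by
    construction.  ``init_threshold`` is typically the single-threshold
    search result.  One pass over the classes by default; ``n_passes``
    allows repeating the sweep.  Classes without a positive validation
    sample keep the initial threshold (no signal to fit).

    Returns the per-class thresholds and the score trace (initial score
    followed by one entry per class visit).
    """
    probs = np.asarray(probs, dtype=float)
    y_true = np.asarray(y_true)
    if not 0.0 < init_threshold < 1.0:
        raise ValueError("init_threshold must lie in (0, 1)")
    n_classes = probs.shape[1]
    thresholds = np.full(n_classes, float(init_threshold))
    support = y_true.sum(axis=0)
    grid = default_grid(grid_lo, grid_hi, grid_step)
    score = _macro_at(probs, y_true, thresholds)
    trace = [score]
    for _ in range(n_passes):
        for c in range(n_classes):
            if support[c] == 0:
                logger.info("class %d has no validation positives; threshold left at init", c)
                trace.append(score)
                continue
            best_t, best_score = thresholds[c], score
            for t in grid:
                candidate = thresholds.copy()
                candidate[c] = t
                s = _macro_at(probs, y_true, candidate)
                if s > best_score:
                    best_t, best_score = float(t), s
            thresholds[c] = best_t
            score = best_score
            trace.append(score)
    return ThresholdVector(thresholds), np.asarray(trace)


def ensemble_average(prob_matrices: list[np.ndarray], ids: list | None = None) -> np.ndarray:
    """Elementwise mean of prediction matrices from several models.

    All matrices must share the same shape and — when ``ids`` are given,
    one id list per matrix — the same sample ordering.
    """
    if not prob_matrices:
        raise ValueError("need at least one prediction matrix")
    mats = [np.asarray(m, dtype=float) for m in prob_matrices]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("prediction matrices must share one shape")
    if ids is not None:
        if len(ids) != len(mats):
            raise ValueError("one id list per prediction matrix required")
        first = list(ids[0])
        if any(list(other) != first for other in ids[1:]):
            raise ValueError("sample orderings (ids) disagree across matrices")
    return np.mean(mats, axis=0)
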