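"""Class-balanced losses for long-tail multi-label data.

The effective number of a class with n positive samples is
``Q_n = (1 - alpha**n) / (1 - alpha)`` where ``alpha = (V - 1)/V`` and V
is the (latent) feature-space volume of the class: each new sample
either overlaps previously seen samples (probability ``Q_{n-1}/V``) or
contributes a genuinely new point.  Weighting each class's loss term by
``1/Q_{n_c}`` instead of ``1/n_c`` discounts the redundancy of the large
classes: at alpha = 0 every class weighs the same, and as alpha -> 1 the
weights approach plain inverse frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pipeline import ClassCountTable

__all__ = [
    "EffectiveNumberModel",
    "ELossWeights",
    "effective_number",
    "eloss_weights",
    "eloss",
    "bce_base_loss",
    "focal_base_loss",
]


def effective_number(n, alpha: float):
    """Effective sample number Q_n = (1 - alpha^n)/(1 - alpha).

    ``n`` may be a scalar or array of integers >= 1; ``alpha`` must lie
    in [0, 1].  The alpha = 1 branch returns n (the V -> infinity limit
    where no two samples overlap).  Q_1 = 1 for every alpha.
    """
    n_arr = np.asarray(n)
    if not np.issubdtype(n_arr.dtype, np.number) or (n_arr < 1).any():
        raise ValueError("n must be >= 1")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if alpha == 1.0:
        q = n_arr.astype(float)
    elif alpha == 0.0:
        q = np.ones_like(n_arr, dtype=float)
    else:
        q = (1.0 - alpha**n_arr.astype(float)) / (1.0 - alpha)
    return q if np.ndim(n) else float(q)


@dataclass(frozen=True)
class EffectiveNumberModel:
    """Effective numbers of a class-count table at a shared alpha.

    ``volume`` is V = 1/(1 - alpha), infinite at alpha = 1.
    """

    alpha: float
    Q: np.ndarray

    @classmethod
    def from_counts(cls, counts: ClassCountTable, alpha: float) -> "EffectiveNumberModel":
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        q = np.array(
            [effective_number(int(n), alpha) if n >= 1 else 0.0 for n in counts.counts]
        )
        return cls(alpha=alpha, Q=q)

    @property
    def volume(self) -> float:
        return np.inf if self.alpha == 1.0 else 1.0 / (1.0 - self.alpha)


@dataclass(frozen=True)
class ELossWeights:
    """Per-class weights 1/Q_{n_c}; zero for classes with no samples."""

    weights: np.ndarray
    counts: ClassCountTable
    alpha: float
    normalized: bool

    @property
    def n_classes(self) -> int:
        return len(self.weights)


def eloss_weights(
    counts: ClassCountTable,
    alpha: float,
    normalize: bool = True,
) -> ELossWeights:
    """Effective-number class weights w_c = (1 - alpha)/(1 - alpha^{n_c}).

    At alpha = 0 all weights are 1 (plain unweighted loss); at alpha = 1
    the weights are inverse class frequency 1/n_c.  Classes with zero
    count get weight 0 and a warning — they carry no signal to weight.

    With ``normalize=True`` (default) the weights are rescaled so they
    sum to the number of classes, keeping the loss magnitude — and hence
    usable learning rates — comparable across alpha values; pass
    ``normalize=False`` for the raw 1/Q_{n_c} weights.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    n_c = counts.counts
    weights = np.zeros(len(n_c), dtype=float)
    present = n_c >= 1
    if (~present).any():
        warnings.warn(
            f"classes {np.flatnonzero(~present).tolist()} have zero samples; "
            "their loss weight is set to 0",
            stacklevel=2,
        )
    if present.any():
        q = effective_number(n_c[present], alpha)
        weights[present] = 1.0 / q
        if normalize:
            weights *= len(n_c) / weights.sum()
    return ELossWeights(weights=weights, counts=counts, alpha=alpha, normalized=normalize)


def eloss(per_class_losses: np.ndarray, weights: ELossWeights) -> float:
    """Weighted sum EL = sum_c w_c * L_c over per-class base-loss terms."""
    losses = np.asarray(per_class_losses, dtype=float)
    if losses.shape != weights.weights.shape:
        raise ValueError(
            f"loss vector of length {losses.shape} does not match "
            f"{weights.weights.shape} classes"
        )
    return float(np.sum(weights.weights * losses))


def _clip_probs(probabilities: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    p = np.asarray(probabilities, dtype=float)
    if ((p < -tol) | (p > 1 + tol)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return np.clip(p, tol, 1 - tol)


def bce_base_loss(probabilities: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Elementwise binary cross-entropy -[y log p + (1-y) log(1-p)]."""
    p = _clip_probs(probabilities)
    y = np.asarray(targets, dtype=float)
    return -(y * np.log(p) + (1 - y) * np.log1p(-p))


def focal_base_loss(
    probabilities: np.ndarray,
    targets: np.ndarray,
    gamma: float = 2.0,
) -> np.ndarray:
    """Focal modulation of BCE: (1 - p_t)^gamma * (-log p_t).

    ``p_t`` is the probability assigned to the true outcome.  gamma = 0
    reduces exactly to BCE; larger gamma down-weights well-classified
    samples, complementing class-level weighting for label imbalance.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    p = _clip_probs(probabilities)
    y = np.asarray(targets, dtype=float)
    p_t = y * p + (1 - y) * (1 - p)
    return (1 - p_t) ** gamma * -np.log(p_t)
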