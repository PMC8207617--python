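"""Training-time optimization: discriminative per-group learning rates,
the exponential learning-rate range test ("LR finder"), and cyclic
cosine-annealed schedules with warm restarts.

Pretrained encoder layers need smaller steps than the freshly
initialized head, so the network is split into two or three layer
groups trained at [lr/3, lr] or [lr/4, lr/2, lr].  The starting lr
itself comes from an exponential sweep from a low value (~1e-5): the
suggested rate is the largest probed one at which the recorded loss is
still decreasing.  During training the lr follows a half-cosine decay
from lr_max to lr_min within each cycle and is reset to lr_max at every
cycle boundary, letting the optimizer escape sharp local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LRSchedule",
    "LayerGrouping",
    "LRFinderResult",
    "discriminative_lrs",
    "lr_find",
    "cosine_cycle_lr",
]


def discriminative_lrs(base_lr: float, n_groups: int) -> list[float]:
    """Per-group learning rates: [lr/3, lr] for 2 groups, [lr/4, lr/2, lr]
    for 3; earlier (encoder) groups get the smaller rates."""
    if base_lr <= 0:
        raise ValueError("base_lr must be positive")
    if n_groups == 2:
        return [base_lr / 3, base_lr]
    if n_groups == 3:
        return [base_lr / 4, base_lr / 2, base_lr]
    raise ValueError("n_groups must be 2 or 3")


@dataclass(frozen=True)
class LayerGrouping:
    """Assignment of every trainable parameter to one layer group.

    Encoder groups precede head groups (group index increases toward the
    output), so group i trains at ``discriminative_lrs(lr, n_groups)[i]``.
    """

    group_of_parameter: dict[str, int]
    n_groups: int

    def __post_init__(self) -> None:
        if self.n_groups not in (2, 3):
            raise ValueError("n_groups must be 2 or 3")
        groups = set(self.group_of_parameter.values())
        if not groups <= set(range(self.n_groups)):
            raise ValueError("group indices must lie in [0, n_groups)")


@dataclass(frozen=True)
class LRSchedule:
    """Cyclic cosine-annealing schedule shared by all layer groups.

    ``lr_max`` holds one peak rate per group; every group follows the
    same cosine phase scaled to its own peak.  ``cycle_length`` is in
    steps (the trainer converts epochs to steps).
    """

    lr_max: tuple[float, ...]
    cycle_length: int
    n_cycles: int = 1
    lr_min: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lr_max", tuple(float(v) for v in np.atleast_1d(self.lr_max)))
        if any(v <= 0 for v in self.lr_max):
            raise ValueError("lr_max values must be positive")
        if self.cycle_length < 1 or self.n_cycles < 1:
            raise ValueError("cycle_length and n_cycles must be positive")
        if self.lr_min < 0 or any(self.lr_min >= v for v in self.lr_max):
            raise ValueError("lr_min must be non-negative and below every lr_max")

    @property
    def total_steps(self) -> int:
        return self.cycle_length * self.n_cycles


def cosine_cycle_lr(step: int, schedule: LRSchedule) -> np.ndarray:
    """Per-group learning rates at ``step`` of a cyclic cosine schedule.

    Within each cycle ``lr(t) = lr_min + (lr_max - lr_min) *
    (1 + cos(pi * t / cycle_length)) / 2`` with ``t = step mod
    cycle_length``; the rate restarts at lr_max at every cycle boundary.
    """
    if not 0 <= step < schedule.total_steps:
        raise ValueError(
            f"step {step} outside [0, {schedule.total_steps}) of the schedule"
        )
    t = step % schedule.cycle_length
    phase = (1 + np.cos(np.pi * t / schedule.cycle_length)) / 2
    lr_max = np.asarray(schedule.lr_max)
    return schedule.lr_min + (lr_max - schedule.lr_min) * phase


@dataclass
class LRFinderResult:
    suggestion: float
    lrs: np.ndarray
    losses: np.ndarray
    smoothed: np.ndarray


def lr_find(
    loss_probe,
    lr_start: float = 1e-5,
    multiplier: float = 1.15,
    max_steps: int = 100,
    smoothing: float = 0.0,
    divergence_factor: float = 4.0,
) -> LRFinderResult:
    """Exponential learning-rate sweep.

    ``loss_probe(lr)`` is called at ``lr_start * multiplier**k`` for
    k = 0, 1, ... and the (optionally EMA-smoothed, bias-corrected)
    losses are recorded; the sweep stops after ``max_steps`` probes or
    once the smoothed loss exceeds ``divergence_factor`` times its
    running minimum.  The suggestion is the largest probed lr at which
    the smoothed loss was still decreasing (last negative finite
    difference).  ``smoothing`` defaults to 0 (raw losses): the probe is
    expected to return an already-representative loss per rate; raise it
    toward ~0.9 for noisy single-batch probes.
    """
    if lr_start <= 0:
        raise ValueError("lr_start must be positive")
    if multiplier <= 1:
        raise ValueError("multiplier must exceed 1")
    if not 0.0 <= smoothing < 1.0:
        raise ValueError("smoothing must lie in [0, 1)")
    lrs: list[float] = []
    losses: list[float] = []
    smoothed: list[float] = []
    ema = 0.0
    running_min = np.inf
    for k in range(max_steps):
        lr = lr_start * multiplier**k
        loss = float(loss_probe(lr))
        lrs.append(lr)
        losses.append(loss)
        if not np.isfinite(loss):
            break
        ema = smoothing * ema + (1 - smoothing) * loss
        sm = ema / (1 - smoothing ** (len(smoothed) + 1)) if smoothing else loss
        smoothed.append(sm)
        running_min = min(running_min, sm)
        # "4x the running minimum" for positive losses; the |min| form
        # keeps the stop meaningful when losses go non-positive
        if sm - running_min > (divergence_factor - 1) * abs(running_min):
            break
    if not smoothed:
        raise RuntimeError("loss probe never returned a finite loss")
    sm_arr = np.asarray(smoothed)
    decreasing = np.flatnonzero(np.diff(sm_arr) < 0)
    idx = int(decreasing[-1] + 1) if decreasing.size else 0
    return LRFinderResult(
        suggestion=lrs[idx],
        lrs=np.asarray(lrs),
        losses=np.asarray(losses),
        smoothed=sm_arr,
    )
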