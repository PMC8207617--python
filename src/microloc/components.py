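"""Architectural building blocks for imbalance-aware microscopy classifiers.

Four deltas applied on top of any convolutional encoder that emits a
C x H' x W' feature map:

* a four-channel input adapter that extends pretrained 3-channel (RGB)
  first-layer kernels with a fourth (yellow/reticulum) channel;
* the adaptive concatenate pooling (ACP) operation — global average and
  global max pooling concatenated channel-wise, giving a 2C feature
  vector for any spatial size;
* a "buffering" classifier head: one or two intermediate fully
  connected layers with decreasing widths (each followed by dropout)
  that slow down feature-information loss before the final class layer;
* a batch hard sampler that keeps only the K largest per-sample losses,
  so easy majority-class samples contribute nothing to the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "ACPConfig",
    "HeadSpec",
    "BatchLossRecord",
    "adapt_input_layer",
    "acp_pool",
    "build_head",
    "head_parameter_count",
    "hard_sample_select",
    "default_hard_k",
]

INIT_STRATEGIES = ("zero", "mean_rgb", "copy_red")


@dataclass(frozen=True)
class ACPConfig:
    """ACP pooling target: output spatial size is fixed at 1x1, so the
    flattened feature length is 2 * in_channels."""

    in_channels: int
    out_height: int = 1
    out_width: int = 1

    def __post_init__(self) -> None:
        if self.in_channels < 1:
            raise ValueError("in_channels must be positive")
        if (self.out_height, self.out_width) != (1, 1):
            raise ValueError("adaptive pooling target is fixed at 1x1")

    @property
    def out_features(self) -> int:
        return 2 * self.in_channels * self.out_height * self.out_width


@dataclass(frozen=True)
class HeadSpec:
    """Classifier-head layout: pooled features -> buffering layers -> classes.

    ``buffering_sizes`` must be strictly decreasing (each buffering layer
    narrows the representation); an empty list gives a single linear map.
    """

    in_features: int
    buffering_sizes: tuple[int, ...] = ()
    dropout_rates: tuple[float, ...] = ()
    n_classes: int = 28

    def __post_init__(self) -> None:
        object.__setattr__(self, "buffering_sizes", tuple(self.buffering_sizes))
        object.__setattr__(self, "dropout_rates", tuple(self.dropout_rates))
        if self.in_features < 1 or self.n_classes < 1:
            raise ValueError("in_features and n_classes must be positive")
        if len(self.buffering_sizes) != len(self.dropout_rates):
            raise ValueError("one dropout rate per buffering layer required")
        sizes = (self.in_features,) + self.buffering_sizes
        if any(later >= earlier for earlier, later in zip(sizes, sizes[1:])):
            raise ValueError("buffering sizes must be strictly decreasing")
        if any(not 0.0 <= r < 1.0 for r in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.in_features,) + self.buffering_sizes + (self.n_classes,)


@dataclass
class BatchLossRecord:
    """Per-sample losses of one batch of size B plus the mining size K."""

    losses: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.losses = np.asarray(self.losses, dtype=float)
        if self.losses.ndim != 1 or len(self.losses) == 0:
            raise ValueError("losses must be a non-empty vector")
        if (self.losses < 0).any():
            raise ValueError("per-sample losses must be non-negative")
        if not 1 <= self.k <= len(self.losses):
            raise ValueError("K must satisfy 1 <= K <= batch size B")

    @property
    def batch_size(self) -> int:
        return len(self.losses)


def adapt_input_layer(
    first_layer_weights_3ch: np.ndarray, init_strategy: str = "mean_rgb"
) -> np.ndarray:
    """Extend 3-channel first-layer convolution kernels to 4 channels.

    The RGB kernels are copied unchanged; the fourth (yellow) channel is
    initialized per ``init_strategy``: ``zero`` (exactly preserves the
    3-channel forward pass on RGB inputs), ``mean_rgb`` (average of the
    three pretrained kernels — the default, a sensible prior for a stain
    correlated with the others) or ``copy_red`` (clone of the red kernel).
    """
    w = np.asarray(first_layer_weights_3ch, dtype=float)
    if w.ndim != 4 or w.shape[1] != 3:
        raise ValueError("expected weights of shape (out_channels, 3, kh, kw)")
    if init_strategy not in INIT_STRATEGIES:
        raise ValueError(f"init_strategy must be one of {INIT_STRATEGIES}")
    if init_strategy == "zero":
        fourth = np.zeros_like(w[:, :1])
    elif init_strategy == "mean_rgb":
        fourth = w.mean(axis=1, keepdims=True)
    else:  # copy_red
        fourth = w[:, :1].copy()
    return np.concatenate([w, fourth], axis=1)


def acp_pool(feature_map: np.ndarray) -> np.ndarray:
    """Adaptive concatenate pooling of a C x H' x W' feature map.

    Returns a vector of length 2C: the first C entries are the
    per-channel spatial means (global average pooling), the last C the
    per-channel spatial maxima (global max pooling).  Accepts a batched
    (B, C, H', W') input, returning (B, 2C).  The output length does not
    depend on the spatial size.
    """
    x = np.asarray(feature_map, dtype=float)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if x.ndim != 4:
        raise ValueError("expected (C, H, W) or (B, C, H, W) feature map")
    if x.shape[2] < 1 or x.shape[3] < 1:
        raise ValueError("spatial dimensions must be non-empty")
    flat = x.reshape(x.shape[0], x.shape[1], -1)
    out = np.concatenate([flat.mean(axis=2), flat.max(axis=2)], axis=1)
    return out[0] if squeeze else out


def build_head(spec: HeadSpec, rng: np.random.Generator | None = None) -> nn.Sequential:
    """Build the buffering-layer classifier head as a layer stack.

    Layout: in_features -> buffering_sizes[0] -> ... -> n_classes, each
    buffering layer followed by ReLU and its dropout; with no buffering
    sizes the head is a single linear map.  The returned stack outputs
    raw class scores (logits).
    """
    rng = rng or np.random.default_rng(0)
    layers: list[nn.Layer] = []
    prev = spec.in_features
    for size, rate in zip(spec.buffering_sizes, spec.dropout_rates):
        layers.append(nn.Linear(prev, size, rng=rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(rate, rng=rng))
        prev = size
    layers.append(nn.Linear(prev, spec.n_classes, rng=rng))
    return nn.Sequential(*layers)


def head_parameter_count(spec: HeadSpec) -> int:
    """Total trainable parameters of the head ((fan_in + 1) * fan_out per
    linear layer; activation/dropout layers have none)."""
    sizes = spec.layer_sizes
    return int(sum((a + 1) * b for a, b in zip(sizes[:-1], sizes[1:])))


def default_hard_k(batch_size: int) -> int:
    """Default mining size K = ceil(B / 2)."""
    return int(np.ceil(batch_size / 2))


def hard_sample_select(record: BatchLossRecord) -> np.ndarray:
    """Indices of the K largest per-sample losses of a batch.

    The selected subset maximizes the summed loss over all K-subsets;
    ties are broken toward the lower index so the selection is
    deterministic.  Averaging the loss over this subset only means the
    easy (majority-class) samples contribute nothing to the gradient.
    Indices are returned sorted ascending.
    """
    order = np.argsort(-record.losses, kind="stable")
    return np.sort(order[: record.k])
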