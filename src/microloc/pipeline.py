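"""Dataset preparation: near-duplicate removal by perceptual hashing,
minority oversampling, multi-label stratified k-fold splitting, and the
resize + random-crop input policy for high-resolution microscopy images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .synthetic import MultiLabelSample

__all__ = [
    "ClassCountTable",
    "FoldAssignment",
    "DedupRecord",
    "compute_image_hash",
    "hamming_distance",
    "deduplicate",
    "class_counts",
    "oversample_minority",
    "stratified_multilabel_split",
    "resize_and_crop",
]

HASH_SIZE = 8  # average-hash grid; 64 bits per channel
DEFAULT_DEDUP_THRESHOLD = 16  # 4 bits per channel over 4 channels


@dataclass(frozen=True)
class ClassCountTable:
    """Per-class positive-sample counts n_c (multi-label: columns of the
    label matrix, so the sum over classes can exceed the sample count)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or (counts < 0).any():
            raise ValueError("counts must be a 1-D vector of non-negative integers")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "ClassCountTable":
        return cls(np.asarray(labels).sum(axis=0).astype(np.int64))

    @property
    def n_classes(self) -> int:
        return len(self.counts)


def class_counts(labels: np.ndarray) -> ClassCountTable:
    """Column sums of an (N, C) binary label matrix."""
    return ClassCountTable.from_labels(labels)


@dataclass(frozen=True)
class FoldAssignment:
    fold_of_sample: np.ndarray
    n_folds: int

    def __post_init__(self) -> None:
        folds = np.asarray(self.fold_of_sample, dtype=np.int64)
        object.__setattr__(self, "fold_of_sample", folds)
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if folds.size and (folds.min() < 0 or folds.max() >= self.n_folds):
            raise ValueError("fold indices out of range")

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample == fold)

    @property
    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold_of_sample, minlength=self.n_folds)


@dataclass(frozen=True)
class DedupRecord:
    removed_id: str
    kept_id: str
    hamming: int


def compute_image_hash(image: np.ndarray) -> np.ndarray:
    """Average-hash fingerprint: boolean vector, 64 bits per channel.

    A single-channel (H, W) image is reduced to an 8x8 grid of mean
    intensities; each bit records whether a cell exceeds the grid mean.
    Multi-channel (C, H, W) images are hashed per channel and the bits
    concatenated.  Deterministic; robust to small intensity perturbations.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot hash an empty image")
    if image.ndim == 2:
        image = image[None]
    if image.ndim != 3:
        raise ValueError("expected (H, W) or (C, H, W) image")
    bits = []
    for chan in image:
        small = resize(chan, (HASH_SIZE, HASH_SIZE), anti_aliasing=True)
        bits.append((small > small.mean()).ravel())
    return np.concatenate(bits)


def hamming_distance(a: np.ndarray, b: np.ndarray) -> int:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprints must have identical length")
    return int(np.count_nonzero(a ^ b))


def deduplicate(
    samples: list[MultiLabelSample],
    hamming_threshold: int = DEFAULT_DEDUP_THRESHOLD,
) -> tuple[list[MultiLabelSample], list[DedupRecord]]:
    """Greedy near-duplicate removal by fingerprint proximity.

    Samples are scanned in id order; one is dropped when its fingerprint
    lies within ``hamming_threshold`` bits of any already-kept sample.
    Returns the kept samples (original list order) and a removal report.
    """
    if hamming_threshold < 0:
        raise ValueError("hamming_threshold must be non-negative")
    order = sorted(range(len(samples)), key=lambda i: samples[i].id)
    kept_idx: list[int] = []
    kept_fps: list[np.ndarray] = []
    removed: list[DedupRecord] = []
    for i in order:
        fp = compute_image_hash(samples[i].channels)
        duplicate_of = None
        if kept_fps:
            dists = np.count_nonzero(np.stack(kept_fps) ^ fp, axis=1)
            j = int(np.argmin(dists))
            if dists[j] <= hamming_threshold:
                duplicate_of = (kept_idx[j], int(dists[j]))
        if duplicate_of is None:
            kept_idx.append(i)
            kept_fps.append(fp)
        else:
            removed.append(
                DedupRecord(
                    removed_id=samples[i].id,
                    kept_id=samples[duplicate_of[0]].id,
                    hamming=duplicate_of[1],
                )
            )
    kept_idx.sort()
    return [samples[i] for i in kept_idx], removed


def oversample_minority(
    counts: ClassCountTable,
    labels: np.ndarray,
    target_ratio: float = 4.0,
) -> np.ndarray:
    """Index multiset replicating rare-class samples a bounded number of times.

    A sample's replication factor is ``floor(min(target_ratio,
    median_count / rarest_count))`` when the count of its rarest label is
    below the median class count, else 1.  Oversampling is deliberately
    capped ("a few times") because unbounded replication of rare samples
    overfits.  Every original index appears at least once.
    """
    if target_ratio < 1:
        raise ValueError("target_ratio must be >= 1")
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[1] != counts.n_classes:
        raise ValueError("labels must be (N, n_classes)")
    nonzero = counts.counts[counts.counts > 0]
    median = float(np.median(nonzero)) if nonzero.size else 0.0
    out: list[int] = []
    safe_counts = np.where(counts.counts > 0, counts.counts, np.iinfo(np.int64).max)
    for i in range(labels.shape[0]):
        on = np.flatnonzero(labels[i])
        rarest = float(safe_counts[on].min()) if on.size else median
        reps = 1
        if rarest < median:
            reps = int(np.floor(min(target_ratio, median / rarest)))
            reps = max(1, reps)
        out.extend([i] * reps)
    return np.asarray(out, dtype=np.int64)


def stratified_multilabel_split(
    labels: np.ndarray,
    n_folds: int,
    seed: int = 0,
) -> FoldAssignment:
    """Iterative multi-label stratification into ``n_folds`` folds.

    Rarest-class-first greedy assignment: repeatedly take the class with
    the fewest unassigned positives, and place each of its unassigned
    samples into the fold that most wants that class (largest remaining
    per-fold desire), breaking ties by remaining fold capacity and then
    at random.  Fold sizes are capped at ceil(N / n_folds), so the
    partition is balanced to within one sample.  Deterministic for a
    fixed seed.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("labels must be (N, C)")
    n, c = labels.shape
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    counts = labels.sum(axis=0)
    scarce = np.flatnonzero((counts > 0) & (counts < n_folds))
    if scarce.size:
        warnings.warn(
            f"classes {scarce.tolist()} have fewer positives than folds; "
            "their per-fold balance cannot be exact",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    desire = np.tile(counts / n_folds, (n_folds, 1))  # (folds, classes)
    capacity = np.full(n_folds, n // n_folds, dtype=np.int64)
    capacity[: n % n_folds] += 1
    assignment = np.full(n, -1, dtype=np.int64)
    remaining_pos = counts.astype(np.int64).copy()

    unassigned = set(range(n))
    members: list[list[int]] = [list(np.flatnonzero(labels[:, k])) for k in range(c)]
    while unassigned:
        with_pos = np.flatnonzero(remaining_pos > 0)
        if with_pos.size == 0:
            # only label-less rows remain (cannot happen for valid data)
            for i in sorted(unassigned):
                f = int(np.argmax(capacity))
                assignment[i] = f
                capacity[f] -= 1
            break
        k = int(with_pos[np.argmin(remaining_pos[with_pos])])
        todo = [i for i in members[k] if assignment[i] == -1]
        rng.shuffle(todo)
        for i in todo:
            open_folds = np.flatnonzero(capacity > 0)
            d = desire[open_folds, k]
            best = open_folds[d == d.max()]
            if best.size > 1:
                cap = capacity[best]
                best = best[cap == cap.max()]
            f = int(best[0]) if best.size == 1 else int(rng.choice(best))
            assignment[i] = f
            capacity[f] -= 1
            on = np.flatnonzero(labels[i])
            desire[f, on] -= 1
            remaining_pos[on] -= 1
            unassigned.discard(i)
    assignment = _repair_stratification(labels, assignment, n_folds, rng)
    return FoldAssignment(fold_of_sample=assignment, n_folds=n_folds)


def _repair_stratification(
    labels: np.ndarray,
    assignment: np.ndarray,
    n_folds: int,
    rng: np.random.Generator,
    max_swaps: int = 2000,
) -> np.ndarray:
    """Swap-based local repair of per-class fold balance.

    The greedy pass can leave the classes assigned last (the most
    frequent ones) more than one sample away from proportionality.
    This pass swaps pairs of samples between folds — which preserves
    fold sizes — whenever the swap strictly reduces the total excess
    deviation ``sum_c sum_f max(0, |count_fc - n_c/k| - 1)``.
    """
    labels = labels.astype(bool)
    n, c = labels.shape
    counts = labels.sum(axis=0)
    target = counts / n_folds
    fold_counts = np.zeros((n_folds, c))
    for f in range(n_folds):
        fold_counts[f] = labels[assignment == f].sum(axis=0)

    def excess(fc: np.ndarray) -> float:
        return float(np.maximum(np.abs(fc - target) - 1.0, 0.0).sum())

    current = excess(fold_counts)
    for _ in range(max_swaps):
        if current <= 0:
            break
        dev = fold_counts - target
        worst_flat = int(np.argmax(np.maximum(np.abs(dev) - 1.0, 0.0)))
        fo, k = divmod(worst_flat, c)
        if abs(dev[fo, k]) <= 1.0:
            break
        over = dev[fo, k] > 0
        fu = int(np.argmin(dev[:, k])) if over else int(np.argmax(dev[:, k]))
        src, dst = (fo, fu) if over else (fu, fo)
        # move a sample with label k from src to dst, swapping with a
        # sample in dst lacking label k; pick the pair that helps most
        donors = np.flatnonzero((assignment == src) & labels[:, k])
        takers = np.flatnonzero((assignment == dst) & ~labels[:, k])
        if donors.size == 0 or takers.size == 0:
            break
        if donors.size > 20:
            donors = rng.choice(donors, size=20, replace=False)
        if takers.size > 20:
            takers = rng.choice(takers, size=20, replace=False)
        best = None
        for i in donors:
            for j in takers:
                delta = labels[i].astype(float) - labels[j].astype(float)
                fc = fold_counts.copy()
                fc[src] -= delta
                fc[dst] += delta
                e = excess(fc)
                if best is None or e < best[0]:
                    best = (e, int(i), int(j), fc)
        if best is None or best[0] >= current:
            break
        current, i, j, fold_counts = best
        assignment[i], assignment[j] = dst, src
    return assignment


def resize_and_crop(
    channels: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Resize a full-resolution sample and cut one random training patch.

    Inputs with original side <= 2048 are resized to 768x768 and a
    512x512 patch is cropped; larger inputs are resized to 1024x1024 and
    a 768x768 patch is cropped.  Crop offsets are drawn uniformly, and
    every channel of the sample receives the identical geometric
    transform so the stains stay pixel-aligned.
    """
    channels = np.asarray(channels, dtype=float)
    squeeze = channels.ndim == 2
    if squeeze:
        channels = channels[None]
    if channels.ndim != 3:
        raise ValueError("expected (H, W) or (C, H, W)")
    if channels.shape[1] != channels.shape[2]:
        raise ValueError("input images must be square")
    side = channels.shape[1]
    resized_side, crop = (768, 512) if side <= 2048 else (1024, 768)
    oy = int(rng.integers(0, resized_side - crop + 1))
    ox = int(rng.integers(0, resized_side - crop + 1))
    out = np.empty((channels.shape[0], crop, crop))
    for k, chan in enumerate(channels):
        big = resize(chan, (resized_side, resized_side), anti_aliasing=True)
        out[k] = big[oy : oy + crop, ox : ox + crop]
    return out[0] if squeeze else out
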