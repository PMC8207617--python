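"""Dataset preparation: dedup, oversampling, stratified folds.

Generates a synthetic dataset with injected exact duplicates, removes
them by perceptual hashing, builds a capped minority-oversampling index
multiset and a 5-fold multi-label stratified split, and prints what
each step did.
"""

import warnings

import numpy as np

from microloc import (
    SyntheticSpec,
    class_counts,
    deduplicate,
    generate_dataset,
    inject_duplicates,
    oversample_minority,
    stratified_multilabel_split,
)

dataset = generate_dataset(SyntheticSpec(n_samples=200, n_classes=8, image_size=48, seed=5))
augmented, dup_map = inject_duplicates(dataset, duplicate_fraction=0.15, perturbation_amplitude=0.0, seed=6)
print(f"injected {len(dup_map)} duplicates -> {len(augmented)} samples")

kept, removed = deduplicate(augmented.samples)
print(f"dedup kept {len(kept)}, removed {len(removed)} (expected ~{len(dup_map)})")

labels = dataset.label_matrix
counts = class_counts(labels)
print("class counts:", counts.counts.tolist())
index_multiset = oversample_minority(counts, labels, target_ratio=4)
reps = np.bincount(index_multiset, minlength=len(labels))
print(
    f"oversampling: {len(labels)} samples -> {len(index_multiset)} draws; "
    f"max replication {reps.max()}x for rare-class samples"
)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # some tail classes have < 5 positives
    folds = stratified_multilabel_split(labels, n_folds=5, seed=1)
print("fold sizes:", folds.fold_sizes.tolist())
for c in [0, 4]:
    per_fold = [int(labels[folds.fold_of_sample == f, c].sum()) for f in range(5)]
    print(f"class {c} positives per fold: {per_fold} (total {counts.counts[c]})")
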