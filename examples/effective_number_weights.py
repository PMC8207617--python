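"""Effective-number class weights across the alpha range.

For a toy long-tail count table, prints the per-class loss weights
1/Q_{n_c} at several alpha values.  At alpha = 0 all classes weigh the
same; as alpha -> 1 the weights approach inverse frequency 1/n_c.  In
between, the effective number Q_n = (1 - alpha^n)/(1 - alpha) discounts
the redundancy among the many similar samples of large classes without
letting a handful of rare samples dominate the loss outright.
"""

import numpy as np

from microloc import ClassCountTable, eloss_weights

counts = ClassCountTable(np.array([2000, 500, 50, 5]))
print("class counts:", counts.counts.tolist())
for alpha in [0.0, 0.9, 0.99, 0.999, 1.0]:
    w = eloss_weights(counts, alpha, normalize=False)
    print(f"alpha={alpha:<6} raw weights 1/Q_n:", np.round(w.weights, 5).tolist())

w = eloss_weights(counts, 0.99, normalize=True)
print("alpha=0.99 normalized (sum = n_classes):", np.round(w.weights, 4).tolist())
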