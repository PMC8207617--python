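"""LR finder and cyclic cosine schedule with discriminative group rates.

First sweeps an exponential range test over a synthetic loss landscape
(loss falls until lr ~0.05, then diverges) to pick the starting rate,
then prints a few points of a two-group cosine cycle schedule built on
it: the encoder group runs at one third of the head group's rate, and
both restart at their maxima at every cycle boundary.
"""

import numpy as np

from microloc import LRSchedule, cosine_cycle_lr, discriminative_lrs, lr_find

result = lr_find(
    lambda lr: 1.0 - lr if lr <= 0.05 else 0.95 + 20 * (lr - 0.05),
    lr_start=1e-5,
    multiplier=1.2,
)
print(f"lr finder probed {len(result.lrs)} rates; suggestion {result.suggestion:.4f}")

lrs = discriminative_lrs(result.suggestion, n_groups=2)
print(f"layer-group rates [encoder, head]: {[round(v, 5) for v in lrs]}")

schedule = LRSchedule(lr_max=tuple(lrs), cycle_length=100, n_cycles=2)
for step in [0, 25, 50, 99, 100, 150]:
    enc, head = cosine_cycle_lr(step, schedule)
    print(f"step {step:>3}: encoder lr {enc:.5f}  head lr {head:.5f}")
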