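# microloc

Imbalance-aware multi-label classification tooling for four-channel
fluorescence microscopy.

Subcellular protein-localization datasets such as the Human Protein
Atlas challenge set pair each sample — four grayscale stains: red
(microtubules), green (protein of interest), blue (nucleus), yellow
(endoplasmic reticulum) — with one or more of 28 localization classes
whose frequencies follow an extreme long tail. The evaluation metric,
macro-F1

    R = TP/(TP+FN),  P = TP/(TP+FP),  F1 = 2PR/(P+R),  macro = Σᵢ F1ᵢ/N,

weights a 30-sample class exactly as much as a 20,000-sample one, so
naive training collapses onto the majority classes. `microloc`
implements, as a tested library, the machinery that counters this:

* **E-loss** — class weights 1/Q_{n_c} from the effective sample number
  Q_n = (1−αⁿ)/(1−α), interpolating between uniform (α=0) and inverse
  frequency (α→1); composable with BCE or focal base losses
  (`microloc.losses`).
* **Hard-example mining** — keep only the K largest per-sample losses
  of each batch so easy majority samples contribute no gradient
  (`microloc.components`).
* **Architecture deltas** — four-channel adapters for pretrained RGB
  input layers, adaptive concatenate pooling (global average ‖ global
  max, C → 2C for any spatial size), and "buffering" classifier heads
  with decreasing intermediate widths (`microloc.components`).
* **Training-time optimization** — discriminative layer-group rates
  ([lr/3, lr] or [lr/4, lr/2, lr]), an exponential LR range test, and
  cyclic cosine annealing with warm restarts (`microloc.schedule`).
* **Testing-time optimization** — single-grid (0.1–0.9, step 0.05) and
  greedy per-class decision-threshold search on validation macro-F1,
  plus prediction ensembling (`microloc.evaluation`).
* **Dataset plumbing** — perceptual-hash near-duplicate removal, capped
  minority oversampling, multi-label stratified k-fold splitting, the
  768/1024 resize + random-crop policy (`microloc.pipeline`), and a
  synthetic long-tail RGBY generator that makes all of the above
  testable without downloading microscopy data (`microloc.synthetic`).

A small NumPy neural-network layer library with hand-written backprop
(`microloc.nn`) and an end-to-end experiment driver
(`microloc.experiment`) let the whole recipe run on a CPU at desk
scale. See `docs/methods.md` for the models and design choices.

## Worked example

Threshold search on an imbalanced validation set (from
`examples/threshold_search.py`): class 0's positives score above 0.55
but the rare class 1's only above 0.25, so no shared cutoff suits both.

```
fixed 0.5 threshold:      macro-F1 0.7000
best single threshold:    0.25 -> macro-F1 0.8836
greedy per-class:         [0.5, 0.25] -> macro-F1 1.0000
score trace: [0.8836, 1.0, 1.0]
```

The fixed cutoff misses the rare class entirely (its F1 term is 0.4 of
the macro deficit); the single-grid search compromises at 0.25; the
greedy pass gives each class its own optimum and recovers a perfect
score on this toy. Effective-number weights for a long-tail count
table (from `examples/effective_number_weights.py`):

```
class counts: [2000, 500, 50, 5]
alpha=0.0    raw weights 1/Q_n: [1.0, 1.0, 1.0, 1.0]
alpha=0.99   raw weights 1/Q_n: [0.01, 0.01007, 0.02532, 0.20404]
alpha=1.0    raw weights 1/Q_n: [0.0005, 0.002, 0.02, 0.2]
```

At α = 0.99 the two big classes weigh almost the same (their extra
samples are largely redundant) while the 5-sample class weighs ~20×
more — a softer correction than raw inverse frequency, which would put
a 400× gap between the extremes.

Each script in `examples/` is a short narrative of one capability:
dataset generation, preparation (dedup/oversample/split), LR
scheduling, threshold search, and a single end-to-end CNN training run
(`examples/train_small_cnn.py`, a minute or two of CPU). The `microloc`
console command wraps the same operations for shell use
(`microloc generate|dedup|split|thresholds|experiment`).

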