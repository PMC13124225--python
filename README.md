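# socialvit

Frame-level classification of rodent social behaviors with a hierarchical
global-context vision transformer, plus the complete surrounding pipeline:
annotation ingestion, leakage-free video splits, class-balanced training,
evaluation reports, and a synthetic two-agent scene generator that makes the
whole workflow runnable without downloading any video data.

## The problem

Quantifying social behavior of laboratory rats traditionally requires
experts to label video frame by frame.  The RatSI dataset (nine 15-minute
top-down recordings of two rats in a 90 × 90 cm observation cage) provides
such frame-level labels; five behaviors are retained here — *Approaching*,
*Following*, *Moving Away*, *Social Nose Contact*, and *Solitary* — because
the remaining five are severely under-represented.  The task is single-frame
five-way classification under heavy class imbalance (Solitary accounts for
roughly two-thirds of all frames).

## The model

The classifier is a four-stage hierarchical vision transformer.  A
convolutional stem (two 3×3, stride-2, same-padded convolutions) embeds a
224×224 image into a 56×56 token grid of width C.  Each stage applies
`depths[s]` units, every unit consisting of four residual sub-blocks in
order:

1. **Local MSA** — multi-head self-attention inside non-overlapping w×w
   windows with learned relative position bias (short-range structure);
2. **DSC-MSFN** — a mixed-scale feedforward network: 1×1 expansion to
   `ratio·C` channels, split into parallel depthwise 3×3 and 5×5 branches,
   GELU, 1×1 projection back to C (multi-scale spatial mixing);
3. **Global MSA** — attention whose *queries* are w² stage-level global
   tokens, produced by progressively downsampling the stage input through
   fused inverted-residual (depthwise conv → squeeze–excitation → 1×1)
   blocks; keys/values come from each window, so every window receives the
   same image-level context;
4. **MLP** — a plain two-layer feedforward.

Between stages, a downsampling block halves the grid and doubles the
channels (56→28→14→7 for the published geometry with windows [7, 7, 14, 7]).
A global-average-pooled head with dropout 0.2 produces the five logits.
Stochastic depth is linearly spaced from 0 to `drop_path_rate` over all
residual sub-blocks; the small/base variants add layer-scale (init 1e-5).

Training follows the published recipe: SGD at lr 0.001, batch 8, up to 50
epochs, weighted cross-entropy with inverse-frequency class weights

    w_g = N_total / (K · N_g),

and plateau learning-rate decay (factor 0.1, patience 20, min-delta 1e-4)
monitoring validation loss.  Three model presets (`tiny`/`small`/`base`)
mirror the published hyperparameter table; a `micro` preset (64×64, dim 16,
depths [1,1,1,1]) supports desk-scale experiments.

The network runs on a small reverse-mode automatic-differentiation engine
written on numpy (`socialvit.nn`): batched matmul, same-padded and depthwise
convolutions, softmax/layer-norm/GELU, pooling and embedding lookup, each
with hand-derived backward passes verified against finite differences.

## Worked example

Split accounting and class weights from the bundled nine-video statistics:

```bash
socialvit summarize
```

```
                  Approaching  Following  Moving Away  Social Nose Contact  Solitary
1                        1405       2150          985                 1799     12281
...
Train (80%)              9904      12382         5673                12854     72474
Validation (20%)         2476       3096         1418                 3213     18119
Test                     2838       3399         1811                 3688     29073
Total                   15218      18877         8902                19755    119666
```

The totals row is the exact column sum (15,218 Approaching frames; 119,666
Solitary); the test row sums videos 4 and 5 (2,838 Approaching), and the
validation row allocates 20% of the train-video frames per behavior (2,476
Approaching).  Inverse-frequency weights from the published training counts:

```python
from socialvit.data import compute_class_weights
from socialvit.data.manifest import RATSI_PUBLISHED_TRAIN_COUNTS

w = compute_class_weights(list(RATSI_PUBLISHED_TRAIN_COUNTS.values()))
for name, value in w.as_dict().items():
    print(f"{name:<22s} {value:.4f}")
```

```
Approaching            2.2877
Following              1.8298
Moving Away            3.9945
Social Nose Contact    1.7628
Solitary               0.3126
```

Minority behaviors (Moving Away, weight ≈ 4.0) are up-weighted; the
dominant Solitary class is down-weighted to ≈ 0.31.  A full desk-scale
training run on synthetic scenes:

```bash
socialvit train --config examples/micro_synthetic.yaml
# trained 5 epochs (max epochs); run dir runs/micro_demo
```

which writes `history.csv` (per-epoch train/validation loss and accuracy and
the learning rate), a split report, best/last checkpoints and a structured
run log.  `socialvit evaluate` then produces the confusion matrix (counts and
row percentages), per-class precision/recall/F1, accuracy and one-vs-rest
AUCs; `socialvit predict` prints per-frame softmax confidences
(`Following Prob: 88.89%` style).

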