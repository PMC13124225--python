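# Methods

## Model

The classifier is a hierarchical vision transformer in the global-context
family: windowed local self-attention for short-range structure, and a
global-query attention in which one set of stage-level query tokens attends
into every window, injecting image-level context at linear cost in the
number of windows.  The feedforward block after local attention is a
mixed-scale depthwise-separable convolution network (DSC-MSFN) rather than a
plain MLP, so that spatial relations between neighboring tokens are mixed at
two kernel scales (3×3 and 5×5) inside the feedforward path.

Composition choices that the architecture description leaves open were
resolved as follows and are fixed throughout:

- **Unit composition.** Each depth unit applies four residual sub-blocks in
  sequence — local MSA, DSC-MSFN, global MSA, MLP — rather than alternating
  single-attention blocks.  Depth counts therefore count full units.
- **Stem widths.** Two 3×3 stride-2 same-padded convolutions: in_channels →
  dim, then dim → dim, followed by layer norm.
- **Relative position bias** is included in local attention (one learned
  table of (2w−1)² offsets per head).  It is a standard component of
  windowed attention; the description is silent, so it defaults on.
- **Global query generator.** For a stage of side S = w·2^k: k repetitions
  of [fused inverted-residual block → 2×2 max pool], then one final fused
  block, flattened to w² tokens.  The fused block is depthwise 3×3 → GELU →
  squeeze–excitation (reduction 4) → 1×1 projection → residual, expansion
  ratio 1.
- **DSC-MSFN.** 1×1 expansion to ratio·C, equal split into depthwise 3×3 and
  5×5 branches, GELU on the expansion and on each branch, concatenation, 1×1
  projection, residual.  The same `mlp_ratio` drives both the DSC-MSFN
  expansion and the MLP hidden width.
- **Downsampling.** Layer norm → fused inverted-residual block → 3×3
  stride-2 convolution to double the channels.
- **Stochastic depth** is linearly spaced from 0 to `drop_path_rate` over
  all residual sub-blocks of the network (four per unit).  Dropout (0.2)
  is applied only in the pooled head.
- **Layer scale** (per-channel residual-branch scaling, init 1e-5) is
  enabled for the small/base presets and disabled for tiny.
- **Ablations.** `use_local_msa=False` and `use_global_msa=False` replace
  the respective attention sub-block with identity (disabling global
  attention also removes the query generator); `use_dsc_msfn=False` replaces
  the mixed-scale feedforward with a plain MLP.  The all-off "baseline" is
  therefore the conv stem + per-unit MLP blocks + downsamplers + head; this
  is one reading of an under-specified baseline and is stated as such.
- **Tie-breaking**: argmax ties resolve to the lowest class index; the class
  order is fixed as [Approaching, Following, Moving Away, Social Nose
  Contact, Solitary].

Parameter counts of the published presets as built here are ≈ 55.8 M
(tiny), 101.0 M (small), 179.1 M (base).  The originally printed counts
(10.0/10.1/11.7 M) are internally inconsistent with the printed
hyperparameters (a base width of 128 with depths [3,4,19,5] cannot weigh
the same as a width-64 tiny), so counts are reported but never asserted.

## Numerical backend

The network runs on a purpose-built numpy reverse-mode autodiff engine
(`socialvit.nn`): a define-by-run tape over float32 arrays with batched
matmul, same-padded strided convolution (im2col with a 1×1 fast path),
depthwise convolution (per-tap accumulation), softmax, layer norm, GELU
(exact erf form), sigmoid, 2×2 max pooling (ties split evenly in the
backward pass), embedding lookup with scatter-add, dropout/stochastic depth,
and a fused weighted-cross-entropy-with-logits.  Every backward pass is
tested against central finite differences (relative tolerance 1e-4 in
float64).  Inference runs under a no-grad mode that skips tape
construction.  Eval-mode forwards are bitwise deterministic on a fixed
platform; a single engine-level seed (`nn.manual_seed`) drives parameter
initialization and the dropout/drop-path masks.

## Data pipeline

Annotation files carry one behavior label per frame (0-based frame index i
maps to decoded frame i).  The parser auto-detects delimiter and header,
normalizes spelling variants ("Social nose contact", "Moving away") onto
canonical names, accepts a user label map for unknown dialects, and keeps
non-retained labels in the track flagged for exclusion.  Frames are resized
bilinearly to the model resolution and scaled to [0, 1] by division by 255;
grayscale sources are replicated across channels.  Splits are by video
identity: whole videos go to the train or test pool and validation frames
are a seeded per-behavior sample of round(val_fraction · count) frames from
the train-video pool, so no recording contributes to more than one subset
(checked on every split).  The class-weight formula as printed reduces to a
constant 1/K; it is implemented as the standard inverse-frequency scheme
N_total/(K·N_g), which matches the stated purpose of up-weighting minority
behaviors and the derived example values (0.3126 for Solitary, 3.9945 for
Moving Away).  The published 80% training-row counts are bundled verbatim
(`RATSI_PUBLISHED_TRAIN_COUNTS`) because the original validation sampling
differs by ±1 frame in two behaviors from round-to-nearest accounting.

## Training

Defaults reproduce the published recipe: plain SGD (momentum 0,
configurable; Adam available behind a flag), lr 0.001, batch 8, 50 epochs,
weighted cross-entropy, plateau decay factor 0.1 / patience 20 / min-delta
1e-4.  The description names validation loss as the plateau monitor while
the workflow summary names validation accuracy; validation loss is the
default and the monitor is configurable.  "Plateau scheduling used for
early stopping" is implemented as plateau decay plus an optional early stop
that triggers when a second full stall cycle completes.  An improvement
must exceed min_delta strictly, so a decrease of exactly 5e-5 does not
count.  Runs write a config snapshot, CSV history, best/last checkpoints
(npz with an embedded config and format version) and a structured log with
seed and lr events.

## Synthetic scenes

The generator emulates a top-down view of a square arena with two elongated
agents (ellipses with a brighter front half so heading is visible).  Class
geometry (arena side 1.0, semi-major axis 0.08): Solitary — centroid
distance ≥ 0.5; Social Nose Contact — head-tip distance ≤ 0.02, agents
facing each other; Following — distance ∈ [0.1, 0.3], both headings within
15° of the inter-centroid line, agent 1 behind; Approaching — distance ∈
[0.15, 0.4], agent 1 heading within 15° of the line to agent 2's head,
agent 2 oriented 40–140° off-axis; Moving Away — distance ∈ [0.15, 0.4],
agent 1 heading within 15° of the opposite direction.  Every sample is
validated against a rule-based decision-list classifier, which makes the
rules mutually exclusive by construction and guarantees that geometry
recovers labels with 100% accuracy on noise-free scenes — so learning
failures cannot be blamed on ambiguous data.  Class allocation uses
largest-remainder rounding (exact at the frame level); frames are assigned
round-robin to pseudo-videos so video-ID splitting is exercised; a
RatSI-like imbalance preset mirrors the real class shares
(≈ 8.3/10.3/4.9/10.8/65.6%).

The deliberate departure from real data: behaviors that are temporal in the
real dataset (approach, follow, move away) are encoded as *static*
orientation cues, because the classifier is frame-level by design.
Passing tests on synthetic scenes therefore demonstrate that the
architecture, losses, splits and metrics are implemented correctly and that
the model can learn geometric relations between two agents — they say
nothing about accuracy on real video, where single-frame ambiguity between
nose contact, approaching and following is the dominant error source.

## Evaluation

Confusion matrices use rows = true class, columns = predicted; a
row-normalized view backs the percentage reports.  Precision, recall and F1
(harmonic mean) are computed per class with zero denominators defined as 0
and logged; overall precision/recall/F1 are emitted both macro- and
support-weighted since the published aggregation is unstated.  ROC curves
are one-vs-rest on softmax scores (scikit-learn threshold sweep) with
trapezoidal AUC, which the tests verify against the Mann–Whitney rank
statistic (ties counted one half) to 1e-9.  Confidence reports format the
top softmax probability as a percentage with two decimals.

## Problem sizes and seeds

Desk-scale sizes were chosen so the full suite and the acceptance script
each run in minutes on one CPU: gradient checks on ≤ (2,4,4,3) tensors;
attention/conv oracles on a few hundred elements; the learning smoke run
trains the micro preset (64×64, dim 16, depths [1,1,1,1]) on 100 noise-free
frames (20 per class, batch 8, lr 0.01, cap 300 epochs, stopping at ≥ 95%
training accuracy — typically ~50–60 epochs); the weighting comparison
trains two micro models for 30 epochs on 140 frames at 10:1 imbalance and
evaluates minority recall on 50 independent uniform frames (at 30 epochs
the weighted/unweighted contrast is strongest; by 50 epochs both runs drift
toward the majority class on out-of-sample scenes).  All randomness is
seeded; the acceptance script derives every component seed from its single
`--seed` argument.

## Known limitations

- No temporal modeling: frames are classified independently.
- The numpy backend is single-threaded BLAS-bound; full-resolution training
  of the published presets is out of reach (inference-only forwards are
  exercised), matching the intended desk scale.
- Real video decoding requires an imageio plugin with ffmpeg support;
  image-directory pseudo-videos are the tested ingestion path.
- The synthetic scenes contain no occlusion, no photorealistic texture and
  exactly two agents.
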