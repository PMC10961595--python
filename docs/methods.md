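# Methods

This note records what the package computes, the assumptions behind it,
the defaults and why, and what the synthetic benchmark does and does not
establish.

## Problem setting

A *complex activity* is a pattern of two or more *concept* instances
(task-relevant simple activities) whose order and frequency matter: the
same three concepts performed in a different order can be a different —
possibly safety-critical — class. Supervision is weak: each training
window `x ∈ R^{S×T}` carries its class `y` and the ordered concept
sequence `c` (variable length k ≪ T), but no per-concept start/end
times. The model must therefore (i) learn concept detection and alignment
jointly from order-only labels, (ii) classify from concepts alone so the
prediction is explainable in concept space, and (iii) explain by
construction, not post hoc.

## Model

Stages and shapes (defaults in parentheses; all configurable through
`ModelConfig`):

- Per-sensor 1-D conv (64 filters, kernel 16, stride 2, ReLU, "same"
  padding), one stem per channel so channels are exchangeable with their
  stems; outputs concatenated to `S×64` maps.
- Cross-sensor 1-D conv (128 filters, kernel 16, stride 2, ReLU). Two
  stride-2 stages give `T′ = ⌈⌈T/2⌉/2⌉`; the smallest admissible input is
  `min_input_length` (31 with defaults), reported in the error when an
  input is too short.
- Bi-directional LSTM (128 units per direction). The backward pass
  reverses each sequence within its own valid length, so right-padding
  never leaks into a sample's representation.
- Time-distributed dense to **M+1** outputs with softmax. The extra
  column is the CTC blank ϵ: alignment training is impossible without it,
  so the bottleneck is M concepts + ϵ and the classifier sees all M+1
  channels.
- Classifier: one causal temporal convolution (64 filters, kernel 8,
  stride 1, **dilation 4**), ReLU, masked global average pooling over the
  valid `T′` steps, dense softmax over L classes.

Joint loss `L = β·L_Y + (1−β)·L_C`, β = 0.5 by default (equal weight to
classification and concept alignment); `L_Y` is categorical
cross-entropy, `L_C` the CTC negative log-likelihood. The logged history
satisfies `L = β·L_Y + (1−β)·L_C` at every epoch to 1e-6.

**Why dilation 4.** CTC is free to place a concept's probability mass
anywhere inside its true extent and in practice concentrates it in brief
spikes separated by long blank stretches. With dilation 1 a kernel-8
convolution over the bottleneck almost never spans two adjacent concept
emissions, so pooled features degrade to a bag of concepts and classes
that differ only in concept *order* (e.g. a compliant cleaning routine
versus the same actions in an unsanitary order) become indistinguishable
— we observed exactly this failure. Dilation 4 widens the receptive
field to 29 bottleneck steps (~116 input samples), enough to cover
adjacent emissions at the benchmark's geometry, and matches the
dilated-causal character of temporal convolutional classifiers.

## Training

- Adam, learning rate 1e-3, batch size 32, gradient-norm clipping at 5
  (guards occasional LSTM spikes early in training).
- Per-channel z-score normalization fitted on the training split and
  stored with the model; padded tails are exactly zero after
  normalization and are masked out of the CTC loss and the pooling.
- Variable-length batching: right-pad to the batch maximum; the CTC
  recursion freezes each sample's forward variables beyond its own `T′`.
- CTC feasibility (shortest alignment = k plus one blank per adjacent
  repeat must fit in `T′`) is checked per window before training and
  reported with the window index.
- Checkpointing: best epoch by validation macro-F1, restored on return;
  early stopping after `patience` (10) epochs without improvement. The
  per-epoch edit-distance log decodes a fixed 64-window monitoring
  subsample (decoding dominates monitoring cost); final evaluation always
  decodes everything.
- Everything is seeded (parameter init, batch order, generator), so runs
  are bit-reproducible on a given platform.

The CTC loss is computed by the standard blank-augmented forward
recursion in log space (guarded −1e30 instead of −∞ keeps log-sum-exp
gradients finite) and differentiated by the package's reverse-mode tape;
it is validated against exhaustive alignment enumeration to 1e-8, and its
gradient against finite differences. No deep-learning framework is used:
`cbhar.autodiff` is a small vectorized numpy tape providing exactly the
operators the model needs, each gradient-checked.

## Decoding and explanations

- **Prefix beam search** (default width 25) merges alignments whose
  collapsed prefixes coincide — that merging is the marginalization over
  alignments — and returns sequences ranked by marginal probability.
  Ties break toward higher probability, then shorter sequences, then
  lexicographic concept order, for determinism. With exhaustive width the
  decoder provably equals full enumeration; all reported concept outputs
  use beam decoding.
- **Concept store**: every training window is decoded once and recorded
  with the model's *predicted* class — not the annotation — so
  counterfactuals are faithful to the model's own decision boundary.
- **Counterfactual**: the store entry with minimum Damerau–Levenshtein
  distance to the decoded test sequence among entries of a different
  class. The restricted (optimal-string-alignment) variant is used:
  single-concept insertions, deletions, substitutions, and adjacent
  transpositions, no substring edited twice; validated against an
  exhaustive edit-script recursion. Distance-0 cross-class collisions are
  excluded (identical explanation, different class would break
  explanation-prediction consistency) and logged as a warning; ties break
  toward the most frequent stored sequence, then lexicographic order.
  When no different-class entry exists the result is an explicit
  "no counterfactual available", not an error.
- Concept *evaluation* deliberately uses the plain Levenshtein distance
  (no transposition) so the reported edit distance is not flattered by
  the counterfactual metric's cheaper swaps.
- "Concept accuracy" is the exact-sequence-match rate; other readings
  (per-segment, set-based) exist, and this choice is the strictest.

## Synthetic benchmark

The generator emulates how complex-activity corpora are commonly
assembled: per-concept signal segments concatenated in a class-specific
order, exporting only sequence-level labels. Concretely:

- Canonical grammar: 5 nursing-procedure classes over 6 concepts with 16
  admissible sequences (e.g. *Unsafe IV/Drips Procedure* includes drips →
  blood collection → vitals); sequences are unique across classes, so the
  sequence label determines the class.
- Concept prototypes: per-channel sinusoids with concept-specific base
  frequency (spread over 0.05–0.33 cycles/sample), per-channel amplitude
  and phase variation, standing in for accelerometer motifs; additive
  Gaussian channel noise (sd 0.25 against unit-order amplitudes).
- Durations: default 120–240 samples per concept (30–60 s at the
  4 Hz-equivalent default geometry), uniform draw per instance.
- Filler: between consecutive concepts, with probability 0.5, 0–40
  samples of low-amplitude (sd 0.15) zero-mean noise — unlabeled motion
  the blank token must absorb.
- The generator keeps a hidden segment log (half-open, 0-based sample
  intervals) for diagnostics; the serialized dataset never contains it
  (a test enforces that the manifest carries no timing fields).

What it does *not* emulate: real accelerometer statistics, inter-subject
variation, concurrent/overlapping concepts, and natural transitions
between movements (the filler model is a stand-in). Passing tests
therefore demonstrate the correctness of the machinery and the
recoverability of order-sensitive structure under the stated noise model
— not field performance on real wearable data.

## Experiment scale

All training experiments in the test suite and the acceptance script run
at a desk scale chosen once: concept durations 30–60 samples (the same
30–60 s segments at a 1 Hz-equivalent sampling), 120 training and 40
validation windows per class, 16 epochs (6 for the loss-weight
ablations). One such training takes ~3 minutes on one CPU. Grammar,
class balance, noise, filler and β are never scaled. The recovery
experiment trains up to three model seeds and requires two to reach
macro-F1 ≥ 0.9, exact-match concept accuracy ≥ 0.8 and mean edit
distance ≤ 0.5; explanation protocols run on the best-converged of those
runs, since they characterize a converged recognizer.

## Faithfulness protocol

Three probes on a held-out set, explanation = decoded concept sequence
(the counterfactual is a deterministic function of it and the predicted
class):

- **P1 consistency**: group windows by explanation; the fraction of
  groups whose members share one prediction. A converged recognizer is
  expected to reach exactly 1.0 — any group at two predictions means two
  inputs with the same explanation and different outputs.
- **P2 stability**: add per-channel Gaussian noise with sd = 5% of the
  channel's within-window sd; among windows whose prediction is
  unchanged, the fraction whose explanation is unchanged (≥ 0.9
  expected; 1.0 trivially at zero noise).
- **P3 sensitivity**: split each window into 4 contiguous segments and
  permute them (non-identity); report the fractions with changed
  prediction and changed explanation. Scrambling reliably changes
  explanations (the decoded order breaks) but often not the prediction —
  a scrambled window still pools to similar concept content — so the
  "majority changed" expectation is evaluated on the union of the two
  changes, with the explanation change alone also required to be a
  majority. Both fractions are reported separately.

## Bottleneck sufficiency

To confirm the classifier-sees-only-concepts composition loses no class
information, an *ideal* concept matrix is built from the generator's
hidden segment log (bottleneck step t one-hot on the concept covering
input sample 4t + 2, blank elsewhere) and a classifier head with the
model's own architecture is fit on the training split's ideal matrices;
its held-out macro-F1 must match or beat the end-to-end model's. The
complementary transfer probe — the *trained* classifier evaluated
directly on ideal matrices — is also reported: it runs ~0.08 F1 lower,
a train/test mismatch in alignment style (the trained classifier has
only ever seen CTC's spiky emissions, the ideal matrix is full-duration
runs), not an information deficit; the fitted-head probe isolates the
information question from that calibration artifact.

## Known limitations

- Sequential concepts only: no concurrency or overlap, matching the
  strictly sequential grammar.
- The counterfactual can only ever be a sequence the model produced on
  training data; rare classes with few stored sequences give coarser
  counterfactuals, and the store grows linearly with the training set.
- No per-concept importance scores; the explanation is the sequence, its
  spans, and the counterfactual.
- Numpy-only training is practical at the benchmark's scale but not for
  long windows (minutes of high-rate data) or large corpora.
- Hyperparameters are fixed defaults, not searched; β, learning rate,
  epochs and architecture widths are exposed in `ModelConfig`.
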