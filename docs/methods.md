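# Methods

This note documents the models, conventions and design choices behind
`distressfuse`, and what the synthetic cohorts do and do not establish.

## Data model

A session bundle is one clinical interview: a transcript of timestamped
utterances (start/stop seconds, speaker, text), a 74-wide audio feature
table at 10 ms frames, a 388-wide video feature table, and a binary
label (1 = depressed, the positive class everywhere). Files are plain
CSV (tab-separated accepted via a dialect flag), times are decimal
seconds — the only unit that spans both the transcript timestamps and
the millisecond-scale frame period. Frame tables with missing cells are
imputed by previous-frame carry-forward (first frame: zeros), logged per
file; the corpus documentation does not prescribe a policy, and
carry-forward is the least-surprising choice for slowly varying
framewise descriptors. Numeric round-trips through the CSV writer are
bit-exact: features are float32 and serialized at 9 significant digits.

## Sentence-level alignment

The modalities share one clock only through the transcript, so the
aligned representation has **one time step per participant utterance**
(interviewer turns are dropped: the participant's speech is the clinical
signal carrier). For an utterance spanning `[start, stop)`:

* the frame slice is rows `[floor(start/period), floor(stop/period))` —
  half-open and 0-based, so adjacent non-overlapping utterances receive
  disjoint slices;
* the audio/video step vector is the per-feature mean of the slice
  (max/std selectable; mean is the default for its robustness to
  framewise noise), zeros when the slice is empty;
* the text step is the mean of the utterance's token embeddings (300-d,
  a deterministically seeded random table by default — any pretrained or
  learned sentence encoder can be substituted by assigning the
  featurizer's embedding table) concatenated with the token count,
  giving 301 features. The 301 width is read as 300-d embedding + 1
  count scalar; nothing finer-grained is implied by the feature schema.

Sequences are zero-padded or truncated (earliest steps kept) to a fixed
length `L`. The reference geometry uses `L = 1700`; every model accepts
any `L` and the desk-scale runs in the test suite use `L` between 6 and
100. A word-level alignment (one step per token, audio/video repeating
the sentence slice — word-level forced alignment is not available in the
schema) feeds the word-level gating variants.

Tokenization is lowercase, punctuation-stripped, whitespace-split. The
idf weight is `ln((1+N)/(1+df)) + 1` over N utterances (the smoothed
form; verified against scikit-learn's TfidfVectorizer in the tests).
TF-IDF vectors plus three lexical statistics (word count, mean sentence
length, type-token ratio) feed the classical classifiers; the sequence
models consume the embedding steps.

## Class balancing

Cohorts carry a 7:3 non-depressed:depressed imbalance. Minority-class
sessions are upsampled (sampling with replacement, seeded) until the
counts match the majority — (130, 59) becomes (130, 130). Balancing is
applied to the *training split only*, after splitting, so duplicated
sessions can never straddle the train/test boundary. Upsampled index
entries get replica ids `<sid>~k` pointing at the same session, keeping
index ids unique.

## The gated fusion network

Geometry (reference build, `NetworkSpec()` defaults):

| stream | layers | widths |
|---|---|---|
| video | 3 gating blocks → dense → dense | 388 → 388 → 200 → 74 |
| audio | 3 gating blocks → dense | 74 → 74 → 74 |
| text | dense → dense | 301 → 150 → 74 |

A gating block computes, per timestep `t`:
`g = σ(x_t·W_G + b_G[t])`, `h = ReLU(x_t·W_T + b_T[t])`,
`out_t = g⊙h + (1−g)⊙x_t`. The transform and gate weight matrices
(`d×d` each) are shared across time but the biases are **per timestep**
(`L×d` each), so a block carries `2·(d² + L·d)` trainable scalars. This
per-timestep-bias structure is what makes the block counts come out at
1,620,288 (d=388) and 262,552 (d=74) at L=1700; a conventional highway
layer with shared biases (`2·(d² + d)`) does not produce those counts.
Gate biases start at −1 so blocks begin near the carry (identity)
behaviour; in the closed-gate limit the block *is* the identity, in the
open-gate limit it is the pure transform path — both limits are tested.

The three 74-wide streams are concatenated **along the time axis** in
the fixed order (audio, video, text) — the fused sequence is 3L×74,
i.e. 5100×74 at reference scale. The order is a config constant
(`concat_order`) since only the fused shape, not the order, is
architecturally determined. An LSTM (128 units; 4-gate recurrence,
`4·u·(in+u+1)` = 103,936 parameters; forget bias 1) reads the fused
sequence; a final affine layer (129 parameters) with a logistic link
yields the probability of depression. Total: 5,907,283 trainable
scalars. `account_for_spec` produces the accounting in closed form;
`count_parameters` measures it from the instantiated layers; the two are
property-tested to agree for random geometries.

**Padding masking.** Padded steps are all-zero rows by contract. The
recurrence skips them: a step whose *input* row is entirely zero carries
the hidden and cell state through unchanged (the mask is derived from
the network inputs before gating, so trained gating biases cannot
re-activate pad rows). Without masking, the forget-gate decay across
hundreds of trailing pad steps erases the signal of short sessions
padded to a long L; with it, sequence length and session length decouple.

**Training.** Adam (step size 10⁻³, moment decays 0.9/0.999 — the
optimizer family is fixed, its hyperparameters are conventional
defaults), binary cross-entropy on the logistic output, minibatches of
8, seeded shuffling; weights use variance-scaled uniform initialization.
Training is deterministic given the seed under single-threaded
execution. A non-finite loss aborts with the epoch, batch index and
learning rate. An optional early stop on training accuracy shortens the
separable-data runs. Calls threshold the probability at 0.5, ties
positive.

All layers are numpy implementations with explicit reverse-mode
gradients (this package's compute core); every layer's analytic
gradients are checked against central finite differences in float64 at
~1e-10 agreement, including the masked LSTM.

## Comparison models and hybrid late fusion

* **Classical first stage** — SVM (RBF, probability outputs) and random
  forest (200 trees) on session-summary vectors: per-feature mean and
  standard deviation over all frames (148-d audio, 776-d video), TF-IDF
  plus lexical statistics for text. Summaries are the standard choice
  for session-level classical baselines.
* **Six-layer CNNs** — per modality: three convolutions (2-D on the
  L×301 text grid treated as a one-channel image; 1-D along time for
  audio/video), each followed by max pooling, then three affine layers;
  ReLU inside, logistic output. Exactly six weight-bearing layers per
  branch. Filter count 8 and kernel 3 are fixed small defaults. Pooling
  windows shrink to the axis length on very short inputs so the stack
  stays valid at desk scale.
* **Recurrent variants** — LSTM or BiLSTM (doubled recurrent parameter
  count) over the fused streams, with gating level `none` (projections
  concatenated without gating blocks), `sentence` (gating blocks on
  sentence-aligned steps) or `word` (gating blocks on word-aligned
  steps).
* **Stacking late fusion** — a second-stage SVM on the concatenation of
  first-stage scores in fixed modality order. Training scores are
  produced **out of fold** by 5-fold stratified cross-fitting, so the
  second stage never sees a score computed on a session its first-stage
  model trained on; fold membership is recorded and asserted. A simple
  unweighted-mean ensemble is available as the alternative combination,
  and stacking inputs may mix raw-modality and fused-model scores.

## Evaluation

Positive class = depressed. Precision, recall, F1 and accuracy from
exact confusion counts; zero-denominator conventions send a metric to 0
(needed because small held-out sets can produce empty prediction
classes). The default split is stratified 80/20 by session with a fixed
seed, recorded in every report; evaluating a model on its own training
sessions sets a warning flag, partial train/test overlap is a hard
error. The permutation null for "no signal" permutes the labels against
the model's own fixed calls — preserving both the class prior and the
model's positive-call rate — and the band for a mean over k runs is
resampled from the pooled permutation draws.

## The synthetic cohort generator

The generator reproduces the corpus *shell*: 189 sessions by default,
depressed fraction 59/189, durations uniform on [420 s, 1980 s]
(7–33 min), audio frames every 10 ms, video at 30 Hz (a video frame rate
is not part of the corpus description; 30 Hz is the common standard and
is a spec field), ~8 utterances/min alternating interviewer/participant
with participant speech covering about half the session. Class signal is
fully parametric:

* audio/video frames are i.i.d. Gaussians with per-feature mean shifts
  added for depressed sessions (`noise_sd` 1.0);
* text signal is the rate at which participant utterances contain a
  token from a small marker lexicon (depressed vs control rates;
  equal rates = no text signal).

The default signal is a moderate multimodal effect (shift 0.5/0.3 on 16
audio/video features, marker rates 0.35 vs 0.05) — the corpus publishes
no effect sizes, so this is a single fixed choice of a learnable but
far-from-separable cohort. Each session draws from a stream seeded
`seed + ordinal`, so cohorts are byte-reproducible and parallelizable.

What the generator does **not** emulate: temporal autocorrelation of
real audio/video descriptors, inter-speaker variability, realistic
language, label noise, or any correlation structure across features.
Passing tests on these cohorts therefore establish that the pipeline's
mechanics are correct (alignment, gating, fusion, stacking, accounting,
splits) and that each model can extract a planted signal of known
location and size — they say nothing about performance on real clinical
interviews, and the published scores on the licensed corpus are
deliberately not asserted anywhere in this package.

## Problem sizes

The reference L=1700 geometry is used for parameter accounting and a
single forward pass (no training needed there). Training runs use desk
scales chosen to finish quickly on one CPU: 30–40 sessions of 0.5–2
minutes, L=12–100, ≤30 epochs (the strong-audio fusion run converges by
epoch 3–5); the full 189-session default cohort is generated in memory
session by session when its shell is measured. Multi-seed behavioural
checks use 5 seeds.

## Known limitations

* The pluggable sentence encoder ships only with the seeded random
  embedding table; no pretrained language-model weights are bundled, so
  text signal reaches the models through marker-token statistics rather
  than semantics.
* Word-level "alignment" repeats the sentence's frame slice per token.
* The numpy compute core is single-threaded and desk-scale by design;
  the full-geometry network is buildable and runnable but training it at
  L=1700 on a large cohort is out of scope.
* `duration_range` may be degenerate (`[d, d]`) for fixed-duration
  cohorts; durations must be positive.
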