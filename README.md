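# distressfuse

Multimodal detection of psychological distress (depression) from clinical
interview sessions, for researchers working with DAIC-WOZ-style corpora:
timestamped transcripts, framewise audio features (74 per 10 ms frame,
including twelve MFCCs) and framewise video features (388 per frame:
facial landmarks, action units, gaze and pose). The licensed corpus itself
is never required — a synthetic-cohort generator reproduces its
statistical shell (189 sessions, 59 depressed / 130 non-depressed, 7–33
minute sessions) with controllable per-modality class signal, so every
stage of the pipeline is testable end to end.

## The model

The three modalities share a time index only through the transcript:
**sentence-level alignment** turns each participant utterance into one
time step, whose audio/video vectors are per-feature means over the
utterance's frame slice and whose text vector is a 300-d mean token
embedding plus a token count (301 features). Sequences are zero-padded or
truncated to a fixed length L (default 1700).

The core classifier is a **gated fusion network**. Audio and video
streams each pass through three stacked gating (highway-style) blocks

&nbsp;&nbsp;&nbsp;&nbsp;g<sub>t</sub> = σ(x<sub>t</sub>W<sub>G</sub> + b<sub>G</sub>[t]),&nbsp;&nbsp;
h<sub>t</sub> = ReLU(x<sub>t</sub>W<sub>T</sub> + b<sub>T</sub>[t]),&nbsp;&nbsp;
out<sub>t</sub> = g<sub>t</sub>⊙h<sub>t</sub> + (1−g<sub>t</sub>)⊙x<sub>t</sub>

with shared d×d transform/gate weights and *per-timestep* L×d biases —
2·(d² + L·d) trainable scalars per block, i.e. 1,620,288 for video
(d=388) and 262,552 for audio (d=74) at L=1700. Dense projections bring
every stream to width 74 (video 388→200→74, text 301→150→74, audio
74→74), the streams are concatenated **along the time axis** into a
3L×74 = 5100×74 fused sequence, and an LSTM (128 units, zero-padding
masked) followed by a logistic output makes the per-session call. The
full geometry totals **5,907,283** trainable parameters; the accounting
is available in closed form without training.

Around it sit the comparison models and the hybrid fusion strategy:
per-modality SVM / random-forest classifiers on session-summary vectors,
six-layer CNNs (Conv2D for the text grid, Conv1D along time for
audio/video), LSTM/BiLSTM variants with sentence- or word-level gating,
and two-stage **stacking late fusion** — a second-stage SVM trained on
out-of-fold first-stage scores. Evaluation reports precision, recall, F1
and accuracy with the depressed class positive. All neural layers
(gating blocks, LSTM/BiLSTM, convolutions, Adam, binary cross-entropy)
are implemented in numpy with analytic gradients, validated against
finite differences in the test suite.

## Worked example

Generate a 40-session cohort whose class signal lives only in the audio
stream, align it at L=100, fit the gated fusion network and score the
held-out split:

```python
from distressfuse import (CohortSpec, SignalModel, iter_cohort, align_cohort,
                          GatedFusionModel, stratified_split, evaluate_model)

spec = CohortSpec(n_sessions=40, depressed_fraction=0.5,
                  duration_range=(60, 120), seed=7)
signal = SignalModel.single_modality("audio", strength=1.5)
bundles = list(iter_cohort(spec, signal))
dataset, featurizer = align_cohort(bundles, L=100)

train_idx, test_idx = stratified_split(dataset.labels, test_fraction=0.2, seed=7)
results = GatedFusionModel(dataset.subset(train_idx)).fit(
    epochs=30, seed=7, early_stop_accuracy=0.99)
print(results.summary())

row = evaluate_model(results, dataset.subset(test_idx),
                     model="gated-fusion", modality="audio+video+text",
                     split="stratified 80/20", seed=7)
print(f"held-out precision={row.precision:.2f} recall={row.recall:.2f} "
      f"f1={row.f1:.2f} accuracy={row.accuracy:.2f}")
```

prints

```
Gated multimodal fusion network
sequence length L=100, fused length 300 x 74
Layer                 Output shape              Params
------------------------------------------------------
audio_gate_1          (100, 74)                 25,752
audio_gate_2          (100, 74)                 25,752
audio_gate_3          (100, 74)                 25,752
audio_proj_1          (100, 74)                  5,550
video_gate_1          (100, 388)               378,688
video_gate_2          (100, 388)               378,688
video_gate_3          (100, 388)               378,688
video_proj_1          (100, 200)                77,800
video_proj_2          (100, 74)                 14,874
text_proj_1           (100, 150)                45,300
text_proj_2           (100, 74)                 11,174
recurrent             (128,)                   103,936
output                (1,)                         129
------------------------------------------------------
Total                                        1,472,083
epochs=30 batch=8 lr=0.001 seed=7
final training loss 0.2276, accuracy 1.000 (8.4s)
held-out precision=1.00 recall=1.00 f1=1.00 accuracy=1.00
```

The per-layer parameter table is the scaled-down (L=100) version of the
reference geometry; at L=1700 the same layers give 1,620,288 / 262,552 /
… / 103,936 / 129 scalars and a 5,907,283 total. A separable
audio-only cohort is fit perfectly within a few epochs — the sanity
ceiling for the harder, partial-signal configurations.

The same pipeline is scriptable from the shell:

```bash
distressfuse simulate --n 40 --depressed-frac 0.5 --signal audio --seed 7 --out cohort/
distressfuse preprocess --cohort cohort/ --l 100 --out tensors.npz
distressfuse train --arch gated-fusion --tensors tensors.npz --epochs 20 --seed 7 --out run/
distressfuse train --arch svm --modality all --cohort cohort/ --seed 7 --out svm_run/
distressfuse fuse --scores svm_run/scores.csv --method stack --out fused.csv
distressfuse report --reports run/eval.csv svm_run/eval.csv
```

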