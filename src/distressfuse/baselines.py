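"""Comparison models and the two-stage hybrid late fusion.

First stage: per-modality classifiers — a maximum-margin classifier (SVM)
or a random forest on session-level summary vectors, or a six-layer
convolutional net / recurrent variants on the aligned sequences.  Each
first-stage model emits a depression score per session; scores used to
train the second stage are produced *out of fold* by 5-fold cross-fitting
so the second stage never sees a score computed on a session that the
first-stage model trained on.

Second stage: a maximum-margin classifier on the concatenated first-stage
scores (fixed modality order) — stacking late fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io_formats import SessionBundle
from .nn import Conv1D, Conv2D, Dense, Flatten, MaxPool1D, MaxPool2D
from .preprocess import (AlignedDataset, TextFeaturizer, lexical_profile,
                         participant_corpus)
from . import fusion as _fusion

MODALITIES = ("text", "audio", "video")


# ---------------------------------------------------------------------------
# session-level summary features for the classical classifiers

@dataclass
class ModalityFeatureVector:
    session_id: str
    modality: str
    vector: np.ndarray


def session_features(bundle: SessionBundle, modality: str,
                     featurizer: TextFeaturizer) -> np.ndarray:
    """Fixed-width summary vector for one session and modality.

    text: tf-idf over the fitted vocabulary of the concatenated participant
    speech, plus the three lexical statistics; audio/video: per-feature
    mean and standard deviation over all frames (148 / 776 dims).
    """
    if modality == "text":
        speech = " ".join(r.text for r in bundle.participant_utterances())
        prof = lexical_profile(bundle.participant_utterances())
        return np.concatenate([
            featurizer.tfidf_vector(speech),
            [prof["word_count"], prof["mean_sentence_length"],
             prof["type_token_ratio"]]])
    table = {"audio": bundle.audio, "video": bundle.video}[modality]
    x = table.features
    return np.concatenate([x.mean(axis=0), x.std(axis=0)])


def feature_matrix(bundles: list[SessionBundle], modality: str,
                   featurizer: TextFeaturizer) -> np.ndarray:
    return np.stack([session_features(b, modality, featurizer) for b in bundles])


# ---------------------------------------------------------------------------
# first-stage classical classifiers

_KINDS = ("max-margin", "random-forest")


def _make_classifier(kind: str, seed: int):
    if kind == "max-margin":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if kind == "random-forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}; expected {_KINDS}")


class ModalityClassifierModel:
    """Classical per-modality classifier bound to its feature matrix."""

    def __init__(self, X: np.ndarray, y: np.ndarray, kind: str = "max-margin"):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        counts = np.bincount(y, minlength=2)
        if counts.min() < 2:
            raise ValueError("need at least 2 sessions per class")
        self.X, self.y, self.kind = np.asarray(X, float), y, kind

    def fit(self, seed: int = 0, n_folds: int = 5) -> "ModalityClassifierResults":
        """Fit on all rows and produce out-of-fold scores by cross-fitting."""
        n_folds = min(n_folds, int(np.bincount(self.y).min()))
        skf = StratifiedKFold(n_splits=max(2, n_folds), shuffle=True,
                              random_state=seed)
        oof = np.full(len(self.y), np.nan)
        fold_of = np.full(len(self.y), -1)
        for k, (tr, te) in enumerate(skf.split(self.X, self.y)):
            clf = _make_classifier(self.kind, seed)
            clf.fit(self.X[tr], self.y[tr])
            oof[te] = clf.predict_proba(self.X[te])[:, 1]
            fold_of[te] = k
        final = _make_classifier(self.kind, seed)
        final.fit(self.X, self.y)
        return ModalityClassifierResults(model=self, classifier=final,
                                         oof_scores=oof, fold_of=fold_of,
                                         seed=seed)


@dataclass
class ModalityClassifierResults:
    model: ModalityClassifierModel
    classifier: object
    oof_scores: np.ndarray  # out-of-fold score per training session
    fold_of: np.ndarray     # which fold each session was held out in
    seed: int

    def predict(self, X: np.ndarray, threshold: float = 0.5):
        probs = self.classifier.predict_proba(np.asarray(X, float))[:, 1]
        return probs, (probs >= threshold).astype(int)

    def summary(self) -> str:
        acc = float((( self.oof_scores >= 0.5).astype(int) == self.model.y).mean())
        return (f"{self.model.kind} classifier, n={len(self.model.y)}, "
                f"out-of-fold accuracy {acc:.3f} "
                f"({self.fold_of.max() + 1} folds, seed {self.seed})")


def train_modality_classifier(X, y, kind="max-margin", seed=0):
    """Functional form: returns the fitted results object."""
    return ModalityClassifierModel(X, y, kind=kind).fit(seed=seed)


# ---------------------------------------------------------------------------
# second-stage stacking fusion

@dataclass
class ScoreRecord:
    session_id: str
    scores: dict[str, float]  # per first-stage model/modality


class StackingFusionModel:
    """Second-stage maximum-margin classifier on first-stage scores.

    The input vector for each session is the concatenation of first-stage
    scores in a fixed column order; training scores must be out-of-fold.
    """

    def __init__(self, scores: np.ndarray, y: np.ndarray,
                 columns: tuple[str, ...] = MODALITIES):
        scores = np.asarray(scores, float)
        if scores.ndim != 2 or scores.shape[1] != len(columns):
            raise ValueError(
                f"score matrix must be (n, {len(columns)}) for columns {columns}")
        if np.isnan(scores).any():
            bad = np.nonzero(np.isnan(scores).any(axis=1))[0]
            raise ValueError(f"missing modality scores for sessions {bad.tolist()}")
        self.scores, self.y, self.columns = scores, np.asarray(y), columns

    def fit(self, seed: int = 0) -> "StackingFusionResults":
        clf = SVC(kernel="rbf", probability=True, random_state=seed)
        clf.fit(self.scores, self.y)
        return StackingFusionResults(model=self, classifier=clf, seed=seed)


@dataclass
class StackingFusionResults:
    model: StackingFusionModel
    classifier: object
    seed: int

    def predict(self, scores: np.ndarray, threshold: float = 0.5):
        scores = np.asarray(scores, float)
        if np.isnan(scores).any():
            bad = np.nonzero(np.isnan(scores).any(axis=1))[0]
            raise ValueError(f"missing modality scores for sessions {bad.tolist()}")
        probs = self.classifier.predict_proba(scores)[:, 1]
        return probs, (probs >= threshold).astype(int)

    def summary(self) -> str:
        return (f"stacking late fusion over columns {self.model.columns}, "
                f"n={len(self.model.y)}, seed {self.seed}")


def late_fuse_stacking(scores, y, columns=MODALITIES, seed=0):
    return StackingFusionModel(scores, y, columns=columns).fit(seed=seed)


def ensemble_scores(score_sets: list[np.ndarray], session_ids=None,
                    method: str = "mean"):
    """Combine member probability vectors: unweighted mean (default).

    ``session_ids``, when given, is a list of id sequences that must agree
    across members.  For ``method='stack'`` use :func:`late_fuse_stacking`
    on the stacked member columns with labels.
    """
    if session_ids is not None:
        first = list(session_ids[0])
        for ids in session_ids[1:]:
            if list(ids) != first:
                raise ValueError("ensemble members have mismatched session ids")
    arrs = [np.asarray(s, float) for s in score_sets]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("ensemble members have mismatched shapes")
    if method != "mean":
        raise ValueError("only method='mean' combines here; use late_fuse_stacking")
    return np.mean(arrs, axis=0)


# ---------------------------------------------------------------------------
# six-layer convolutional nets

class CNNModalityModel:
    """Six-layer convolutional classifier for one modality.

    The text branch treats the L x 301 step matrix as a one-channel 2-D
    grid and applies 2-D convolutions; audio/video branches convolve along
    time (1-D).  Each branch has exactly six weight-bearing layers: three
    convolutions (each followed by max pooling) and three affine layers,
    rectifier activations inside and a logistic output.
    """

    def __init__(self, dataset: AlignedDataset, modality: str,
                 filters: int = 8, kernel: int = 3):
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        self.dataset, self.modality = dataset, modality
        self.filters, self.kernel = filters, kernel
        x = dataset.modality(modality)
        self.input_shape = x.shape[1:]

    def _build(self, seed: int):
        rng = np.random.default_rng(seed)
        f, k = self.filters, self.kernel
        if self.modality == "text":
            self._front = [Conv2D(1, f, (k, k), rng=rng, name="conv2d_1"),
                           MaxPool2D(2),
                           Conv2D(f, f, (k, k), rng=rng, name="conv2d_2"),
                           MaxPool2D(2),
                           Conv2D(f, f, (k, k), rng=rng, name="conv2d_3"),
                           MaxPool2D(2), Flatten()]
        else:
            c = self.input_shape[1]
            self._front = [Conv1D(c, f, k, rng=rng, name="conv1d_1"), MaxPool1D(2),
                           Conv1D(f, f, k, rng=rng, name="conv1d_2"), MaxPool1D(2),
                           Conv1D(f, f, k, rng=rng, name="conv1d_3"), MaxPool1D(2),
                           Flatten()]
        x = self.dataset.modality(self.modality)[:1].astype(np.float32)
        flat = self._forward_front(x).shape[1]
        self._back = [Dense(flat, 32, activation="relu", rng=rng, name="dense_1"),
                      Dense(32, 16, activation="relu", rng=rng, name="dense_2"),
                      Dense(16, 1, activation="linear", rng=rng, name="output")]

    def _forward_front(self, x):
        h = x
        for lay in self._front:
            h = lay.forward(h)
        return h

    def _forward(self, x):
        h = self._forward_front(x)
        if h.ndim > 2:
            h = h.reshape(h.shape[0], -1)
        for lay in self._back:
            h = lay.forward(h)
        return h

    def _backward(self, dlogits):
        d = dlogits
        for lay in reversed(self._back):
            d = lay.backward(d)
        for lay in reversed(self._front):
            d = lay.backward(d)

    def weight_bearing_layers(self) -> list:
        return [lay for lay in self._front + self._back if lay.params]

    def fit(self, epochs: int = 20, batch_size: int = 8,
            learning_rate: float = 1e-3, seed: int = 0,
            early_stop_accuracy: float | None = None) -> "SequenceModelResults":
        self._build(seed)
        assert len(self.weight_bearing_layers()) == 6
        cfg = _fusion.TrainConfig(epochs, batch_size, learning_rate, seed,
                                  early_stop_accuracy)
        x = self.dataset.modality(self.modality).astype(np.float32)
        history = _fusion._train_network(
            self, self.weight_bearing_layers(),
            batch_fn=lambda idx: x[idx], n=len(self.dataset),
            y=self.dataset.labels, cfg=cfg,
            network_forward=self._forward, network_backward=self._backward)
        return SequenceModelResults(model=self, history=history, config=cfg,
                                    description=f"6-layer CNN ({self.modality})")


@dataclass
class SequenceModelResults:
    """Results wrapper shared by the CNN and recurrent variants."""

    model: object
    history: dict
    config: object
    description: str = ""

    def predict(self, dataset: AlignedDataset, threshold: float = 0.5):
        from .nn.layers import sigmoid
        if isinstance(self.model, CNNModalityModel):
            x = dataset.modality(self.model.modality).astype(np.float32)
            probs = np.empty(len(dataset))
            for lo in range(0, len(dataset), 16):
                probs[lo:lo + 16] = sigmoid(
                    self.model._forward(x[lo:lo + 16])).reshape(-1)
        else:
            probs = self.model.network.predict_proba(dataset.arrays())
        return probs, (probs >= threshold).astype(int)

    def summary(self) -> str:
        return (f"{self.description}: final loss {self.history['loss'][-1]:.4f}, "
                f"training accuracy {self.history['accuracy'][-1]:.3f}")


def build_cnn_modality(dataset: AlignedDataset, modality: str,
                       filters: int = 8, kernel: int = 3) -> CNNModalityModel:
    return CNNModalityModel(dataset, modality, filters=filters, kernel=kernel)


# ---------------------------------------------------------------------------
# recurrent variants with optional gating

class SequenceVariantModel:
    """LSTM/BiLSTM fusion variant with configurable gating level.

    ``gating_level='none'`` concatenates the projected streams without
    gating blocks; ``'sentence'`` / ``'word'`` apply the three stacked
    gating blocks to sentence- or word-aligned step sequences (the caller
    supplies a dataset aligned at the matching level).
    """

    def __init__(self, dataset: AlignedDataset, kind: str = "recurrent",
                 gating_level: str = "sentence"):
        if kind not in ("recurrent", "bidirectional"):
            raise ValueError(f"unknown kind {kind!r}")
        if gating_level not in ("none", "sentence", "word"):
            raise ValueError(f"unknown gating_level {gating_level!r}")
        from dataclasses import replace
        L = dataset.sessions[0].L
        spec = replace(_fusion.NetworkSpec().scaled(L),
                       n_gating_blocks=0 if gating_level == "none" else 3,
                       bidirectional=(kind == "bidirectional"))
        self.inner = _fusion.GatedFusionModel(dataset, spec=spec)
        self.kind, self.gating_level = kind, gating_level

    def fit(self, **kwargs) -> "SequenceModelResults":
        res = self.inner.fit(**kwargs)
        desc = (f"{'BiLSTM' if self.kind == 'bidirectional' else 'LSTM'} "
                f"(gating: {self.gating_level})")
        return SequenceModelResults(model=res, history=res.history,
                                    config=res.config, description=desc)


def train_sequence_variant(dataset: AlignedDataset, kind="recurrent",
                           gating_level="sentence", **fit_kwargs):
    return SequenceVariantModel(dataset, kind=kind,
                                gating_level=gating_level).fit(**fit_kwargs)
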