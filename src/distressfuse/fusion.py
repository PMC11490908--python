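"""The gated multimodal fusion network.

Architecture (for sequence length L, audio 74-d, video 388-d, text 301-d):

* video stream: three stacked gating blocks at width 388, then dense
  projections 388 -> 200 -> 74;
* audio stream: three stacked gating blocks at width 74, then dense 74 -> 74;
* text stream: dense projections 301 -> 150 -> 74 (no gating — the gating
  mechanism filters the audio/visual channels before fusion);
* the three streams, now all L x 74, are concatenated **along the time
  axis** (order audio, video, text) into a 3L x 74 fused sequence;
* an LSTM with 128 units consumes the fused sequence; a final affine layer
  with a logistic link yields the per-session probability of depression.

Each gating block carries shared d x d transform/gate weights plus
per-timestep L x d biases, giving ``2*(d^2 + L*d)`` trainable scalars —
1,620,288 at (d=388, L=1700) and 262,552 at (d=74, L=1700).  At the full
input geometry the network totals 5,907,283 trainable scalars; the
accounting is available without instantiating any weights.

Training uses Adam with binary cross-entropy, the exposed surface is a
statsmodels-style pair: :class:`GatedFusionModel` built from an aligned
dataset, whose :meth:`~GatedFusionModel.fit` returns
:class:`GatedFusionResults` carrying the trained network, its history,
parameter account and a ``summary()`` table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .nn import (LSTM, Adam, BiLSTM, HighwayGating, TimeDense, Dense,
                 binary_cross_entropy)
from .preprocess import AlignedDataset

FUSION_WIDTH = 74
MODALITIES = ("audio", "video", "text")


@dataclass(frozen=True)
class GatingBlockSpec:
    """Geometry of one gating block: feature width d, sequence length L."""

    d: int
    L: int
    transform_activation: str = "relu"
    gate_activation: str = "sigmoid"

    def __post_init__(self):
        if self.d < 1 or self.L < 1:
            raise ValueError("gating block needs d >= 1 and L >= 1")

    @property
    def param_count(self) -> int:
        """Closed form: shared d x d gate+transform weights, L x d biases each."""
        return 2 * (self.d ** 2 + self.L * self.d)


def build_gating_block(spec: GatingBlockSpec, rng=None,
                       name: str = "highway") -> HighwayGating:
    if spec.gate_activation != "sigmoid" or spec.transform_activation != "relu":
        raise ValueError("gating blocks use a logistic gate and rectifier transform")
    return HighwayGating(spec.d, spec.L, rng=rng, name=name)


@dataclass(frozen=True)
class NetworkSpec:
    """Geometry of the full fusion network (defaults are the reference build)."""

    L: int = 1700
    audio_d: int = 74
    video_d: int = 388
    text_d: int = 301
    video_proj: tuple[int, ...] = (200, 74)
    text_proj: tuple[int, ...] = (150, 74)
    audio_proj: tuple[int, ...] = (74,)
    n_gating_blocks: int = 3  # per audio/video stream
    recurrent_units: int = 128
    bidirectional: bool = False
    concat_order: tuple[str, ...] = ("audio", "video", "text")

    def __post_init__(self):
        widths = {self.video_proj[-1], self.text_proj[-1], self.audio_proj[-1]}
        if widths != {FUSION_WIDTH} and len(widths) != 1:
            raise ValueError(
                f"all projection targets must share one fusion width, got {widths}")
        if set(self.concat_order) != set(MODALITIES):
            raise ValueError(f"concat_order must permute {MODALITIES}")

    @property
    def fusion_width(self) -> int:
        return self.audio_proj[-1]

    @property
    def fused_length(self) -> int:
        """Length of the time-axis concatenation of the three streams."""
        return 3 * self.L

    def scaled(self, L: int) -> "NetworkSpec":
        """Same architecture at a different sequence length (desk scale)."""
        return replace(self, L=L)


@dataclass
class ParameterAccount:
    """Per-layer trainable-scalar counts and their total."""

    layers: list[tuple[str, tuple, int]]  # (name, output shape, count)

    @property
    def total(self) -> int:
        return sum(c for _, _, c in self.layers)

    def by_name(self) -> dict[str, int]:
        return {name: c for name, _, c in self.layers}

    def to_table(self) -> str:
        rows = [f"{'Layer':<22}{'Output shape':<20}{'Params':>12}",
                "-" * 54]
        rows += [f"{name:<22}{str(shape):<20}{count:>12,}"
                 for name, shape, count in self.layers]
        rows += ["-" * 54, f"{'Total':<42}{self.total:>12,}"]
        return "\n".join(rows)


def account_for_spec(spec: NetworkSpec) -> ParameterAccount:
    """Closed-form parameter accounting; no weights are allocated."""
    L, fw = spec.L, spec.fusion_width
    layers: list[tuple[str, tuple, int]] = []
    for mod in ("audio", "video"):
        d = getattr(spec, f"{mod}_d")
        block = GatingBlockSpec(d=d, L=L)
        for k in range(spec.n_gating_blocks):
            layers.append((f"{mod}_gate_{k + 1}", (L, d), block.param_count))
    for mod in MODALITIES:
        d_in = getattr(spec, f"{mod}_d")
        for j, d_out in enumerate(getattr(spec, f"{mod}_proj"), start=1):
            layers.append((f"{mod}_proj_{j}", (L, d_out), d_out * (d_in + 1)))
            d_in = d_out
    u = spec.recurrent_units
    rec_count = 4 * u * (fw + u + 1)
    head_in = u
    if spec.bidirectional:
        rec_count *= 2
        head_in = 2 * u
    layers.append(("recurrent", (u if not spec.bidirectional else 2 * u,),
                   rec_count))
    layers.append(("output", (1,), head_in + 1))
    return ParameterAccount(layers=layers)


class FusionNetwork:
    """Instantiated weights + forward/backward for a :class:`NetworkSpec`."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        L = spec.L
        self.streams: dict[str, list] = {m: [] for m in MODALITIES}
        for mod in ("audio", "video"):
            d = getattr(spec, f"{mod}_d")
            for k in range(spec.n_gating_blocks):
                self.streams[mod].append(
                    build_gating_block(GatingBlockSpec(d=d, L=L), rng=rng,
                                       name=f"{mod}_gate_{k + 1}"))
        for mod in MODALITIES:
            d_in = getattr(spec, f"{mod}_d")
            for j, d_out in enumerate(getattr(spec, f"{mod}_proj"), start=1):
                self.streams[mod].append(
                    TimeDense(d_in, d_out, activation="relu", rng=rng,
                              name=f"{mod}_proj_{j}"))
                d_in = d_out
        rec_cls = BiLSTM if spec.bidirectional else LSTM
        self.recurrent = rec_cls(spec.fusion_width, spec.recurrent_units,
                                 rng=rng, name="recurrent")
        head_in = spec.recurrent_units * (2 if spec.bidirectional else 1)
        self.head = Dense(head_in, 1, activation="linear", rng=rng, name="output")

    def layers(self) -> list:
        return ([lay for m in MODALITIES for lay in self.streams[m]]
                + [self.recurrent, self.head])

    def parameter_account(self) -> ParameterAccount:
        """Account measured from the instantiated layers (not the closed forms)."""
        spec = self.spec
        entries = []
        for mod in MODALITIES:
            for lay in self.streams[mod]:
                shape = (spec.L, getattr(lay, "d", getattr(lay, "d_out", 0)))
                entries.append((lay.name, shape, lay.param_count()))
        entries.append((self.recurrent.name,
                        (self.head.d_in,), self.recurrent.param_count()))
        entries.append((self.head.name, (1,), self.head.param_count()))
        return ParameterAccount(layers=entries)

    def forward(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        """Batch of per-modality (N, L, d) arrays -> logits (N, 1).

        Zero-padded steps (all-zero rows of the *input*) are masked out of
        the recurrent pass, so padding never dilutes the fused sequence.
        """
        outs, masks = {}, {}
        for mod in MODALITIES:
            x = np.asarray(batch[mod], dtype=np.float32)
            d_expected = getattr(self.spec, f"{mod}_d")
            if x.ndim != 3 or x.shape[1] != self.spec.L or x.shape[2] != d_expected:
                raise ValueError(
                    f"{mod} input shape {x.shape} does not match spec "
                    f"(None, {self.spec.L}, {d_expected})")
            masks[mod] = np.abs(x).sum(axis=2) > 0
            for lay in self.streams[mod]:
                x = lay.forward(x)
            outs[mod] = x
        fused = np.concatenate([outs[m] for m in self.spec.concat_order], axis=1)
        mask = np.concatenate([masks[m] for m in self.spec.concat_order], axis=1)
        self._fused_shape = fused.shape
        h = self.recurrent.forward(fused, mask=mask)
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits)
        dfused = self.recurrent.backward(dh)
        L = self.spec.L
        offsets = {}
        pos = 0
        for m in self.spec.concat_order:
            offsets[m] = (pos, pos + L)
            pos += L
        for mod in MODALITIES:
            lo, hi = offsets[mod]
            dx = dfused[:, lo:hi]
            for lay in reversed(self.streams[mod]):
                dx = lay.backward(dx)

    def predict_proba(self, batch: dict[str, np.ndarray],
                      batch_size: int = 16) -> np.ndarray:
        from .nn.layers import sigmoid
        n = len(next(iter(batch.values())))
        probs = np.empty(n)
        for lo in range(0, n, batch_size):
            sub = {m: batch[m][lo:lo + batch_size] for m in MODALITIES}
            probs[lo:lo + batch_size] = sigmoid(self.forward(sub)).reshape(-1)
        return probs


def count_parameters(network: FusionNetwork) -> ParameterAccount:
    return network.parameter_account()


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    #: stop once training accuracy reaches this value (None = run all epochs)
    early_stop_accuracy: float | None = None


class TrainingDiverged(RuntimeError):
    pass


def _train_network(network, forward_backward_layers, batch_fn, n, y, cfg,
                   network_forward, network_backward):
    """Shared minibatch Adam/BCE loop; returns history dict."""
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(forward_backward_layers, learning_rate=cfg.learning_rate)
    history = {"loss": [], "accuracy": []}
    y = np.asarray(y, dtype=np.float32)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, n_correct = [], 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb, yb = batch_fn(idx), y[idx]
            opt.zero_grads()
            logits = network_forward(xb)
            loss, p, dlogits = binary_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size}"
                    f" (learning_rate={cfg.learning_rate})")
            network_backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            n_correct += int(((p >= 0.5) == (yb == 1)).sum())
        history["loss"].append(sum(losses) / n)
        history["accuracy"].append(n_correct / n)
        if (cfg.early_stop_accuracy is not None
                and history["accuracy"][-1] >= cfg.early_stop_accuracy):
            break
    return history


class GatedFusionModel:
    """Gated fusion network bound to an aligned training dataset.

    Parameters
    ----------
    dataset : AlignedDataset
        Sentence-aligned sessions; their L must match ``spec.L``.
    spec : NetworkSpec, optional
        Architecture geometry; defaults to the reference build scaled to the
        dataset's sequence length.
    """

    def __init__(self, dataset: AlignedDataset, spec: NetworkSpec | None = None):
        if len(dataset) == 0:
            raise ValueError("empty training dataset")
        L = dataset.sessions[0].L
        self.spec = spec if spec is not None else NetworkSpec().scaled(L)
        if self.spec.L != L:
            raise ValueError(f"dataset L={L} does not match spec L={self.spec.L}")
        self.dataset = dataset

    def fit(self, epochs: int = 30, batch_size: int = 8,
            learning_rate: float = 1e-3, seed: int = 0,
            early_stop_accuracy: float | None = None) -> "GatedFusionResults":
        cfg = TrainConfig(epochs, batch_size, learning_rate, seed,
                          early_stop_accuracy)
        network = FusionNetwork(self.spec, seed=seed)
        arrays = self.dataset.arrays()
        y = self.dataset.labels
        t0 = time.monotonic()
        history = _train_network(
            network, network.layers(),
            batch_fn=lambda idx: {m: arrays[m][idx] for m in MODALITIES},
            n=len(self.dataset), y=y, cfg=cfg,
            network_forward=network.forward, network_backward=network.backward)
        return GatedFusionResults(model=self, network=network, history=history,
                                  config=cfg, fit_seconds=time.monotonic() - t0)


@dataclass
class GatedFusionResults:
    """Trained fusion network + history, accounting and prediction."""

    model: GatedFusionModel
    network: FusionNetwork
    history: dict
    config: TrainConfig
    fit_seconds: float = 0.0

    @property
    def parameter_account(self) -> ParameterAccount:
        return self.network.parameter_account()

    def predict(self, dataset: AlignedDataset, threshold: float = 0.5):
        """Per-session probability and binary call (ties -> positive)."""
        probs = self.network.predict_proba(dataset.arrays())
        return probs, (probs >= threshold).astype(int)

    def summary(self) -> str:
        acct = self.parameter_account
        lines = ["Gated multimodal fusion network",
                 f"sequence length L={self.model.spec.L}, "
                 f"fused length {self.model.spec.fused_length} x "
                 f"{self.model.spec.fusion_width}",
                 acct.to_table(),
                 f"epochs={self.config.epochs} batch={self.config.batch_size} "
                 f"lr={self.config.learning_rate} seed={self.config.seed}",
                 f"final training loss {self.history['loss'][-1]:.4f}, "
                 f"accuracy {self.history['accuracy'][-1]:.3f} "
                 f"({self.fit_seconds:.1f}s)"]
        return "\n".join(lines)


def build_fusion_network(spec: NetworkSpec, seed: int = 0) -> FusionNetwork:
    """Functional alias for constructing the instantiated network."""
    return FusionNetwork(spec, seed=seed)
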