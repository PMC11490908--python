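"""Metrics, reports, splits and the permutation-null reference band.

The positive class is *depressed* throughout.  Degenerate denominators
follow the explicit convention precision/recall/F1 -> 0, needed because
small held-out sets can produce empty prediction classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split as _sk_split

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(calls, labels) -> ConfusionCounts:
    """Exact confusion counts; positive class = depressed (label 1)."""
    calls = np.asarray(calls).astype(int)
    labels = np.asarray(labels).astype(int)
    if calls.shape != labels.shape:
        raise ValueError(f"calls {calls.shape} vs labels {labels.shape} mismatch")
    return ConfusionCounts(
        tp=int(((calls == 1) & (labels == 1)).sum()),
        fp=int(((calls == 1) & (labels == 0)).sum()),
        fn=int(((calls == 0) & (labels == 1)).sum()),
        tn=int(((calls == 0) & (labels == 0)).sum()))


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(precision, recall, f1, accuracy) with zero-denominator -> 0."""
    if c.total < 1:
        raise ValueError("empty confusion table")
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    accuracy = (c.tp + c.tn) / c.total
    return precision, recall, f1, accuracy


@dataclass
class EvalRow:
    model: str
    modality: str
    precision: float
    recall: float
    f1: float
    accuracy: float
    split: str
    seed: int
    warning: str = ""


@dataclass
class EvalReport:
    rows: list[EvalRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def stratified_split(labels, test_fraction: float = 0.2, seed: int = 0):
    """Stratified session-level split; returns (train_idx, test_idx)."""
    idx = np.arange(len(labels))
    tr, te = _sk_split(idx, test_size=test_fraction, stratify=np.asarray(labels),
                       random_state=seed)
    return np.sort(tr), np.sort(te)


def evaluate_calls(calls, labels, model: str = "", modality: str = "",
                   split: str = "", seed: int = 0, warning: str = "") -> EvalRow:
    if len(labels) == 0:
        raise ValueError("empty test set")
    p, r, f1, acc = precision_recall_f1(confusion_counts(calls, labels))
    return EvalRow(model=model, modality=modality, precision=p, recall=r,
                   f1=f1, accuracy=acc, split=split, seed=seed, warning=warning)


def evaluate_model(results, test_dataset, train_ids=None, model: str = "",
                   modality: str = "", split: str = "", seed: int = 0,
                   threshold: float = 0.5) -> EvalRow:
    """Evaluate any fitted results object (``predict(dataset)``) on held-out data.

    ``train_ids``, when given, guards against train/test leakage: overlap is
    a hard error unless the overlap is the full training set (evaluating on
    the training data itself), which is flagged with a warning instead.
    """
    test_ids = [s.session_id for s in test_dataset.sessions]
    warning = ""
    if train_ids is not None:
        overlap = set(train_ids) & set(test_ids)
        if overlap and set(test_ids) <= set(train_ids):
            warning = "evaluated on training sessions"
            log.warning("evaluating on the training set (%d sessions)", len(test_ids))
        elif overlap:
            raise ValueError(
                f"train/test overlap for sessions {sorted(overlap)[:5]}...")
    _, calls = results.predict(test_dataset, threshold=threshold)
    return evaluate_calls(calls, test_dataset.labels, model=model,
                          modality=modality, split=split, seed=seed,
                          warning=warning)


def compare_models(rows: list[EvalRow]) -> pd.DataFrame:
    """One row per (model, modality), sorted by model name; shared split only."""
    if not rows:
        return pd.DataFrame(columns=["model", "modality", "precision", "recall",
                                     "f1", "accuracy", "split", "seed", "warning"])
    splits = {r.split for r in rows}
    if len(splits) > 1:
        raise ValueError(f"reports mix splits: {sorted(splits)}")
    keys = [(r.model, r.modality) for r in rows]
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate (model, modality) rows")
    df = pd.DataFrame([vars(r) for r in rows])
    return df.sort_values(["model", "modality"]).reset_index(drop=True)


def permutation_null_f1(calls, labels, n_permutations: int = 500,
                        seed: int = 0) -> np.ndarray:
    """F1 distribution when the model's calls are decoupled from the labels.

    Permuting the labels against the fixed calls preserves both the class
    prior and the model's positive-call rate, which is the correct null for
    'the model carries no signal'.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    out = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(labels)
        _, _, out[b], _ = precision_recall_f1(confusion_counts(calls, perm))
    return out


def null_band_for_mean(null_samples: np.ndarray, n_seeds: int,
                       n_draws: int = 2000, seed: int = 0,
                       coverage: float = 0.998) -> tuple[float, float]:
    """Band for the *mean over n_seeds runs* of a null-distributed statistic.

    Resamples means of ``n_seeds`` draws from the pooled null samples and
    returns the central ``coverage`` interval.
    """
    rng = np.random.default_rng(seed)
    means = rng.choice(null_samples, size=(n_draws, n_seeds)).mean(axis=1)
    alpha = (1.0 - coverage) / 2.0
    return (float(np.quantile(means, alpha)),
            float(np.quantile(means, 1.0 - alpha)))
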