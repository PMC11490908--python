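"""Sentence-level alignment, text featurization and class balancing.

The three modalities of an interview share one time index only through the
transcript's utterance timestamps.  Alignment therefore produces one time
step per *participant* utterance (interviewer turns are dropped — the
participant's speech is the clinical signal carrier): the audio and video
step vectors are per-feature means over the utterance's frame slice, and
the text step is a 300-dimensional mean token embedding concatenated with
the token count, giving 301 features.  Sequences are zero-padded or
truncated (earliest steps kept) to a fixed length ``L`` (default 1700).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

from .io_formats import CohortIndex, FrameTable, SessionBundle, TranscriptRecord

log = logging.getLogger(__name__)

DEFAULT_L = 1700
EMBED_DIM = 300
TEXT_DIM = EMBED_DIM + 1  # embedding mean + token count

_TOKEN_RE = re.compile(r"[^a-z0-9']+")


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace."""
    return [t for t in _TOKEN_RE.sub(" ", text.lower()).split() if t]


@dataclass
class TextFeaturizer:
    """Vocabulary, smoothed idf weights and a seeded random embedding table.

    idf(t) = ln((1 + N) / (1 + df_t)) + 1 over a corpus of N utterances.
    The embedding table is a deterministic function of (vocabulary, seed); a
    pretrained table can be substituted by assigning ``embedding_table``.
    Out-of-vocabulary tokens embed to zero and carry zero idf weight.
    """

    vocabulary: dict[str, int]
    idf: np.ndarray
    embedding_table: np.ndarray  # (V, 300)
    seed: int = 0

    @property
    def embed_dim(self) -> int:
        return self.embedding_table.shape[1]

    def tfidf_vector(self, text: str) -> np.ndarray:
        """L2-normalised tf-idf vector over the fitted vocabulary."""
        vec = np.zeros(len(self.vocabulary))
        for tok in tokenize(text):
            j = self.vocabulary.get(tok)
            if j is not None:
                vec[j] += 1.0
        vec *= self.idf
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    def embed_text(self, text: str) -> np.ndarray:
        """301-d step vector: mean token embedding (300) + token count (1)."""
        tokens = tokenize(text)
        out = np.zeros(TEXT_DIM)
        if not tokens:
            return out
        embs = [self.embedding_table[self.vocabulary[t]]
                for t in tokens if t in self.vocabulary]
        if embs:
            out[:EMBED_DIM] = np.mean(embs, axis=0)
        out[EMBED_DIM] = len(tokens)
        return out

    def embed_token(self, token: str) -> np.ndarray:
        out = np.zeros(TEXT_DIM)
        j = self.vocabulary.get(token)
        if j is not None:
            out[:EMBED_DIM] = self.embedding_table[j]
        out[EMBED_DIM] = 1.0
        return out


def fit_text_featurizer(utterances: list[str], seed: int = 0) -> TextFeaturizer:
    """Fit vocabulary + idf on a corpus of participant utterances."""
    if not utterances:
        raise ValueError("cannot fit a text featurizer on an empty corpus")
    df_counts: dict[str, int] = {}
    for utt in utterances:
        for tok in set(tokenize(utt)):
            df_counts[tok] = df_counts.get(tok, 0) + 1
    vocab = {tok: j for j, tok in enumerate(sorted(df_counts))}
    n = len(utterances)
    idf = np.array([math.log((1 + n) / (1 + df_counts[tok])) + 1.0
                    for tok in sorted(df_counts)])
    rng = np.random.default_rng(seed)
    table = rng.standard_normal((len(vocab), EMBED_DIM)) / math.sqrt(EMBED_DIM)
    return TextFeaturizer(vocabulary=vocab, idf=idf, embedding_table=table,
                          seed=seed)


def participant_corpus(bundles: list[SessionBundle]) -> list[str]:
    return [r.text for b in bundles for r in b.participant_utterances()]


# ---------------------------------------------------------------------------
# frame slicing and alignment

def slice_frames(frames: FrameTable, start: float, stop: float) -> np.ndarray:
    """Rows with frame index in ``[floor(start/period), floor(stop/period))``.

    Half-open, 0-based.  A window extending past the table end is truncated
    to the available frames (logged); a window entirely past the end returns
    an empty matrix.
    """
    if not (0 <= start < stop):
        raise ValueError(f"need 0 <= start < stop, got [{start}, {stop})")
    lo = math.floor(start / frames.frame_period)
    hi = math.floor(stop / frames.frame_period)
    if hi > frames.n_frames:
        log.warning("frame window [%g, %g) extends past table end (%d frames); truncated",
                    start, stop, frames.n_frames)
    return frames.features[lo:min(hi, frames.n_frames)]


@dataclass
class AlignedSession:
    """Fixed-length per-modality sequences for one session.

    Rows at index >= ``valid_steps`` are exactly zero (padding).
    """

    text_seq: np.ndarray   # (L, 301)
    audio_seq: np.ndarray  # (L, 74)
    video_seq: np.ndarray  # (L, 388)
    valid_steps: int
    label: int
    session_id: str = ""

    @property
    def L(self) -> int:
        return self.text_seq.shape[0]


_AGGREGATORS = {"mean": lambda m: m.mean(axis=0),
                "max": lambda m: m.max(axis=0),
                "std": lambda m: m.std(axis=0)}


def _aligned_from_steps(steps, bundle, L, session_id):
    n_keep = min(len(steps), L)
    if len(steps) > L:
        log.info("session %s: %d steps truncated to L=%d", bundle.session_id,
                 len(steps), L)
    text = np.zeros((L, TEXT_DIM), dtype=np.float32)
    audio = np.zeros((L, bundle.audio.d), dtype=np.float32)
    video = np.zeros((L, bundle.video.d), dtype=np.float32)
    for i, (t, a, v) in enumerate(steps[:n_keep]):
        text[i], audio[i], video[i] = t, a, v
    return AlignedSession(text_seq=text, audio_seq=audio, video_seq=video,
                          valid_steps=n_keep, label=bundle.label,
                          session_id=session_id or bundle.session_id)


def _modality_step(bundle, rec, agg):
    out = []
    for table in (bundle.audio, bundle.video):
        sl = slice_frames(table, rec.start_time, rec.stop_time)
        out.append(np.zeros(table.d) if sl.shape[0] == 0 else agg(sl))
    return out


def align_sentence_level(bundle: SessionBundle, featurizer: TextFeaturizer,
                         L: int = DEFAULT_L, agg: str = "mean") -> AlignedSession:
    """One aligned time step per participant utterance, in transcript order."""
    utterances = bundle.participant_utterances()
    if not utterances:
        raise ValueError(f"session {bundle.session_id}: no participant content")
    agg_fn = _AGGREGATORS[agg]
    steps = []
    for rec in utterances:
        a, v = _modality_step(bundle, rec, agg_fn)
        steps.append((featurizer.embed_text(rec.text), a, v))
    return _aligned_from_steps(steps, bundle, L, bundle.session_id)


def align_word_level(bundle: SessionBundle, featurizer: TextFeaturizer,
                     L: int = DEFAULT_L, agg: str = "mean") -> AlignedSession:
    """One step per participant token; audio/video repeat the sentence slice.

    Word-level forced alignment is not available in the schema, so each
    token inherits its sentence's aggregated audio/video vector.
    """
    utterances = bundle.participant_utterances()
    if not utterances:
        raise ValueError(f"session {bundle.session_id}: no participant content")
    agg_fn = _AGGREGATORS[agg]
    steps = []
    for rec in utterances:
        a, v = _modality_step(bundle, rec, agg_fn)
        for tok in tokenize(rec.text):
            steps.append((featurizer.embed_token(tok), a, v))
    return _aligned_from_steps(steps, bundle, L, bundle.session_id)


def lexical_profile(transcript: list[TranscriptRecord]) -> dict:
    """Word count, mean sentence length and type-token ratio (participant only
    when speaker labels are present in the list passed in)."""
    texts = [r.text for r in transcript]
    if not texts:
        raise ValueError("empty transcript")
    per_utt = [tokenize(t) for t in texts]
    all_tokens = [t for toks in per_utt for t in toks]
    if not all_tokens:
        raise ValueError("transcript contains no tokens")
    return {"word_count": len(all_tokens),
            "mean_sentence_length": float(np.mean([len(t) for t in per_utt])),
            "type_token_ratio": len(set(all_tokens)) / len(all_tokens)}


# ---------------------------------------------------------------------------
# class balancing

def upsample_minority(index: CohortIndex, seed: int = 0) -> CohortIndex:
    """Duplicate minority-class entries (with replacement) until balanced.

    Replicas get ids ``<sid>~k`` so the index keeps unique session ids while
    pointing at the same on-disk session.  Run on the *training split only*
    to avoid duplicated sessions leaking across splits.
    """
    n0, n1 = index.class_counts
    if n0 == 0 or n1 == 0:
        raise ValueError("upsampling needs both classes present")
    if n0 == n1:
        return CohortIndex(entries=list(index.entries))
    minority = 1 if n1 < n0 else 0
    pool = [e for e in index.entries if e[2] == minority]
    rng = np.random.default_rng(seed)
    deficit = abs(n0 - n1)
    entries = list(index.entries)
    picks = rng.integers(len(pool), size=deficit)
    for k, p in enumerate(picks, start=1):
        sid, path, label = pool[p]
        entries.append((f"{sid}~{k}", path, label))
    return CohortIndex(entries=entries)


# ---------------------------------------------------------------------------
# dataset containers used by the models

@dataclass
class AlignedDataset:
    """A stack of aligned sessions with array views per modality."""

    sessions: list[AlignedSession] = field(default_factory=list)

    def __len__(self):
        return len(self.sessions)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.sessions])

    def modality(self, name: str) -> np.ndarray:
        attr = {"text": "text_seq", "audio": "audio_seq", "video": "video_seq"}[name]
        return np.stack([getattr(s, attr) for s in self.sessions])

    def arrays(self) -> dict[str, np.ndarray]:
        return {m: self.modality(m) for m in ("audio", "video", "text")}

    def subset(self, idx) -> "AlignedDataset":
        return AlignedDataset([self.sessions[i] for i in np.asarray(idx)])


def align_cohort(bundles: list[SessionBundle], featurizer: TextFeaturizer = None,
                 L: int = DEFAULT_L, level: str = "sentence",
                 agg: str = "mean") -> tuple[AlignedDataset, TextFeaturizer]:
    """Fit a featurizer on the cohort (unless given) and align every session."""
    if featurizer is None:
        featurizer = fit_text_featurizer(participant_corpus(bundles))
    align = align_sentence_level if level == "sentence" else align_word_level
    ds = AlignedDataset([align(b, featurizer, L=L, agg=agg) for b in bundles])
    return ds, featurizer
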