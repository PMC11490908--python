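"""Synthetic interview cohorts with the statistical shell of DAIC-WOZ.

The licensed corpus cannot be redistributed, so every downstream stage is
exercised on generated cohorts that copy its *shell* — 189 sessions with a
7:3 non-depressed:depressed imbalance (130/59), 7-33 minute sessions,
74-dimensional audio features at 10 ms frames, 388-dimensional video
features — while the *class signal* is fully controllable: per-feature
Gaussian mean shifts for audio/video and a marker-token rate for text.

No acoustic or visual realism is attempted; the point is controllable
effect sizes, so that chance-level behaviour on zero-signal cohorts and
high accuracy on strong-signal cohorts are both predictable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (AUDIO_DIM, AUDIO_FRAME_PERIOD, VIDEO_DIM, CohortIndex,
                         FrameTable, SessionBundle, Speaker, TranscriptRecord,
                         read_session_bundle, write_cohort_index,
                         write_session_bundle)

#: everyday vocabulary used for all utterances
BASE_LEXICON = (
    "i you we today yesterday work home family friend time day week sleep "
    "food music walk talk think feel know want need good fine okay maybe "
    "really just about thing people place year school job city house morning"
).split()

#: marker tokens injected into depressed-class participant utterances
MARKER_LEXICON = "tired empty hopeless worthless alone numb heavy exhausted".split()

WORDS_PER_SECOND = 2.5  # speaking rate used to size utterance texts


@dataclass(frozen=True)
class CohortSpec:
    """Shape parameters of a generated cohort (defaults mirror the corpus)."""

    n_sessions: int = 189
    depressed_fraction: float = 59 / 189
    duration_range: tuple[float, float] = (420.0, 1980.0)  # 7-33 min
    audio_frame_period: float = AUDIO_FRAME_PERIOD
    video_frame_period: float = 1 / 30  # common video standard; corpus silent
    utterance_rate: float = 8.0  # utterances per minute (both speakers)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.depressed_fraction < 1:
            raise ValueError("depressed_fraction must be in (0, 1)")
        if self.duration_range[0] > self.duration_range[1]:
            raise ValueError("duration_range must be non-decreasing")
        if self.duration_range[0] <= 0:
            raise ValueError("durations must be positive")


@dataclass(frozen=True)
class SignalModel:
    """Controllable class signal injected per modality.

    ``audio_shift``/``video_shift`` are added to the frame-feature means of
    depressed-class sessions.  ``text_marker_rate`` is the probability that a
    depressed-class participant utterance contains a token from
    :data:`MARKER_LEXICON`; ``control_marker_rate`` is the same probability
    for non-depressed sessions (equal rates = no text signal).
    """

    audio_shift: np.ndarray = field(default_factory=lambda: np.zeros(AUDIO_DIM))
    video_shift: np.ndarray = field(default_factory=lambda: np.zeros(VIDEO_DIM))
    text_marker_rate: float = 0.0
    control_marker_rate: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "audio_shift",
                           np.broadcast_to(np.asarray(self.audio_shift, float),
                                           (AUDIO_DIM,)).copy())
        object.__setattr__(self, "video_shift",
                           np.broadcast_to(np.asarray(self.video_shift, float),
                                           (VIDEO_DIM,)).copy())
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for r in (self.text_marker_rate, self.control_marker_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("marker rates must be probabilities")

    # -- convenience constructors used throughout tests and examples ------
    @classmethod
    def null(cls, noise_sd: float = 1.0) -> "SignalModel":
        """No class signal in any modality."""
        return cls(noise_sd=noise_sd)

    @classmethod
    def single_modality(cls, modality: str, strength: float,
                        n_features: int = 16, noise_sd: float = 1.0,
                        marker_rate: float = 0.8) -> "SignalModel":
        """Signal confined to one modality (shift on the first features)."""
        audio = np.zeros(AUDIO_DIM)
        video = np.zeros(VIDEO_DIM)
        rates = (0.0, 0.0)
        if modality == "audio":
            audio[:n_features] = strength
        elif modality == "video":
            video[:n_features] = strength
        elif modality == "text":
            rates = (marker_rate, 0.02)
        else:
            raise ValueError(f"unknown modality {modality!r}")
        return cls(audio_shift=audio, video_shift=video,
                   text_marker_rate=rates[0], control_marker_rate=rates[1],
                   noise_sd=noise_sd)

    @classmethod
    def split(cls, audio_strength: float = 0.6, video_strength: float = 0.4,
              text_marker_rate: float = 0.5, n_features: int = 16,
              noise_sd: float = 1.0) -> "SignalModel":
        """Independent partial signal in each modality."""
        audio = np.zeros(AUDIO_DIM)
        audio[:n_features] = audio_strength
        video = np.zeros(VIDEO_DIM)
        video[:n_features] = video_strength
        return cls(audio_shift=audio, video_shift=video,
                   text_marker_rate=text_marker_rate,
                   control_marker_rate=0.05, noise_sd=noise_sd)


#: default signal for the default cohort: a moderate, multimodal effect —
#: the corpus publishes no per-feature effect sizes, so this is the package's
#: single fixed choice of a learnable but far-from-separable cohort.
DEFAULT_SIGNAL = SignalModel.split(audio_strength=0.5, video_strength=0.3,
                                   text_marker_rate=0.35, n_features=16,
                                   noise_sd=1.0)


def _make_transcript(label: int, duration: float, spec: CohortSpec,
                     signal: SignalModel, rng: np.random.Generator
                     ) -> list[TranscriptRecord]:
    """Alternating interviewer/participant utterances covering the session.

    Each interviewer+participant cycle occupies ``2/utterance_rate`` minutes;
    the participant's utterance fills ~half the cycle so participant speech
    covers roughly 50% of session time.
    """
    n_cycles = max(1, round(duration / 60.0 * spec.utterance_rate / 2.0))
    cycle = duration / n_cycles
    marker_rate = signal.text_marker_rate if label else signal.control_marker_rate
    records = []
    for k in range(n_cycles):
        t0 = k * cycle
        q_stop = t0 + 0.35 * cycle
        records.append(TranscriptRecord(
            start_time=t0 + 0.01 * cycle, stop_time=q_stop,
            speaker=Speaker.INTERVIEWER,
            text=" ".join(rng.choice(BASE_LEXICON, size=4))))
        a_start, a_stop = t0 + 0.40 * cycle, t0 + 0.90 * cycle
        n_words = max(1, round((a_stop - a_start) * WORDS_PER_SECOND))
        words = list(rng.choice(BASE_LEXICON, size=n_words))
        if rng.random() < marker_rate:
            words[rng.integers(len(words))] = str(rng.choice(MARKER_LEXICON))
        records.append(TranscriptRecord(
            start_time=a_start, stop_time=a_stop,
            speaker=Speaker.PARTICIPANT, text=" ".join(words)))
    return records


def generate_session(label: int, spec: CohortSpec, signal: SignalModel,
                     rng: np.random.Generator, session_id: str = "S0000"
                     ) -> SessionBundle:
    """Generate one session bundle for the given class label.

    Duration is uniform over ``spec.duration_range``; frame features are
    ``Normal(label * shift, noise_sd^2)`` i.i.d. per frame.
    """
    duration = float(rng.uniform(*spec.duration_range))
    n_audio = round(duration / spec.audio_frame_period)
    n_video = round(duration / spec.video_frame_period)
    audio = rng.standard_normal((n_audio, AUDIO_DIM), dtype=np.float32)
    audio *= signal.noise_sd
    audio += (label * signal.audio_shift).astype(np.float32)
    video = rng.standard_normal((n_video, VIDEO_DIM), dtype=np.float32)
    video *= signal.noise_sd
    video += (label * signal.video_shift).astype(np.float32)
    transcript = _make_transcript(label, duration, spec, signal, rng)
    return SessionBundle(
        session_id=session_id, transcript=transcript,
        audio=FrameTable(spec.audio_frame_period, audio),
        video=FrameTable(spec.video_frame_period, video),
        label=label, duration=duration)


def cohort_labels(spec: CohortSpec) -> list[int]:
    """Deterministic label sequence: exactly ``round(n * fraction)`` depressed."""
    n_dep = round(spec.n_sessions * spec.depressed_fraction)
    labels = [1] * n_dep + [0] * (spec.n_sessions - n_dep)
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(labels)
    return labels


def iter_cohort(spec: CohortSpec, signal: SignalModel = DEFAULT_SIGNAL):
    """Yield ``SessionBundle`` objects one at a time (nothing kept in memory).

    Each session draws from its own stream seeded ``spec.seed + ordinal``, so
    cohorts are reproducible session-by-session and under parallel generation.
    """
    if spec.n_sessions < 2:
        raise ValueError("a cohort needs at least 2 sessions")
    for ordinal, label in enumerate(cohort_labels(spec)):
        rng = np.random.default_rng(spec.seed + ordinal + 1)
        yield generate_session(label, spec, signal, rng,
                               session_id=f"S{ordinal:04d}")


def generate_cohort(spec: CohortSpec, signal: SignalModel = DEFAULT_SIGNAL,
                    out_dir=None) -> CohortIndex:
    """Generate a full cohort; write bundles plus ``index.csv`` if ``out_dir``.

    Deterministic given ``spec`` (including its seed) and ``signal``.
    """
    entries = []
    bundles = [] if out_dir is None else None
    for bundle in iter_cohort(spec, signal):
        if out_dir is not None:
            write_session_bundle(bundle, out_dir)
            entries.append((bundle.session_id, bundle.session_id, bundle.label))
        else:
            bundles.append(bundle)
            entries.append((bundle.session_id, bundle.session_id, bundle.label))
    index = CohortIndex(entries=entries)
    if out_dir is not None:
        write_cohort_index(index, Path(out_dir) / "index.csv")
        return index
    index.bundles = bundles  # in-memory cohorts carry their sessions along
    return index


def load_cohort(cohort_dir) -> list[SessionBundle]:
    """Load every bundle referenced by ``<cohort_dir>/index.csv``."""
    from .io_formats import read_cohort_index
    index = read_cohort_index(Path(cohort_dir) / "index.csv")
    return [read_session_bundle(cohort_dir, sid) for sid, _, _ in index.entries]


def ground_truth_summary(index: CohortIndex, cohort_dir=None) -> dict:
    """Class counts and duration statistics for a cohort index.

    When ``cohort_dir`` is given, labels and durations are re-read from the
    on-disk sidecars and missing sessions raise an error naming them.
    """
    import json

    if cohort_dir is not None:
        missing = [sid for sid, _, _ in index.entries
                   if not (Path(cohort_dir) / f"{sid}_meta.json").exists()]
        if missing:
            raise FileNotFoundError(
                f"cohort is missing session files for: {', '.join(missing)}")
        metas = [json.loads((Path(cohort_dir) / f"{sid}_meta.json").read_text())
                 for sid, _, _ in index.entries]
        labels = [m["label"] for m in metas]
        durations = [m["duration"] for m in metas]
    else:
        labels = [label for _, _, label in index.entries]
        durations = [b.duration for b in getattr(index, "bundles", [])]
    summary = {"n_sessions": len(index),
               "n_non_depressed": labels.count(0),
               "n_depressed": labels.count(1)}
    if durations:
        summary.update(duration_min=float(min(durations)),
                       duration_max=float(max(durations)),
                       duration_mean=float(np.mean(durations)))
    return summary
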