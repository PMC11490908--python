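"""Reading, writing and validating interview session bundles.

A *session bundle* is one clinical interview in the layout used by
timestamped-interview corpora such as DAIC-WOZ: a transcript table with
utterance start/stop times and speaker labels, a framewise audio-feature
table (74 features per 10 ms frame), a framewise video-feature table
(388 features per frame) and a binary depression label.

Everything here is plain CSV (comma by default, tab via ``dialect``),
UTF-8, '.' decimal separator.  Times are seconds expressed as decimals.
"""

from __future__ import annotations

import enum
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

AUDIO_DIM = 74
VIDEO_DIM = 388
AUDIO_FRAME_PERIOD = 0.010

#: numeric dtype used for frame tables; float32 round-trips exactly through
#: the '%.9g' text format used by :func:`write_session_bundle`.
FRAME_DTYPE = np.float32


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


class RowError(ValueError):
    """A specific row of a file violates an invariant; message cites the row."""


class Speaker(str, enum.Enum):
    PARTICIPANT = "participant"
    INTERVIEWER = "interviewer"


#: default mapping from raw speaker strings to the enum; anything not in the
#: mapping is treated as the interviewer (corpora name the agent differently).
DEFAULT_SPEAKER_MAP = {"Participant": Speaker.PARTICIPANT,
                       "participant": Speaker.PARTICIPANT}


@dataclass(frozen=True)
class TranscriptRecord:
    """One utterance: ``[start_time, stop_time)`` in seconds, speaker, text."""

    start_time: float
    stop_time: float
    speaker: Speaker
    text: str

    def __post_init__(self):
        if not self.stop_time > self.start_time:
            raise ValueError(
                f"stop_time {self.stop_time} must exceed start_time {self.start_time}")
        if self.start_time < 0:
            raise ValueError(f"start_time {self.start_time} is negative")
        if not self.text.strip():
            raise ValueError("utterance text is empty")


@dataclass
class FrameTable:
    """Framewise feature matrix sampled at a fixed ``frame_period`` (seconds)."""

    frame_period: float
    features: np.ndarray  # (n_frames, d)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=FRAME_DTYPE)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if np.isnan(self.features).any():
            raise ValueError("frame table contains missing values after validation")

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]


@dataclass
class SessionBundle:
    """One interview session: transcript + audio/video frame tables + label."""

    session_id: str
    transcript: list[TranscriptRecord]
    audio: FrameTable
    video: FrameTable
    label: int  # 0 = non-depressed, 1 = depressed
    duration: float  # seconds

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.transcript and max(r.stop_time for r in self.transcript) > self.duration + 1e-6:
            raise ValueError("transcript extends past the session duration")

    def participant_utterances(self) -> list[TranscriptRecord]:
        return [r for r in self.transcript if r.speaker is Speaker.PARTICIPANT]


@dataclass
class CohortIndex:
    """Index of a cohort on disk: (session_id, path, label) per session."""

    entries: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("session_ids in a cohort index must be unique")

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_non_depressed, n_depressed); sums to ``len(entries)``."""
        labels = [e[2] for e in self.entries]
        return labels.count(0), labels.count(1)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# transcript I/O

_REQUIRED_TRANSCRIPT_COLUMNS = ("start_time", "stop_time", "speaker", "value")


def read_transcript(path, speaker_map: dict | None = None,
                    dialect: str = ",") -> list[TranscriptRecord]:
    """Read a transcript CSV into records sorted by start time.

    Expected columns: ``start_time, stop_time, speaker, value``.  Speaker
    strings are mapped to :class:`Speaker` via ``speaker_map`` (default:
    ``"Participant"`` -> participant, anything else -> interviewer).

    Raises
    ------
    SchemaError
        if a required column is missing.
    RowError
        if a time is unparseable or ``stop <= start``; the message cites the
        1-based data row.
    """
    speaker_map = DEFAULT_SPEAKER_MAP if speaker_map is None else speaker_map
    df = pd.read_csv(path, sep=dialect, dtype=str, keep_default_na=False)
    for col in _REQUIRED_TRANSCRIPT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"transcript {path}: missing column '{col}'")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start = float(getattr(row, "start_time"))
            stop = float(getattr(row, "stop_time"))
        except ValueError as exc:
            raise RowError(f"transcript {path}, row {i}: unparseable time ({exc})") from exc
        speaker = speaker_map.get(getattr(row, "speaker"), Speaker.INTERVIEWER)
        try:
            records.append(TranscriptRecord(start, stop, speaker, getattr(row, "value")))
        except ValueError as exc:
            raise RowError(f"transcript {path}, row {i}: {exc}") from exc
    records.sort(key=lambda r: r.start_time)
    return records


def read_frame_table(path, expected_d: int,
                     frame_period: float = AUDIO_FRAME_PERIOD,
                     dialect: str = ",") -> FrameTable:
    """Read a framewise feature CSV (headered or headerless).

    Rows with missing cells are imputed by previous-frame carry-forward
    (a missing first frame becomes zeros); each imputation is logged.

    Raises :class:`SchemaError` when the column count differs from
    ``expected_d``.
    """
    df = pd.read_csv(path, sep=dialect, header=None)
    if df.shape[0] and df.iloc[0].map(_is_not_number).any():
        df = pd.read_csv(path, sep=dialect, header=0)
    if df.shape[1] != expected_d:
        raise SchemaError(
            f"frame table {path}: {df.shape[1]} != {expected_d} feature columns")
    values = df.to_numpy(dtype=np.float64)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        log.info("frame table %s: carry-forward imputed %d missing cells", path, n_missing)
        values = _carry_forward(values)
    return FrameTable(frame_period=frame_period, features=values)


def _is_not_number(x) -> bool:
    try:
        float(x)
        return False
    except (TypeError, ValueError):
        return True


def _carry_forward(values: np.ndarray) -> np.ndarray:
    """Previous-frame carry-forward imputation; first frame falls back to 0."""
    values = values.copy()
    missing = np.isnan(values[0])
    values[0, missing] = 0.0
    for i in range(1, values.shape[0]):
        missing = np.isnan(values[i])
        values[i, missing] = values[i - 1, missing]
    return values


# ---------------------------------------------------------------------------
# bundle I/O

_FLOAT_FMT = "%.9g"  # exact for float32


def write_session_bundle(bundle: SessionBundle, directory) -> dict[str, str]:
    """Write one bundle as transcript/audio/video CSVs plus a JSON sidecar.

    Returns the cohort-relative paths of the written files.  Re-writing an
    existing session id overwrites the files and logs a warning.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = bundle.session_id
    paths = {
        "transcript": f"{sid}_transcript.csv",
        "audio": f"{sid}_audio.csv",
        "video": f"{sid}_video.csv",
        "meta": f"{sid}_meta.json",
    }
    if (directory / paths["meta"]).exists():
        log.warning("session %s already exists in %s; overwriting", sid, directory)
    tdf = pd.DataFrame(
        {"start_time": [r.start_time for r in bundle.transcript],
         "stop_time": [r.stop_time for r in bundle.transcript],
         "speaker": [("Participant" if r.speaker is Speaker.PARTICIPANT else "Ellie")
                     for r in bundle.transcript],
         "value": [r.text for r in bundle.transcript]},
        columns=["start_time", "stop_time", "speaker", "value"])
    try:
        tdf.to_csv(directory / paths["transcript"], index=False, float_format="%.17g")
        np.savetxt(directory / paths["audio"], bundle.audio.features,
                   fmt=_FLOAT_FMT, delimiter=",")
        np.savetxt(directory / paths["video"], bundle.video.features,
                   fmt=_FLOAT_FMT, delimiter=",")
        meta = {"session_id": sid, "label": int(bundle.label),
                "duration": bundle.duration,
                "audio_frame_period": bundle.audio.frame_period,
                "video_frame_period": bundle.video.frame_period}
        (directory / paths["meta"]).write_text(json.dumps(meta, indent=1))
    except OSError as exc:
        raise OSError(f"writing session bundle {sid} under {directory}: {exc}") from exc
    return paths


def read_session_bundle(directory, session_id: str) -> SessionBundle:
    """Inverse of :func:`write_session_bundle` (bit-exact on numeric content)."""
    directory = Path(directory)
    meta = json.loads((directory / f"{session_id}_meta.json").read_text())
    transcript_path = directory / f"{session_id}_transcript.csv"
    transcript = read_transcript(transcript_path)
    audio = read_frame_table(directory / f"{session_id}_audio.csv", AUDIO_DIM,
                             frame_period=meta["audio_frame_period"])
    video = read_frame_table(directory / f"{session_id}_video.csv", VIDEO_DIM,
                             frame_period=meta["video_frame_period"])
    return SessionBundle(session_id=session_id, transcript=transcript,
                         audio=audio, video=video, label=meta["label"],
                         duration=meta["duration"])


def write_cohort_index(index: CohortIndex, path) -> None:
    pd.DataFrame(index.entries, columns=["session_id", "path", "label"]).to_csv(
        path, index=False)


def read_cohort_index(path) -> CohortIndex:
    df = pd.read_csv(path, dtype={"session_id": str, "path": str, "label": int})
    for col in ("session_id", "path", "label"):
        if col not in df.columns:
            raise SchemaError(f"cohort index {path}: missing column '{col}'")
    return CohortIndex(entries=[tuple(r) for r in df.itertuples(index=False)])
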