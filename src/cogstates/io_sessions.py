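"""Session data model and readers/writers.

All session artifacts live in plain headered CSV (one writer/reader pair per
type) with a JSON sidecar carrying metadata that the CSV itself cannot
(sampling rate, frame rate, montage, subject identity).  EDF is supported
read-only.  Time is seconds from session start; windows downstream are
half-open ``[start, end)``.

Landmark indices follow the 1-based p1..p68 convention used throughout the
facial-feature formulas; storage is 0-based and the conversion is done here
and in :mod:`cogstates.facial_features`, never by callers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    IngestionError,
    MontageMismatchError,
    OrderingError,
    RangeError,
)

#: The 14-channel 10-20 subset of the wireless headset, in recording order.
EMOTIV_14 = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

SCORE_INTERVAL = 10.0  # seconds between successive engagement scores


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _write_sidecar(path, meta: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path) -> dict:
    p = _sidecar_path(path)
    if p.exists():
        return json.loads(p.read_text())
    return {}


@dataclass
class EEGRecording:
    """Multichannel EEG segment, microvolts, channels x samples."""

    data: np.ndarray
    fs: float
    channels: tuple[str, ...] = EMOTIV_14
    subject_id: str = ""
    session_id: str = ""
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2:
            raise FormatError("EEG data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channels):
            raise MontageMismatchError(
                f"{self.data.shape[0]} data rows vs {len(self.channels)} channel names"
            )
        if not self.fs > 0:
            raise RangeError(f"sampling rate must be positive, got {self.fs}")
        if np.isnan(self.data).any():
            raise IngestionError("EEG data contains NaN after ingestion")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def slice_seconds(self, start: float, end: float) -> "EEGRecording":
        """Samples with timestamps in the half-open [start, end)."""
        i0 = int(round((start - self.t0) * self.fs))
        i1 = int(round((end - self.t0) * self.fs))
        i0, i1 = max(i0, 0), min(i1, self.n_samples)
        return EEGRecording(
            self.data[:, i0:i1], self.fs, self.channels,
            self.subject_id, self.session_id, t0=start,
        )


@dataclass
class BaselineRecording:
    """Pre-task resting recording: 15 s eyes open, 15 s closed, 6 s ready."""

    open_eyes: EEGRecording
    closed_eyes: EEGRecording
    ready: EEGRecording

    def __post_init__(self):
        segs = (self.open_eyes, self.closed_eyes, self.ready)
        if len({s.fs for s in segs}) != 1:
            raise FormatError("baseline segments disagree on sampling rate")
        if len({s.channels for s in segs}) != 1:
            raise FormatError("baseline segments disagree on channel order")

    @property
    def duration(self) -> float:
        return self.open_eyes.duration + self.closed_eyes.duration + self.ready.duration

    def concatenated(self) -> EEGRecording:
        """All three segments joined, for whole-baseline power estimation."""
        data = np.concatenate(
            [self.open_eyes.data, self.closed_eyes.data, self.ready.data], axis=1
        )
        return EEGRecording(data, self.open_eyes.fs, self.open_eyes.channels,
                            self.open_eyes.subject_id, self.open_eyes.session_id)


@dataclass
class LandmarkSequence:
    """Per-frame 68-point planar landmarks in pixels."""

    points: np.ndarray  # [n_frames, 68, 2]
    fps: float
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[1:] != (68, 2):
            raise FormatError(
                f"landmarks must be [n_frames, 68, 2], got {self.points.shape}"
            )
        # fps is deliberately not range-checked here: validate_session reports
        # a non-positive fps as a content violation instead of refusing the data.

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps if self.fps > 0 else float("nan")

    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class TrialLog:
    """Continuous-performance-task responses: (onset seconds, correct)."""

    trials: list[tuple[float, bool]] = field(default_factory=list)

    def __post_init__(self):
        onsets = [t for t, _ in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise OrderingError("trial onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def mistakes_in(self, start: float, end: float) -> int:
        """Incorrect trials with onset in the half-open [start, end)."""
        return sum(1 for t, ok in self.trials if start <= t < end and not ok)


@dataclass
class EngagementScoreSeries:
    """One score in [0, 1] per consecutive 10-s interval."""

    scores: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        for i, (t, s) in enumerate(self.scores):
            if not 0.0 <= s <= 1.0:
                raise RangeError(f"score {s} at row {i} outside [0, 1]")
        starts = [t for t, _ in self.scores]
        for a, b in zip(starts, starts[1:]):
            if not np.isclose(b - a, SCORE_INTERVAL):
                raise OrderingError(
                    f"score intervals must be consecutive {SCORE_INTERVAL}-s steps"
                )

    @property
    def values(self) -> np.ndarray:
        return np.array([s for _, s in self.scores], dtype=float)

    def in_window(self, start: float, end: float) -> np.ndarray:
        return np.array(
            [s for t, s in self.scores if start <= t < end], dtype=float
        )


@dataclass
class SkillScores:
    """Cognitive-skill assessment scores, each in [0, 800]."""

    focused_attention: float
    planning: float
    shifting: float

    def __post_init__(self):
        for name in ("focused_attention", "planning", "shifting"):
            v = getattr(self, name)
            if not 0.0 <= v <= 800.0:
                raise RangeError(f"{name} score {v} outside [0, 800]")

    def as_dict(self) -> dict[str, float]:
        return {
            "focused_attention": self.focused_attention,
            "planning": self.planning,
            "shifting": self.shifting,
        }


@dataclass
class SessionBundle:
    """Everything recorded in one session; only the EEG is mandatory."""

    eeg: EEGRecording
    baseline: BaselineRecording | None = None
    landmarks: LandmarkSequence | None = None
    trial_log: TrialLog | None = None
    engagement: EngagementScoreSeries | None = None
    skills: SkillScores | None = None

    @property
    def subject_id(self) -> str:
        return self.eeg.subject_id


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_eeg(path, format: str = "csv", fs: float | None = None,
             montage: tuple[str, ...] | None = None) -> EEGRecording:
    """Read an EEG recording from CSV (canonical) or EDF (read-only).

    CSV dialect: header row of channel names, one sample per row.  ``fs`` is
    taken from the JSON sidecar when present, else from the argument.  When a
    ``montage`` is declared the file's columns must match it exactly.
    """
    if format == "edf":
        return _read_edf(path, montage)
    if format != "csv":
        raise FormatError(f"unknown EEG format {format!r}")
    df = pd.read_csv(path)
    meta = _read_sidecar(path)
    if fs is None:
        fs = meta.get("fs")
    if fs is None:
        raise FormatError(f"no sampling rate for {path}: pass fs= or provide a sidecar")
    channels = tuple(df.columns)
    if montage is not None and channels != tuple(montage):
        raise MontageMismatchError(
            f"{path}: {len(channels)} columns {channels[:3]}... vs "
            f"declared {len(montage)}-channel montage"
        )
    values = df.to_numpy(dtype=float).T
    if np.isnan(values).any():
        bad_rows = np.where(np.isnan(values).any(axis=0))[0]
        raise IngestionError(f"{path}: NaN cell(s) at data row(s) {bad_rows[:5].tolist()}")
    return EEGRecording(values, float(fs), channels,
                        subject_id=meta.get("subject_id", ""),
                        session_id=meta.get("session_id", ""),
                        t0=float(meta.get("t0", 0.0)))


def _read_edf(path, montage=None) -> EEGRecording:
    import mne  # heavy import, deferred

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    channels = tuple(raw.ch_names)
    if montage is not None and channels != tuple(montage):
        raise MontageMismatchError(
            f"{path}: EDF channels {channels} vs declared montage"
        )
    data = raw.get_data() * 1e6  # mne returns volts; the model is microvolts
    return EEGRecording(data, float(raw.info["sfreq"]), channels)


def write_eeg(rec: EEGRecording, path) -> None:
    df = pd.DataFrame(rec.data.T, columns=list(rec.channels))
    df.to_csv(path, index=False)
    _write_sidecar(path, {
        "fs": rec.fs, "channels": list(rec.channels),
        "subject_id": rec.subject_id, "session_id": rec.session_id,
        "t0": rec.t0,
    })


def read_landmarks(path, fps: float | None = None) -> LandmarkSequence:
    """Read a landmark CSV with 136 coordinate columns x1,y1,...,x68,y68."""
    df = pd.read_csv(path)
    if df.shape[1] != 136:
        raise FormatError(f"{path}: expected 136 coordinate columns, got {df.shape[1]}")
    meta = _read_sidecar(path)
    if fps is None:
        fps = meta.get("fps")
    if fps is None:
        raise FormatError(f"no frame rate for {path}: pass fps= or provide a sidecar")
    pts = df.to_numpy(dtype=float).reshape(-1, 68, 2)
    return LandmarkSequence(pts, float(fps),
                            subject_id=meta.get("subject_id", ""),
                            session_id=meta.get("session_id", ""))


def write_landmarks(seq: LandmarkSequence, path) -> None:
    cols = [f"{ax}{i}" for i in range(1, 69) for ax in ("x", "y")]
    flat = seq.points.reshape(seq.n_frames, 136)
    pd.DataFrame(flat, columns=cols).to_csv(path, index=False)
    _write_sidecar(path, {"fps": seq.fps, "subject_id": seq.subject_id,
                          "session_id": seq.session_id})


def read_trial_log(path) -> TrialLog:
    """CSV schema: onset_time, correct (0/1 or true/false)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return TrialLog([])
    if df.empty:
        return TrialLog([])
    trials = [
        (float(t), bool(c))
        for t, c in zip(df["onset_time"], df["correct"].astype(bool))
    ]
    return TrialLog(trials)


def write_trial_log(log: TrialLog, path) -> None:
    pd.DataFrame(log.trials, columns=["onset_time", "correct"]).to_csv(
        path, index=False
    )


def read_scores(path) -> EngagementScoreSeries:
    """CSV schema: interval_start, score."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return EngagementScoreSeries([])
    if df.empty:
        return EngagementScoreSeries([])
    return EngagementScoreSeries(
        [(float(t), float(s)) for t, s in zip(df["interval_start"], df["score"])]
    )


def write_scores(series: EngagementScoreSeries, path) -> None:
    pd.DataFrame(series.scores, columns=["interval_start", "score"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_session(bundle: SessionBundle) -> list[str]:
    """Cross-modality consistency report; empty list means valid.

    Content problems are reported, never raised: a partially usable session
    is still a session.
    """
    problems: list[str] = []
    eeg = bundle.eeg
    if eeg.n_samples == 0:
        problems.append("EEG recording is empty")
    span = eeg.duration

    if bundle.baseline is not None:
        b = bundle.baseline
        if b.open_eyes.fs != eeg.fs:
            problems.append("baseline sampling rate differs from session EEG")
        if b.open_eyes.channels != eeg.channels:
            problems.append("baseline channel order differs from session EEG")
    if bundle.landmarks is not None:
        lm = bundle.landmarks
        if not lm.fps > 0:
            problems.append("landmark fps is not positive")
        elif abs(lm.duration - span) > 0.5 * span and span > 0:
            problems.append(
                f"landmark duration {lm.duration:.1f}s far from EEG span {span:.1f}s"
            )
    if bundle.trial_log is not None and bundle.trial_log.trials:
        last = bundle.trial_log.trials[-1][0]
        if last > span:
            problems.append(f"trial at {last:.1f}s beyond EEG span {span:.1f}s")
    if bundle.engagement is not None and bundle.engagement.scores:
        cover = bundle.engagement.scores[-1][0] + SCORE_INTERVAL
        if cover < span - SCORE_INTERVAL:
            problems.append(
                f"engagement scores cover {cover:.0f}s of a {span:.0f}s recording"
            )
    return problems
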