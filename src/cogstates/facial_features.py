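"""Geometric facial-landmark features and their per-window aggregation.

All formulas use the 1-based p1..p68 landmark numbering of the standard
68-point annotation scheme (jaw p1-17, brows p18-27, nose p28-36, eyes
p37-48, mouth p49-68).  Four scalar features are computed per frame:

* EAR - eye aspect ratio, the eye's height-to-width ratio; dips toward zero
  mark blinks.  The right-eye formula uses p37-42; the same formula applied
  to the symmetric block p43-48 yields the left eye, and ``ear`` is their
  mean.
* MAR - mouth aspect ratio, three inner-lip vertical gaps over mouth width.
* NTJ - nose-tip-to-right-jaw distance normalized by jaw width (yaw proxy).
* NTC - nose-tip-to-chin distance normalized by brow-to-jaw verticals
  (pitch proxy).

All four are ratios of Euclidean distances, hence invariant under planar
rotation, translation, and uniform scaling of a frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyWindowError, ProviderError
from .io_sessions import LandmarkSequence

#: EAR threshold below which the eye counts as closed, with the number of
#: consecutive frames required before a closure is a blink.  0.21 is the
#: conventional operating point of landmark-based blink detectors.
BLINK_EAR_THRESHOLD = 0.21
BLINK_MIN_FRAMES = 2

BASE_FEATURES = ("ear", "ear_right", "ear_left", "mar", "ntj", "ntc")


def _p(frame: np.ndarray, i: int) -> np.ndarray:
    """1-based landmark lookup: _p(frame, 31) is the nose tip p31."""
    return frame[i - 1]


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def _ratio(num: float, den: float) -> float:
    """NaN-signalling division for degenerate geometry (zero denominator)."""
    return num / den if den > 0 else float("nan")


def ear_right(frame: np.ndarray) -> float:
    """(||p42-p38|| + ||p41-p39||) / (2 ||p40-p37||)."""
    num = _dist(_p(frame, 42), _p(frame, 38)) + _dist(_p(frame, 41), _p(frame, 39))
    return _ratio(num, 2.0 * _dist(_p(frame, 40), _p(frame, 37)))


def ear_left(frame: np.ndarray) -> float:
    """Right-eye formula on the symmetric block p43-48."""
    num = _dist(_p(frame, 48), _p(frame, 44)) + _dist(_p(frame, 47), _p(frame, 45))
    return _ratio(num, 2.0 * _dist(_p(frame, 46), _p(frame, 43)))


def ear(frame: np.ndarray) -> float:
    """Mean of the right- and left-eye aspect ratios."""
    return 0.5 * (ear_right(frame) + ear_left(frame))


def mar(frame: np.ndarray) -> float:
    """(||p68-p62|| + ||p67-p63|| + ||p66-p64||) / (3 ||p55-p49||)."""
    num = (_dist(_p(frame, 68), _p(frame, 62))
           + _dist(_p(frame, 67), _p(frame, 63))
           + _dist(_p(frame, 66), _p(frame, 64)))
    return _ratio(num, 3.0 * _dist(_p(frame, 55), _p(frame, 49)))


def ntj(frame: np.ndarray) -> float:
    """||p31-p3|| / ||p15-p3||: nose tip offset along the jaw line."""
    return _ratio(_dist(_p(frame, 31), _p(frame, 3)),
                  _dist(_p(frame, 15), _p(frame, 3)))


def ntc(frame: np.ndarray) -> float:
    """2 ||p31-p9|| / (||p22-p8|| + ||p23-p10||): nose-to-chin, normalized."""
    den = _dist(_p(frame, 22), _p(frame, 8)) + _dist(_p(frame, 23), _p(frame, 10))
    return _ratio(2.0 * _dist(_p(frame, 31), _p(frame, 9)), den)


@dataclass
class FrameFeatures:
    ear: float
    ear_right: float
    ear_left: float
    mar: float
    ntj: float
    ntc: float
    frame_index: int
    timestamp: float
    degenerate: bool = False


def frame_features(frame: np.ndarray, frame_index: int = 0,
                   timestamp: float = 0.0) -> FrameFeatures:
    vals = {
        "ear_right": ear_right(frame), "ear_left": ear_left(frame),
        "mar": mar(frame), "ntj": ntj(frame), "ntc": ntc(frame),
    }
    vals["ear"] = 0.5 * (vals["ear_right"] + vals["ear_left"])
    degenerate = any(np.isnan(v) for v in vals.values())
    return FrameFeatures(frame_index=frame_index, timestamp=timestamp,
                         degenerate=degenerate, **vals)


def frame_feature_series(seq: LandmarkSequence) -> pd.DataFrame:
    """One row of geometric features per frame; degenerate frames are
    flagged (column ``degenerate``), never dropped."""
    ts = seq.timestamps()
    rows = [frame_features(seq.points[i], i, float(ts[i]))
            for i in range(seq.n_frames)]
    return pd.DataFrame([vars(r) for r in rows])


def count_blinks(ear_values: np.ndarray,
                 threshold: float = BLINK_EAR_THRESHOLD,
                 min_frames: int = BLINK_MIN_FRAMES) -> int:
    """Number of closures: maximal sub-threshold runs of >= min_frames."""
    below = np.asarray(ear_values) < threshold
    count, run = 0, 0
    for b in below:
        if b:
            run += 1
        else:
            if run >= min_frames:
                count += 1
            run = 0
    if run >= min_frames:
        count += 1
    return count


def aggregate_window(series: pd.DataFrame, window) -> dict[str, float]:
    """Summary statistics {mean, sd, min, max} per base feature plus a blink
    count, over the frames whose timestamp falls in [window.start, window.end).

    Degenerate frames are excluded from the statistics; the blink count uses
    the mean-EAR series of the valid frames.
    """
    mask = (series["timestamp"] >= window.start) & (series["timestamp"] < window.end)
    sub = series.loc[mask]
    if sub.empty:
        raise EmptyWindowError(
            f"no frames in window [{window.start}, {window.end})"
        )
    valid = sub.loc[~sub["degenerate"]]
    if valid.empty:
        raise EmptyWindowError("window contains only degenerate frames")
    out: dict[str, float] = {}
    for feat in BASE_FEATURES:
        col = valid[feat]
        out[f"{feat}_mean"] = float(col.mean())
        out[f"{feat}_sd"] = float(col.std(ddof=1)) if len(col) > 1 else 0.0
        out[f"{feat}_min"] = float(col.min())
        out[f"{feat}_max"] = float(col.max())
    out["blink_count"] = float(count_blinks(valid["ear"].to_numpy()))
    return out


def facial_window_table(seq: LandmarkSequence, windows: Sequence) -> pd.DataFrame:
    """Per-window facial feature table mirroring the EEG table schema."""
    series = frame_feature_series(seq)
    rows = []
    for w in windows:
        feats = aggregate_window(series, w)
        feats.update({"window_index": w.index, "start": w.start, "end": w.end})
        rows.append(feats)
    return pd.DataFrame(rows).set_index("window_index")


# ---------------------------------------------------------------------------
# pluggable frame embeddings
# ---------------------------------------------------------------------------

class SyntheticEmbeddingProvider:
    """Deterministic stand-in embedding: a fixed random linear map of the
    flattened landmark coordinates, squashed by tanh.

    This is a synthetic provider for exercising the embedding interface; it
    carries geometric information only, not any learned representation.
    """

    def __init__(self, dim: int = 1024, seed: int = 0):
        self.dim = dim
        rng = np.random.default_rng(seed)
        self._w = rng.normal(scale=1.0 / np.sqrt(136), size=(dim, 136))

    def __call__(self, frame: np.ndarray) -> np.ndarray:
        return np.tanh(self._w @ (np.asarray(frame, dtype=float).ravel() / 100.0))


def embed_frames(seq: LandmarkSequence,
                 provider: Callable[[np.ndarray], np.ndarray],
                 window=None) -> np.ndarray:
    """Fixed-length clip embedding: per-frame provider vectors averaged
    across the (optionally windowed) frames."""
    ts = seq.timestamps()
    if window is not None:
        idx = np.where((ts >= window.start) & (ts < window.end))[0]
    else:
        idx = np.arange(seq.n_frames)
    if idx.size == 0:
        raise EmptyWindowError("no frames to embed in the requested window")
    vecs = []
    dim = None
    for i in idx:
        v = np.asarray(provider(seq.points[i]), dtype=float).ravel()
        if dim is None:
            dim = v.size
        elif v.size != dim:
            raise ProviderError(
                f"provider returned length {v.size} after length {dim}"
            )
        vecs.append(v)
    return np.mean(vecs, axis=0)
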