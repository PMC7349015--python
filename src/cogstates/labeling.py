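"""Window segmentation and the three labeling rules.

Sessions are cut into consecutive, non-overlapping, half-open windows of a
fixed length (10 s or 60 s), discarding any trailing partial window.  Three
targets are labeled per window:

* engagement - the headset's per-10-s score against the pooled-cohort
  median threshold; a 60-s window uses the median of its six scores.
  Scores exactly at the threshold label as non-engaged (the positive,
  recall-weighted class).
* instantaneous attention - fewer than ``m`` mistakes (incorrect trials)
  in the window means highly attentive (1); ``m`` or more means low (0).
  The published threshold is m = 4.
* cognitive skills - assessment scores 0-800 cut at 200 and 400 into
  low / moderate / high.

Everywhere downstream, the *low* state (non-engaged, low attention, low
skill) is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .errors import DegenerateTableError, RangeError
from .io_sessions import EngagementScoreSeries, TrialLog, SCORE_INTERVAL

ATTENTION_MISTAKE_THRESHOLD = 4
SKILL_CUTS = (200.0, 400.0)


@dataclass(frozen=True)
class Window:
    """Half-open interval [start, end) with its position in the session."""

    start: float
    end: float
    index: int
    subject_id: str = ""

    @property
    def length(self) -> float:
        return self.end - self.start


def segment_windows(duration: float, window_len: float,
                    subject_id: str = "") -> list[Window]:
    """floor(duration / window_len) consecutive windows; the trailing
    partial window is discarded.  840 s at 10 s -> 84 windows, at 60 s -> 14."""
    if window_len <= 0:
        raise RangeError(f"window length must be positive, got {window_len}")
    n = int(np.floor(duration / window_len + 1e-9))
    return [
        Window(i * window_len, (i + 1) * window_len, i, subject_id)
        for i in range(n)
    ]


def median_threshold(all_scores) -> float:
    """Pooled-cohort median engagement score (the labeling threshold)."""
    scores = np.asarray(all_scores, dtype=float)
    if scores.size == 0:
        raise RangeError("cannot take the median of an empty score pool")
    return float(np.median(scores))


def engagement_labels(scores: EngagementScoreSeries, windows: Sequence[Window],
                      threshold: float) -> list[int | None]:
    """1 = engaged (score strictly above threshold), 0 = non-engaged.

    A 10-s window uses its single score, a 60-s window the median of its six;
    windows not fully covered by scores are unlabeled (None).  Ties at the
    threshold go to non-engaged.
    """
    out: list[int | None] = []
    for w in windows:
        vals = scores.in_window(w.start, w.end)
        expected = int(round(w.length / SCORE_INTERVAL))
        if vals.size != expected or expected == 0:
            out.append(None)
            continue
        score = float(np.median(vals))
        out.append(1 if score > threshold else 0)
    return out


def attention_labels(log: TrialLog, windows: Sequence[Window],
                     m: int = ATTENTION_MISTAKE_THRESHOLD) -> list[int]:
    """1 = high attention (< m mistakes in window), 0 = low (>= m)."""
    return [1 if log.mistakes_in(w.start, w.end) < m else 0 for w in windows]


def skill_class(score: float) -> str:
    """low (< 200), moderate (200 <= score < 400), high (>= 400)."""
    if not 0.0 <= score <= 800.0:
        raise RangeError(f"skill score {score} outside [0, 800]")
    if score < SKILL_CUTS[0]:
        return "low"
    if score < SKILL_CUTS[1]:
        return "moderate"
    return "high"


def label_dependence(labels_a, labels_b,
                     continuity_correction: bool = False):
    """Chi-square test of independence on the 2x2 table of paired binary
    labels -> (chi2, df, p).  No Yates correction by default."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise RangeError("label vectors must be paired")
    table = pd.crosstab(a, b).to_numpy()
    if table.shape != (2, 2) or (table.sum(axis=0) == 0).any() \
            or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(
            "chi-square needs a 2x2 table with nonzero marginals"
        )
    res = chi2_contingency(table, correction=continuity_correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def label_table(windows: Sequence[Window], engagement=None, attention=None,
                skills: dict[str, str] | None = None) -> pd.DataFrame:
    """Labels CSV schema: subject, window index/extent, one column per target."""
    rows = []
    for i, w in enumerate(windows):
        row = {
            "subject_id": w.subject_id, "window_index": w.index,
            "start": w.start, "end": w.end,
            "engagement": engagement[i] if engagement is not None else None,
            "attention": attention[i] if attention is not None else None,
        }
        if skills:
            row.update({f"skill_{k}": v for k, v in skills.items()})
        rows.append(row)
    return pd.DataFrame(rows)
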