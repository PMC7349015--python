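"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without any recorded data:

* **EEG** - each channel is a sum of band-limited sinusoids (one random
  in-band carrier frequency and phase per channel and band) plus a
  white + 1/f noise mixture.  Sinusoidal carriers rather than filtered
  noise give analytically known band powers for oracle tests.  Engagement
  state modulates alpha power (alpha suppression when engaged), attention
  state modulates theta/beta (theta rise, beta drop when attention lapses);
  both latent states are drawn per 10-s interval.  A per-subject amplitude
  scale U(0.5, 2) mimics inter-individual gain differences (hair, skull
  thickness) that motivate decibel baseline normalization.
* **Landmarks** - a neutral 68-point face template animated with blinks
  (eye landmarks collapse for 150-300 ms at a class-dependent rate),
  occasional mouth openings, slow head-pose drift (scaling the NTJ/NTC
  pose proxies) and Gaussian jitter.
* **Trial log** - one continuous-performance trial per second; the number
  of incorrect trials per 10-s window is Poisson with a mean set by the
  window's attention state.
* **Engagement scores** - one score in [0, 1] per 10 s, drawn from
  class-separated distributions whose separation is scaled by
  ``engagement_signal_strength`` (1 = perfectly separated at 0.5,
  0 = identical distributions).

Every generator is a pure function of (config, seed): identical inputs give
bit-identical outputs.  All distributions here are stand-ins with plausible
structure, not fits to any recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_sessions import (
    BaselineRecording,
    EEGRecording,
    EngagementScoreSeries,
    LandmarkSequence,
    SessionBundle,
    SkillScores,
    TrialLog,
    EMOTIV_14,
    SCORE_INTERVAL,
)

ENGAGEMENT_CLASSES = ("engaged", "non_engaged")
ATTENTION_CLASSES = ("attention_high", "attention_low")

#: Band carrier frequency ranges (Hz) used for synthesis; drawn with a 10%
#: margin inside each band to limit leakage across dyadic filter edges.
SYNTH_BAND_RANGES = {
    "delta": (0.8, 3.6),
    "theta": (4.4, 7.6),
    "alpha": (8.4, 11.6),   # classical alpha; sits inside the dyadic 8-16 band
    "beta": (17.6, 30.4),
    "gamma": (33.6, 46.0),
}

#: Default class -> band -> amplitude (uV).  Engagement trades alpha power
#: against beta (alpha suppression with beta rise when engaged -- the
#: direction of the classical beta/(alpha+theta) engagement index);
#: attention trades theta against beta (theta rise, beta drop during
#: lapses).  Within each pair the amplitudes are power-balanced (equal sum
#: of squares: 14.697 = sqrt(6^2 + 14^2 - 4^2), 11.705 =
#: sqrt(3^2 + 12^2 - 4^2)), and a window combines its two states in the
#: power domain, so total power is identical across all four latent
#: combinations: only the deliberately modulated bands carry class signal
#: and the relative powers of the untouched bands stay flat.
DEFAULT_BAND_AMPLITUDES = {
    "engaged":        {"delta": 5.0, "theta": 6.0, "alpha": 4.0, "beta": 14.697, "gamma": 3.0},
    "non_engaged":    {"delta": 5.0, "theta": 6.0, "alpha": 14.0, "beta": 6.0, "gamma": 3.0},
    "attention_high": {"delta": 5.0, "theta": 4.0, "alpha": 9.0, "beta": 11.705, "gamma": 3.0},
    "attention_low":  {"delta": 5.0, "theta": 12.0, "alpha": 9.0, "beta": 3.0, "gamma": 3.0},
}

_CLASS_PAIR = {
    "engaged": ENGAGEMENT_CLASSES, "non_engaged": ENGAGEMENT_CLASSES,
    "attention_high": ATTENTION_CLASSES, "attention_low": ATTENTION_CLASSES,
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated study design: 840-s (14-min) sessions at
    128 Hz across 14 channels, 30-fps landmarks, one engagement score per
    10 s, and an imbalanced low-attention state (~15% of windows), with
    full class separation (strength 1) and modest background noise.
    """

    n_subjects: int = 60
    session_duration: float = 840.0
    fs: float = 128.0
    fps: float = 30.0
    band_amplitudes: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BAND_AMPLITUDES.items()})
    noise_sd: float = 2.0
    blink_rate: dict = field(
        default_factory=lambda: {"engaged": 8.0, "non_engaged": 18.0})
    mistake_rate: dict = field(
        default_factory=lambda: {"high": 0.5, "low": 8.0})
    engagement_signal_strength: float = 1.0
    seed: int = 0
    # secondary knobs
    trial_cadence: float = 1.0          # seconds between trials
    p_engaged: float = 0.5              # P(interval engaged)
    p_low_given_engaged: float = 0.08   # attention lapse probabilities,
    p_low_given_non_engaged: float = 0.22  # chosen to couple the two states
    subject_scale_range: tuple = (0.5, 2.0)
    landmark_jitter: float = 0.3        # px
    channels: tuple = EMOTIV_14
    modalities: tuple = ("eeg", "baseline", "landmarks", "trials", "scores", "skills")

    def __post_init__(self):
        for amps in self.band_amplitudes.values():
            if any(a < 0 for a in amps.values()):
                raise ValueError("band amplitudes must be non-negative")
        if self.noise_sd < 0 or any(r < 0 for r in self.mistake_rate.values()):
            raise ValueError("rates and noise must be non-negative")
        if not 0.0 <= self.engagement_signal_strength <= 1.0:
            raise ValueError("engagement_signal_strength must be in [0, 1]")


def effective_amplitudes(config: SyntheticConfig, class_label: str) -> dict:
    """Class amplitudes shrunk toward their pair mean by (1 - strength).

    At strength 1 the configured amplitudes are used as-is; at 0 the two
    classes of a pair become indistinguishable.
    """
    amps = config.band_amplitudes[class_label]
    pair = _CLASS_PAIR.get(class_label)
    if pair is None:
        return dict(amps)
    s = config.engagement_signal_strength
    mean = {b: np.mean([config.band_amplitudes[c][b] for c in pair])
            for b in amps}
    return {b: mean[b] + s * (amps[b] - mean[b]) for b in amps}


def _session_samples(config: SyntheticConfig) -> int:
    exact = config.session_duration * config.fs
    n = int(np.floor(exact + 1e-9))
    if abs(exact - round(exact)) > 1e-9:
        warnings.warn(
            f"session_duration*fs = {exact} is not integral; rounding down to {n}"
        )
    return n


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _noise(n_channels: int, n: int, sd: float,
           rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0 or n == 0:
        return np.zeros((n_channels, n))
    out = np.empty((n_channels, n))
    for c in range(n_channels):
        mix = 0.5 * rng.standard_normal(n) + 0.5 * _pink_noise(n, rng)
        out[c] = sd * mix / mix.std()
    return out


def _band_carriers(amps: dict, n_channels: int, n: int, fs: float,
                   rng: np.random.Generator):
    """Sum-of-sinusoids signal and the realized per-band variance per channel."""
    t = np.arange(n) / fs
    signal = np.zeros((n_channels, n))
    var = {b: np.zeros(n_channels) for b in amps}
    for band, a in amps.items():
        lo, hi = SYNTH_BAND_RANGES[band]
        hi = min(hi, fs / 2 * 0.95)
        freqs = rng.uniform(lo, hi, n_channels)
        phases = rng.uniform(0, 2 * np.pi, n_channels)
        comp = a * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
        signal += comp
        var[band] = comp.var(axis=1)
    return signal, var


def generate_eeg_session(config: SyntheticConfig, class_label: str,
                         seed: int | None = None,
                         duration: float | None = None):
    """One single-class EEG recording plus its ground-truth band structure.

    Returns ``(EEGRecording, DataFrame)`` where the frame holds the realized
    per-channel variance fraction of each band (noise excluded).
    """
    if class_label not in config.band_amplitudes:
        raise KeyError(f"unknown class {class_label!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cfg = config if duration is None else replace(config, session_duration=duration)
    n = _session_samples(cfg)
    amps = effective_amplitudes(config, class_label)
    n_ch = len(config.channels)
    signal, var = _band_carriers(amps, n_ch, n, config.fs, rng)
    signal += _noise(n_ch, n, config.noise_sd, rng)
    total = np.sum([v for v in var.values()], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = {b: np.where(total > 0, v / total, 0.0) for b, v in var.items()}
    truth = pd.DataFrame(frac, index=list(config.channels))
    rec = EEGRecording(signal, config.fs, config.channels,
                       session_id=class_label)
    return rec, truth


def _piecewise_eeg(config: SyntheticConfig, eng_states, att_states,
                   amp_scale: float, rng: np.random.Generator) -> EEGRecording:
    """Session whose band amplitudes follow per-10-s latent states."""
    seg_n = int(round(SCORE_INTERVAL * config.fs))
    n_ch = len(config.channels)
    segments = []
    for e, a in zip(eng_states, att_states):
        amps_e = effective_amplitudes(config, "engaged" if e else "non_engaged")
        amps_a = effective_amplitudes(
            config, "attention_high" if a else "attention_low")
        # power-domain combination: band power = mean of the two states'
        # powers, keeping total power independent of the state combination
        amps = {b: amp_scale * np.sqrt(0.5 * (amps_e[b] ** 2 + amps_a[b] ** 2))
                for b in amps_e}
        seg, _ = _band_carriers(amps, n_ch, seg_n, config.fs, rng)
        seg += _noise(n_ch, seg_n, amp_scale * config.noise_sd, rng)
        segments.append(seg)
    data = np.concatenate(segments, axis=1) if segments else np.zeros((n_ch, 0))
    return EEGRecording(data, config.fs, config.channels)


def generate_baseline(config: SyntheticConfig,
                      seed: int | None = None) -> BaselineRecording:
    """Resting recording: 15 s eyes open, 15 s eyes closed, 6 s ready.

    The closed-eyes segment carries doubled alpha amplitude -- the classical
    resting alpha effect, used only as plausible structure.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    base_amps = {
        b: np.mean([config.band_amplitudes[c][b] for c in ENGAGEMENT_CLASSES])
        for b in SYNTH_BAND_RANGES
    }
    n_ch = len(config.channels)

    def segment(duration: float, amps: dict) -> EEGRecording:
        n = int(round(duration * config.fs))
        sig, _ = _band_carriers(amps, n_ch, n, config.fs, rng)
        sig += _noise(n_ch, n, config.noise_sd, rng)
        return EEGRecording(sig, config.fs, config.channels)

    closed_amps = dict(base_amps)
    closed_amps["alpha"] = 2.0 * closed_amps["alpha"]
    return BaselineRecording(
        open_eyes=segment(15.0, base_amps),
        closed_eyes=segment(15.0, closed_amps),
        ready=segment(6.0, base_amps),
    )


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def neutral_face_template() -> np.ndarray:
    """A symmetric frontal 68-point face in a 200x200 px frame (y down)."""
    pts = np.zeros((68, 2))
    # jaw p1-17: semi-ellipse ear-to-ear through the chin
    phi = np.linspace(0, np.pi, 17)
    pts[0:17, 0] = 100 - 70 * np.cos(phi)
    pts[0:17, 1] = 80 + 90 * np.sin(phi)
    # brows p18-27
    pts[17:22] = np.column_stack([np.linspace(58, 88, 5),
                                  [80, 76, 74, 75, 78]])
    pts[22:27] = np.column_stack([np.linspace(112, 142, 5),
                                  [78, 75, 74, 76, 80]])
    # nose bridge p28-31 (p31 = tip) and nostril line p32-36
    pts[27:31] = [[100, 92], [100, 100], [100, 108], [100, 115]]
    pts[31:36] = np.column_stack([np.linspace(90, 110, 5), np.full(5, 120.0)])
    # right eye p37-42 (p37 outer corner, clockwise)
    pts[36:42] = [[65, 95], [75, 91], [85, 91], [92, 95], [85, 99], [75, 99]]
    # left eye p43-48 (p43 inner corner)
    pts[42:48] = [[108, 95], [115, 91], [125, 91], [135, 95], [125, 99], [115, 99]]
    # outer lip p49-60
    pts[48:60] = [[78, 140], [85, 135], [93, 133], [100, 132], [107, 133],
                  [115, 135], [122, 140], [115, 146], [107, 149], [100, 150],
                  [93, 149], [85, 146]]
    # inner lip p61-68
    pts[60:68] = [[82, 140], [92, 137], [100, 136], [108, 137], [118, 140],
                  [108, 143], [100, 144], [92, 143]]
    return pts

#: 0-based indices of the moving eye landmarks (p38, p39, p41, p42 and the
#: left-eye mirror p44, p45, p47, p48), split top/bottom.
_EYE_TOP = np.array([37, 38, 43, 44])
_EYE_BOTTOM = np.array([40, 41, 46, 47])
_EYE_MID_Y = 95.0
_MOUTH_LOWER = np.array([55, 56, 57, 58, 59, 65, 66, 67])  # p56-60, p66-68
_NOSE = np.arange(27, 36)                                   # p28-36


def _draw_blinks(duration: float, rate_per_min, rng: np.random.Generator,
                 state_len: float = SCORE_INTERVAL):
    """Blink (start, end) events from a (piecewise) Poisson process with a
    0.4-s refractory gap; ``rate_per_min`` is a scalar or per-interval array."""
    rates = np.atleast_1d(np.asarray(rate_per_min, dtype=float))
    events = []
    t = 0.0
    while t < duration:
        idx = min(int(t / state_len), rates.size - 1)
        rate = rates[idx]
        if rate <= 0:
            t = (idx + 1) * state_len if rates.size > 1 else duration
            continue
        gap = rng.exponential(60.0 / rate)
        t += max(gap, 0.4)
        if t >= duration:
            break
        dur = rng.uniform(0.15, 0.3)
        events.append((t, min(t + dur, duration)))
        t += dur
    return events


def _animate(config: SyntheticConfig, duration: float, blink_events,
             rng: np.random.Generator) -> np.ndarray:
    n_frames = int(round(duration * config.fps))
    ts = np.arange(n_frames) / config.fps
    pts = np.repeat(neutral_face_template()[None, :, :], n_frames, axis=0)

    # blink closure profile: triangular rise/fall inside each event
    closure = np.zeros(n_frames)
    for start, end in blink_events:
        mask = (ts >= start) & (ts < end)
        if not mask.any():
            continue
        mid = 0.5 * (start + end)
        half = max(0.5 * (end - start), 1e-6)
        closure[mask] = np.maximum(closure[mask],
                                   1.0 - np.abs(ts[mask] - mid) / half)
    top_gap = pts[0, _EYE_TOP, 1] - _EYE_MID_Y        # negative offsets
    bot_gap = pts[0, _EYE_BOTTOM, 1] - _EYE_MID_Y
    pts[:, _EYE_TOP, 1] = _EYE_MID_Y + np.outer(1 - closure, top_gap)
    pts[:, _EYE_BOTTOM, 1] = _EYE_MID_Y + np.outer(1 - closure, bot_gap)

    # occasional mouth openings (~2/min, 1 s long, smooth bump)
    n_open = rng.poisson(duration / 30.0)
    opening = np.zeros(n_frames)
    for start in rng.uniform(0, max(duration - 1.0, 0.0), n_open):
        mask = (ts >= start) & (ts < start + 1.0)
        opening[mask] = np.maximum(
            opening[mask], np.sin(np.pi * (ts[mask] - start)) ** 2)
    pts[:, _MOUTH_LOWER, 1] += 6.0 * opening[:, None]

    # slow head-pose drift: yaw shifts the nose block in x (drives NTJ),
    # pitch shifts it in y (drives NTC)
    yaw = 6.0 * np.sin(2 * np.pi * ts / rng.uniform(25, 45)
                       + rng.uniform(0, 2 * np.pi))
    pitch = 4.0 * np.sin(2 * np.pi * ts / rng.uniform(30, 60)
                         + rng.uniform(0, 2 * np.pi))
    pts[:, _NOSE, 0] += yaw[:, None]
    pts[:, _NOSE, 1] += pitch[:, None]

    if config.landmark_jitter > 0:
        pts += rng.normal(scale=config.landmark_jitter, size=pts.shape)
    return pts


def generate_landmark_sequence(config: SyntheticConfig, class_label: str,
                               duration: float | None = None,
                               seed: int | None = None):
    """Animated landmark sequence for one class.

    Returns ``(LandmarkSequence, blink_events)`` where the events are the
    ground-truth (start, end) times of the generated blinks.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    duration = config.session_duration if duration is None else duration
    rate = config.blink_rate.get(class_label, 10.0)
    events = _draw_blinks(duration, rate, rng)
    pts = _animate(config, duration, events, rng)
    return LandmarkSequence(pts, config.fps, session_id=class_label), events


def _landmarks_for_states(config: SyntheticConfig, eng_states,
                          rng: np.random.Generator):
    duration = len(eng_states) * SCORE_INTERVAL
    rates = np.array([
        config.blink_rate["engaged" if e else "non_engaged"] for e in eng_states
    ])
    events = _draw_blinks(duration, rates, rng)
    pts = _animate(config, duration, events, rng)
    return LandmarkSequence(pts, config.fps), events


# ---------------------------------------------------------------------------
# behavioural streams
# ---------------------------------------------------------------------------

def generate_trial_log(config: SyntheticConfig, attention_profile,
                       seed: int | None = None) -> TrialLog:
    """Trials at a fixed cadence; per 10-s window the number of incorrect
    trials is Poisson(mistake_rate[state]) truncated to the trials available.

    ``attention_profile`` holds one entry per 10-s window: "high"/"low"
    (or truthy 1/0).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    duration = len(attention_profile) * SCORE_INTERVAL
    onsets = np.arange(0.5 * config.trial_cadence, duration, config.trial_cadence)
    correct = np.ones(onsets.size, dtype=bool)
    for i, state in enumerate(attention_profile):
        key = state if isinstance(state, str) else ("high" if state else "low")
        lam = config.mistake_rate[key]
        w0, w1 = i * SCORE_INTERVAL, (i + 1) * SCORE_INTERVAL
        idx = np.where((onsets >= w0) & (onsets < w1))[0]
        k = min(int(rng.poisson(lam)), idx.size)
        if k > 0:
            correct[rng.choice(idx, size=k, replace=False)] = False
    return TrialLog([(float(t), bool(c)) for t, c in zip(onsets, correct)])


def generate_engagement_scores(config: SyntheticConfig, classes,
                               seed: int | None = None) -> EngagementScoreSeries:
    """One score per 10-s interval.

    Engaged intervals draw 0.5 + 0.5*Beta(2,2)*s, non-engaged the mirror
    image, blended with a class-free uniform component by the signal
    strength ``s``; strength 1 separates the classes exactly at 0.5,
    strength 0 makes the distributions identical.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    s = config.engagement_signal_strength
    scores = []
    for i, cls in enumerate(classes):
        engaged = cls in (1, True, "engaged")
        u = rng.beta(2.0, 2.0)
        z = rng.uniform(-1.0, 1.0)
        signed = u if engaged else -u
        val = 0.5 + 0.5 * (s * signed + (1.0 - s) * z)
        scores.append((i * SCORE_INTERVAL, float(np.clip(val, 0.0, 1.0))))
    return EngagementScoreSeries(scores)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def iter_cohort(config: SyntheticConfig):
    """Yield ``(SessionBundle, truth)`` per subject without holding the whole
    cohort in memory; ``truth`` is a per-10-s-window DataFrame of the latent
    engagement/attention states.

    Per-subject seeds are spawned deterministically from ``config.seed``.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    n_int = int(np.floor(config.session_duration / SCORE_INTERVAL + 1e-9))
    for s_idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        subject = f"S{s_idx:03d}"
        eng = (rng.uniform(size=n_int) < config.p_engaged).astype(int)
        p_low = np.where(eng == 1, config.p_low_given_engaged,
                         config.p_low_given_non_engaged)
        att = (rng.uniform(size=n_int) >= p_low).astype(int)  # 1 = high
        scale = rng.uniform(*config.subject_scale_range)

        eeg = baseline = landmarks = trial_log = scores = skills = None
        if "eeg" in config.modalities:
            eeg = _piecewise_eeg(config, eng, att, scale, rng)
            eeg.subject_id = subject
        if "baseline" in config.modalities:
            baseline = generate_baseline(
                config, seed=int(rng.integers(2 ** 31)))
            for seg in (baseline.open_eyes, baseline.closed_eyes, baseline.ready):
                seg.data *= scale
                seg.subject_id = subject
        if "landmarks" in config.modalities:
            landmarks, _ = _landmarks_for_states(config, eng, rng)
            landmarks.subject_id = subject
        if "trials" in config.modalities:
            trial_log = generate_trial_log(
                config, ["high" if a else "low" for a in att],
                seed=int(rng.integers(2 ** 31)))
        if "scores" in config.modalities:
            scores = generate_engagement_scores(
                config, eng, seed=int(rng.integers(2 ** 31)))
        if "skills" in config.modalities:
            skills = SkillScores(*[float(v) for v in rng.uniform(0, 800, 3)])
        if eeg is None:
            raise ValueError("cohort generation requires the eeg modality")
        bundle = SessionBundle(eeg=eeg, baseline=baseline, landmarks=landmarks,
                               trial_log=trial_log, engagement=scores,
                               skills=skills)
        truth = pd.DataFrame({
            "subject_id": subject,
            "window_index": np.arange(n_int),
            "engagement_state": eng,
            "attention_state": att,
            "amp_scale": scale,
        })
        yield bundle, truth


def generate_cohort(config: SyntheticConfig):
    """All subjects at once -> (list of SessionBundle, concatenated truth)."""
    bundles, truths = [], []
    for bundle, truth in iter_cohort(config):
        bundles.append(bundle)
        truths.append(truth)
    truth = (pd.concat(truths, ignore_index=True) if truths
             else pd.DataFrame(columns=["subject_id", "window_index",
                                        "engagement_state", "attention_state",
                                        "amp_scale"]))
    return bundles, truth
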