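"""Stage orchestration: simulate -> extract -> label -> train -> report.

Every stage reads and writes flat CSV/JSON artifacts in a working directory
so each step is independently inspectable, and writes a manifest (inputs,
seed, config hash, wall time) next to its outputs.  Reruns with identical
inputs are byte-identical up to timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import CogstatesError, FormatError
from .experiments import window_feature_table
from .facial_features import facial_window_table
from .io_sessions import (
    SessionBundle,
    read_eeg,
    read_landmarks,
    read_scores,
    read_trial_log,
    write_eeg,
    write_landmarks,
    write_scores,
    write_trial_log,
)
from .labeling import (
    attention_labels,
    engagement_labels,
    label_table,
    median_threshold,
    segment_windows,
    skill_class,
)
from .modeling import ExperimentConfig, train_eval
from .synthetic import SyntheticConfig, iter_cohort

STAGES = ("simulate", "extract-eeg", "extract-face", "label", "train", "report")


@dataclass
class PipelineConfig:
    """One file that fully determines a pipeline run."""

    workdir: str = "pipeline_run"
    seed: int = 0
    window_len: int = 10
    target: str = "engagement"
    modality: str = "eeg"
    feature_mode: str = "frequency"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)

    def __post_init__(self):
        if self.window_len not in (10, 60):
            raise FormatError("window_len must be 10 or 60")
        if self.target not in ("engagement", "attention", "focused_attention",
                               "planning", "shifting"):
            raise FormatError(f"unknown target {self.target!r}")
        if self.modality not in ("eeg", "facial"):
            raise FormatError(f"unknown modality {self.modality!r}")
        # one seed drives every stage
        self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)
        self.experiment = dataclasses.replace(
            self.experiment, seed=self.seed, target=self.target,
            window_len=self.window_len)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["band_amplitudes"] = {
            k: dict(v) for k, v in d["synthetic"]["band_amplitudes"].items()}
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = SyntheticConfig(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in raw.pop("synthetic", {}).items()})
        exp = ExperimentConfig(**raw.pop("experiment", {}))
        return cls(synthetic=syn, experiment=exp, **raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _manifest(workdir: Path, stage: str, config: PipelineConfig,
              outputs: list[str], t0: float) -> None:
    manifest = {
        "stage": stage, "seed": config.seed,
        "config_hash": _config_hash(config), "version": __version__,
        "outputs": sorted(outputs), "wall_time_s": round(time.time() - t0, 3),
    }
    (workdir / f"manifest_{stage.replace('-', '_')}.json").write_text(
        json.dumps(manifest, indent=1))
    (workdir / "config_resolved.json").write_text(
        json.dumps(config.to_dict(), indent=1, default=str))


def _subject_dirs(workdir: Path) -> list[Path]:
    return sorted(p for p in (workdir / "cohort").glob("S*") if p.is_dir())


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise CogstatesError(
            f"missing upstream artifact {path} ({what}); run the earlier stage first")
    return path


def run_stage(name: str, config: PipelineConfig) -> list[str]:
    """Run one named stage; returns the list of files written."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    runner = {
        "simulate": _stage_simulate,
        "extract-eeg": _stage_extract_eeg,
        "extract-face": _stage_extract_face,
        "label": _stage_label,
        "train": _stage_train,
        "report": _stage_report,
    }.get(name)
    if runner is None:
        raise CogstatesError(f"unknown stage {name!r}; stages are {STAGES}")
    outputs = runner(workdir, config)
    _manifest(workdir, name, config, outputs, t0)
    return outputs


def _stage_simulate(workdir: Path, config: PipelineConfig) -> list[str]:
    outputs = []
    truths = []
    for bundle, truth in iter_cohort(config.synthetic):
        sdir = workdir / "cohort" / bundle.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        write_eeg(bundle.eeg, sdir / "eeg.csv")
        outputs.append(str(sdir / "eeg.csv"))
        if bundle.landmarks is not None:
            write_landmarks(bundle.landmarks, sdir / "landmarks.csv")
            outputs.append(str(sdir / "landmarks.csv"))
        if bundle.trial_log is not None:
            write_trial_log(bundle.trial_log, sdir / "trials.csv")
            outputs.append(str(sdir / "trials.csv"))
        if bundle.engagement is not None:
            write_scores(bundle.engagement, sdir / "scores.csv")
            outputs.append(str(sdir / "scores.csv"))
        if bundle.skills is not None:
            (sdir / "skills.json").write_text(
                json.dumps(bundle.skills.as_dict(), indent=1))
            outputs.append(str(sdir / "skills.json"))
        truths.append(truth)
    truth_path = workdir / "ground_truth.csv"
    pd.concat(truths, ignore_index=True).to_csv(truth_path, index=False)
    outputs.append(str(truth_path))
    return outputs


def _stage_extract_eeg(workdir: Path, config: PipelineConfig) -> list[str]:
    frames = []
    for sdir in _subject_dirs(workdir):
        _require(sdir / "eeg.csv", "simulated EEG")
        eeg = read_eeg(sdir / "eeg.csv")
        eeg.subject_id = sdir.name
        bundle = SessionBundle(eeg=eeg)
        frames.append(window_feature_table(
            bundle, config.window_len, config.feature_mode))
    out = workdir / f"features_eeg_{config.window_len}s.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    return [str(out)]


def _stage_extract_face(workdir: Path, config: PipelineConfig) -> list[str]:
    frames = []
    for sdir in _subject_dirs(workdir):
        _require(sdir / "landmarks.csv", "simulated landmarks")
        seq = read_landmarks(sdir / "landmarks.csv")
        windows = segment_windows(seq.duration, config.window_len, sdir.name)
        table = facial_window_table(seq, windows).reset_index()
        table.insert(0, "subject_id", sdir.name)
        frames.append(table)
    out = workdir / f"features_face_{config.window_len}s.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    return [str(out)]


def _stage_label(workdir: Path, config: PipelineConfig) -> list[str]:
    subject_dirs = _subject_dirs(workdir)
    pooled = []
    for sdir in subject_dirs:
        _require(sdir / "scores.csv", "engagement scores")
        pooled.append(read_scores(sdir / "scores.csv").values)
    tau = median_threshold(np.concatenate(pooled))
    tables = []
    for sdir in subject_dirs:
        scores = read_scores(sdir / "scores.csv")
        log = read_trial_log(_require(sdir / "trials.csv", "trial log"))
        duration = len(scores.scores) * 10.0
        windows = segment_windows(duration, config.window_len, sdir.name)
        skills = None
        if (sdir / "skills.json").exists():
            skills = {k: skill_class(v) for k, v in
                      json.loads((sdir / "skills.json").read_text()).items()}
        tables.append(label_table(
            windows,
            engagement=engagement_labels(scores, windows, tau),
            attention=attention_labels(log, windows),
            skills=skills,
        ))
    out = workdir / f"labels_{config.window_len}s.csv"
    pd.concat(tables, ignore_index=True).to_csv(out, index=False)
    (workdir / "engagement_threshold.json").write_text(
        json.dumps({"median_threshold": tau}))
    return [str(out), str(workdir / "engagement_threshold.json")]


_META_COLS = ("subject_id", "window_index", "start", "end", "qc_flag")


def _load_features_labels(workdir: Path, config: PipelineConfig):
    tag = "eeg" if config.modality == "eeg" else "face"
    fpath = _require(workdir / f"features_{tag}_{config.window_len}s.csv",
                     "feature table")
    lpath = _require(workdir / f"labels_{config.window_len}s.csv", "labels")
    feats = pd.read_csv(fpath)
    labels = pd.read_csv(lpath)
    required = {"subject_id", "window_index"}
    for path, df in ((fpath, feats), (lpath, labels)):
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"{path} lacks column(s) {sorted(missing)}")
    merged = feats.merge(labels, on=["subject_id", "window_index"],
                         suffixes=("", "_lbl"))
    if config.target in ("engagement", "attention"):
        y = merged[config.target]
    else:
        col = f"skill_{config.target}"
        if col not in merged.columns:
            raise FormatError(f"labels file lacks column {col}")
        y = (merged[col] == "low").astype(int).rsub(1)  # low -> 0 (positive)
    keep = y.notna()
    if "qc_flag" in merged.columns:
        keep &= ~merged["qc_flag"].astype(bool)
    merged = merged.loc[keep]
    cols = [c for c in feats.columns if c not in _META_COLS]
    return merged[cols], y.loc[keep].to_numpy().astype(int), \
        merged["subject_id"].to_numpy()


def _stage_train(workdir: Path, config: PipelineConfig) -> list[str]:
    X, y, groups = _load_features_labels(workdir, config)
    report = train_eval(config.experiment, X, y, groups)
    out = workdir / f"model_report_{config.target}_{config.window_len}s.json"
    out.write_text(json.dumps(report.to_dict(), indent=1, default=str))
    if report.metrics.pr_curve:
        pr = pd.DataFrame(report.metrics.pr_curve,
                          columns=["recall", "precision"])
        pr.to_csv(workdir / f"pr_curve_{config.target}.csv", index=False)
    return [str(out)]


def _stage_report(workdir: Path, config: PipelineConfig) -> list[str]:
    reports = sorted(workdir.glob("model_report_*.json"))
    if not reports:
        raise CogstatesError(
            f"no model reports in {workdir}; run the train stage first")
    summary = {p.stem.replace("model_report_", ""):
               json.loads(p.read_text()) for p in reports}
    lines = ["target,model,f2,precision,recall,accuracy,cv_mean,cv_sd"]
    for tag, rep in summary.items():
        lines.append(
            f"{tag},{rep['model']},{rep['f2']:.4f},{rep['precision']:.4f},"
            f"{rep['recall']:.4f},{rep['accuracy']:.4f},"
            f"{rep['cv_mean']:.4f},{rep['cv_sd']:.4f}")
    out = workdir / "summary.csv"
    out.write_text("\n".join(lines) + "\n")
    return [str(out)]


def make_fixtures(scale: str, outdir, seed: int = 7) -> PipelineConfig:
    """Generator-built test cohorts: ``unit`` = one subject, seconds of
    signal; ``integration`` = 20 subjects, 5-minute sessions."""
    if scale == "unit":
        syn = SyntheticConfig(n_subjects=1, session_duration=30.0, seed=seed)
    elif scale == "integration":
        syn = SyntheticConfig(n_subjects=20, session_duration=300.0, seed=seed)
    else:
        raise CogstatesError(f"unknown fixture scale {scale!r}")
    config = PipelineConfig(workdir=str(outdir), seed=seed, synthetic=syn)
    run_stage("simulate", config)
    return config
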