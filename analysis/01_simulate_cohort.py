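"""Simulate the analysis cohort.

Writes a 12-subject, 5-minute synthetic cohort (EEG, landmarks, trial logs,
engagement scores, skill scores) as flat CSV/JSON under
scratch/analysis_run/cohort/, with the latent per-window states in
ground_truth.csv.
"""

from common import WORKDIR, pipeline_config

from cogstates.pipeline import run_stage


def main():
    cfg = pipeline_config()
    outputs = run_stage("simulate", cfg)
    print(f"simulated {cfg.synthetic.n_subjects} subjects "
          f"x {cfg.synthetic.session_duration:.0f}s into {WORKDIR}")
    print(f"{len(outputs)} artifact files written "
          f"(EEG/landmark/trial/score CSVs + skills JSON per subject)")


if __name__ == "__main__":
    main()
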