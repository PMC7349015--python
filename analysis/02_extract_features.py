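"""Extract per-window features from the simulated cohort.

EEG windows get the 70 canonical frequency-domain features (5 per channel:
four relative band powers + average power); landmark sequences get the
geometric EAR/MAR/NTJ/NTC window summaries with blink counts.
"""

import pandas as pd
from common import WORKDIR, pipeline_config

from cogstates.pipeline import run_stage


def main():
    cfg = pipeline_config()
    eeg_out = run_stage("extract-eeg", cfg)[0]
    face_out = run_stage("extract-face", cfg)[0]
    eeg = pd.read_csv(eeg_out)
    face = pd.read_csv(face_out)
    n_feat = len([c for c in eeg.columns
                  if c not in ("subject_id", "window_index", "start", "end",
                               "qc_flag")])
    print(f"EEG features: {len(eeg)} windows x {n_feat} features -> {eeg_out}")
    print(f"  QC-flagged windows: {int(eeg['qc_flag'].sum())}")
    print(f"facial features: {len(face)} windows -> {face_out}")
    print(f"  mean blinks per 10-s window: {face['blink_count'].mean():.2f}")


if __name__ == "__main__":
    main()
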