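"""Label the cohort windows and test engagement/attention dependence.

Engagement labels come from the pooled-median threshold over the cohort's
scores; attention labels from the fewer-than-4-mistakes rule; skills from
the 200/400 cut points.  A chi-square test of independence between the two
binary window labels is reported.
"""

import json

import pandas as pd
from common import RESULTS, WORKDIR, pipeline_config

from cogstates.labeling import label_dependence
from cogstates.pipeline import run_stage


def main():
    cfg = pipeline_config()
    label_path = run_stage("label", cfg)[0]
    labels = pd.read_csv(label_path)
    tau = json.loads((WORKDIR / "engagement_threshold.json").read_text())
    print(f"labels -> {label_path}")
    print(f"pooled-median engagement threshold: "
          f"{tau['median_threshold']:.5f}")
    print(f"engaged fraction: {labels['engagement'].mean():.3f}; "
          f"low-attention fraction: {1 - labels['attention'].mean():.3f}")
    chi2, df, p = label_dependence(labels["engagement"], labels["attention"])
    print(f"engagement/attention dependence: X2={chi2:.3f}, df={df}, p={p:.4g}")
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "label_dependence.json").write_text(json.dumps(
        {"chi2": chi2, "df": df, "p": p,
         "threshold": tau["median_threshold"]}, indent=1))


if __name__ == "__main__":
    main()
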