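"""Train and evaluate the engagement and attention models.

Engagement: standard scaling, no balancing (median-split labels are
near-balanced).  Attention: robust scaling + SMOTE (low attention is the
minority).  Both grids pit the random-forest preset against KNN on mean CV
F2; metrics are reported on the untouched 20% test split with the low
state as the positive class.
"""

import json
import shutil

from common import RESULTS, WORKDIR, pipeline_config

from cogstates.pipeline import run_stage


def main():
    RESULTS.mkdir(exist_ok=True)
    for target, scaling, balance in (("engagement", "standard", "none"),
                                     ("attention", "robust", "smote")):
        cfg = pipeline_config(target=target, scaling=scaling, balance=balance)
        report_path = run_stage("train", cfg)[0]
        rep = json.loads(open(report_path).read())
        print(f"{target}: model={rep['model']} F2={rep['f2']:.3f} "
              f"precision={rep['precision']:.3f} recall={rep['recall']:.3f} "
              f"(CV {rep['cv_mean']:.3f} +/- {rep['cv_sd']:.3f})")
        shutil.copy(report_path, RESULTS / f"model_report_{target}.json")
    summary = run_stage("report", pipeline_config())[0]
    shutil.copy(summary, RESULTS / "model_summary.csv")
    print(f"summary table -> {RESULTS / 'model_summary.csv'}")


if __name__ == "__main__":
    main()
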