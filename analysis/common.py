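"""Shared configuration for the numbered analysis drivers.

The analysis cohort is 12 subjects with 5-minute sessions — large enough
for every stage to be exercised end to end while keeping the on-disk
artifacts small.  Raw per-subject CSVs land under scratch/ (regenerable);
summary tables and model reports are copied into results/.
"""

from pathlib import Path

from cogstates.modeling import ExperimentConfig
from cogstates.pipeline import PipelineConfig
from cogstates.synthetic import SyntheticConfig

ROOT = Path(__file__).resolve().parents[1]
WORKDIR = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"

SEED = 20240


def pipeline_config(target: str = "engagement",
                    balance: str = "none",
                    scaling: str = "standard") -> PipelineConfig:
    synthetic = SyntheticConfig(n_subjects=12, session_duration=300.0,
                                seed=SEED)
    experiment = ExperimentConfig(
        target=target, scaling=scaling, balance=balance, cv_folds=5,
        models={"rf": [{"n_estimators": 100}],
                "knn": [{"n_neighbors": 11}]},
        seed=SEED)
    return PipelineConfig(workdir=str(WORKDIR), seed=SEED,
                          target=target, synthetic=synthetic,
                          experiment=experiment)
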