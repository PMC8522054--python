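import warnings

import pytest

from twohit.pipeline import PipelineConfig, run_pipeline
from twohit.synthetic_cohort import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, seed 1 (the study conditions)."""
    return simulate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def pipeline_results(cohort, tmp_path_factory):
    """Full pipeline run on the default cohort (shared across tests)."""
    outdir = tmp_path_factory.mktemp("pipeline")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = run_pipeline(cohort, outdir, PipelineConfig(seed=0))
    results["outdir"] = outdir
    return results


@pytest.fixture(scope="session")
def classified(pipeline_results):
    return pipeline_results["variants"]
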