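import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

logging.getLogger("neoepitope").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """The golden synthetic cohort: seed 1, 2 patients, 3 regions."""
    from neoepitope.fixtures import make_cohort

    root = tmp_path_factory.mktemp("cohort")
    return make_cohort(root, seed=1, n_patients=2, n_regions=3)


@pytest.fixture(scope="session")
def cohort_run(cohort, tmp_path_factory):
    """One full unfiltered pipeline run over the golden cohort."""
    from neoepitope.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("cohort_out")
    config = PipelineConfig(
        vcf_dir=cohort.vcf_dir,
        genome=cohort.genome,
        transcripts=cohort.transcripts,
        out_dir=out,
        hla=cohort.hla_simple,
        hla_dialect="simple_tsv",
        predictor="table",
        predictor_table=cohort.predictor_table,
        filtered=False,
        recognition=True,
        epitope_db=cohort.epitope_db,
        novelty=True,
        proteome=cohort.proteome,
        expression=cohort.expression,
    )
    return run_pipeline(config)
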