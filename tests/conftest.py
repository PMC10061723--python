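import pytest

from mirvar import GeneratorConfig, PipelineConfig, generate_cohort, run_pipeline


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """One default synthetic cohort (seed 1), shared across the session."""
    outdir = tmp_path_factory.mktemp("cohort")
    files, truth = generate_cohort(GeneratorConfig(seed=1), outdir)
    return files, truth


@pytest.fixture(scope="session")
def pipeline_run(cohort, tmp_path_factory):
    files, truth = cohort
    outdir = tmp_path_factory.mktemp("pipeline")
    result = run_pipeline(PipelineConfig.from_cohort(files, outdir))
    return result, truth
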