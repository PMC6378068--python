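import pathlib

import pytest
from hypothesis import HealthCheck, settings

from netpharm import (
    FixtureSpec,
    PipelineConfig,
    PipelineInputs,
    generate_paper_shape_fixture,
    read_compound_table,
    run_pipeline,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

HERBS = ("HMM", "PHP", "AMK", "RMB", "CZR", "HDW")


@pytest.fixture(scope="session")
def representative_table():
    """The 24-compound reference ADME table bundled with the package."""
    from importlib import resources

    ref = resources.files("netpharm.data") / "wpx_representative_compounds.tsv"
    with resources.as_file(ref) as path:
        return read_compound_table(path, herb_code="WPX")


@pytest.fixture(scope="session")
def study_fixture(tmp_path_factory):
    """Deterministic study-shaped fixture files plus ground truth."""
    out = tmp_path_factory.mktemp("fixture")
    return generate_paper_shape_fixture(FixtureSpec(seed=0), out)


@pytest.fixture(scope="session")
def fixture_inputs(study_fixture):
    return PipelineInputs(
        compound_tables={h: study_fixture.files[f"compounds_{h}"] for h in HERBS},
        edges=study_fixture.files["edges"],
        disease=study_fixture.files["disease"],
        pathway_gmt=study_fixture.files["pathways"],
        go_gmt=study_fixture.files["go_bp"],
    )


@pytest.fixture(scope="session")
def fixture_report(study_fixture, fixture_inputs, tmp_path_factory):
    """The full pipeline run once over the study fixture."""
    out = tmp_path_factory.mktemp("pipeline_out")
    config = PipelineConfig.from_yaml(study_fixture.files["config"])
    report = run_pipeline(config, fixture_inputs, out)
    return report, pathlib.Path(out)
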